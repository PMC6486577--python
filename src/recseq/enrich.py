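"""Per-position counting, enrichment scores, heat maps, and aggregation.

For each half-site position i the post-selection abundance of the
canonical base (A_i) and the summed non-canonical bases (B_i) are compared
with the corresponding pre-selection fractions (alpha_i, beta_i) through

    r_i = (A_i / B_i) / (alpha_i / beta_i)

after pseudocounting.  Per-base heat-map cells are post/pre frequency
ratios normalized to the canonical base; replicates are combined by
positionwise geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .readio import ExtractedRead
from .targets import PRIME, Side, TargetSite, positions_sequence_order

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_PSEUDOCOUNT = 0.5


class TallyError(ValueError):
    pass


class PairingError(ValueError):
    pass


class AggregationError(ValueError):
    pass


def _labels(site: TargetSite, side: Side) -> list[str]:
    suffix = PRIME if side is Side.RIGHT else ""
    return [f"{p}{suffix}" for p in positions_sequence_order(site, side)]


@dataclass
class CountTable:
    """Per-position x per-base counts for one sample.

    ``counts`` rows follow half-site string order (5' to 3' of the read);
    ``positions`` holds the center-out position number of each row.
    """

    site: TargetSite
    side: Side
    counts: np.ndarray  # (L, 4) ACGT
    n_reads: int

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        L = len(self.site.half(self.side))
        if self.counts.shape != (L, 4):
            raise TallyError(f"counts must have shape ({L}, 4)")
        if np.any(self.counts.sum(axis=1) != self.n_reads):
            raise TallyError("column sums must equal n_reads at every position")

    @property
    def positions(self) -> list[int]:
        return positions_sequence_order(self.site, self.side)

    @property
    def labels(self) -> list[str]:
        return _labels(self.site, self.side)

    @property
    def canonical_index(self) -> np.ndarray:
        return np.array([_BASE_INDEX[b] for b in self.site.half(self.side)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "label", self.labels)
        df.insert(1, "position", self.positions)
        return df


def tally(reads: Sequence[ExtractedRead | str], site: TargetSite, side: Side | str) -> CountTable:
    """Count bases per half-site position over kept reads."""
    side = Side(side)
    half = site.half(side)
    L = len(half)
    counts = np.zeros((L, 4), dtype=np.int64)
    n = 0
    for r in reads:
        variant = r if isinstance(r, str) else r.variant
        if variant is None or len(variant) != L:
            raise TallyError("variant length does not match the half-site")
        for i, b in enumerate(variant):
            counts[i, _BASE_INDEX[b]] += 1
        n += 1
    if n == 0:
        raise TallyError("cannot tally zero reads")
    return CountTable(site, side, counts, n)


@dataclass
class EnrichmentProfile:
    """Per-position enrichment for one experiment or replicate aggregate."""

    site: TargetSite
    side: Side
    A: np.ndarray
    B: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    r: np.ndarray
    e: np.ndarray  # (L, 4) per-base enrichment, canonical column == 1
    replicate_id: str = ""

    @property
    def log2_r(self) -> np.ndarray:
        return np.log2(self.r)

    @property
    def positions(self) -> list[int]:
        return positions_sequence_order(self.site, self.side)

    @property
    def labels(self) -> list[str]:
        return _labels(self.site, Side(self.side))

    @property
    def canonical_half(self) -> str:
        return self.site.half(self.side)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "position": self.positions,
                "canonical": list(self.canonical_half),
                "A": self.A,
                "B": self.B,
                "alpha": self.alpha,
                "beta": self.beta,
                "r": self.r,
                "log2_r": self.log2_r,
            }
        )
        for j, b in enumerate(BASES):
            df[f"log2_e_{b}"] = np.log2(self.e[:, j])
        return df


def _check_paired(pre: CountTable, post: CountTable) -> None:
    if pre.site.sequence != post.site.sequence or Side(pre.side) is not Side(post.side):
        raise PairingError("pre and post tables refer to different sites/sides")


def enrichment(
    pre: CountTable,
    post: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    replicate_id: str = "",
) -> EnrichmentProfile:
    """Per-position enrichment profile from paired pre/post count tables."""
    _check_paired(pre, post)
    c = post.canonical_index
    rows = np.arange(post.counts.shape[0])
    A = post.counts[rows, c].astype(float)
    B = post.counts.sum(axis=1) - A
    a_pre = pre.counts[rows, c].astype(float)
    b_pre = pre.counts.sum(axis=1) - a_pre
    # pseudocount all four aggregates before forming any ratio
    Ap, Bp = A + pseudocount, B + pseudocount
    ap, bp = a_pre + pseudocount, b_pre + pseudocount
    alpha = ap / (ap + bp)
    beta = bp / (ap + bp)
    r = (Ap / Bp) / (alpha / beta)
    e = per_base_enrichment(pre, post, pseudocount)
    return EnrichmentProfile(
        post.site, Side(post.side), A, B, alpha, beta, r, e, replicate_id
    )


def per_base_enrichment(
    pre: CountTable, post: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Per-base matrix e[i][b]: post/pre frequency ratio vs canonical.

    e[i][b] = (F_post(i,b)/F_pre(i,b)) / (F_post(i,c)/F_pre(i,c)) with
    pseudocounted frequencies; the canonical column is exactly 1.
    """
    _check_paired(pre, post)
    Fpost = (post.counts + pseudocount) / (post.n_reads + 4 * pseudocount)
    Fpre = (pre.counts + pseudocount) / (pre.n_reads + 4 * pseudocount)
    ratio = Fpost / Fpre
    c = post.canonical_index
    rows = np.arange(ratio.shape[0])
    e = ratio / ratio[rows, c][:, None]
    e[rows, c] = 1.0
    return e


@dataclass
class ReplicateSet:
    """Profiles of independent replicates of one experiment."""

    members: list[EnrichmentProfile]

    def __post_init__(self) -> None:
        if not self.members:
            raise AggregationError("replicate set is empty")
        ref = self.members[0]
        for m in self.members[1:]:
            if m.site.sequence != ref.site.sequence or Side(m.side) is not Side(ref.side):
                raise AggregationError("replicates mix sites or sides")


def aggregate(replicates: ReplicateSet | Sequence[EnrichmentProfile]) -> EnrichmentProfile:
    """Positionwise geometric mean of r_i and of the per-base matrix."""
    if not isinstance(replicates, ReplicateSet):
        replicates = ReplicateSet(list(replicates))
    members = replicates.members
    ref = members[0]
    r = np.exp(np.mean([np.log(m.r) for m in members], axis=0))
    e = np.exp(np.mean([np.log(m.e) for m in members], axis=0))
    n = float(len(members))
    return EnrichmentProfile(
        ref.site,
        Side(ref.side),
        A=np.mean([m.A for m in members], axis=0),
        B=np.mean([m.B for m in members], axis=0),
        alpha=np.mean([m.alpha for m in members], axis=0),
        beta=np.mean([m.beta for m in members], axis=0),
        r=r,
        e=e,
        replicate_id=f"geomean(n={int(n)})",
    )


@dataclass
class FullSiteProfile:
    """Left- and right-half profiles concatenated with primed right labels.

    Ordered outermost-left to outermost-right: left positions descending
    to the core, then primed right positions ascending away from it.
    No counts are recomputed; the halves come from separate experiments.
    """

    site: TargetSite
    labels: list[str]
    positions: list[int]
    sides: list[Side]
    canonical: str
    r: np.ndarray
    e: np.ndarray

    @property
    def log2_r(self) -> np.ndarray:
        return np.log2(self.r)

    def half_log2_r(self, side: Side | str) -> np.ndarray:
        """log2 r over one half, ordered innermost (core-adjacent) first."""
        side = Side(side)
        idx = [i for i, s in enumerate(self.sides) if s is side]
        vals = self.log2_r[idx]
        return vals[::-1] if side is Side.LEFT else vals

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "position": self.positions,
                "side": [s.value for s in self.sides],
                "canonical": list(self.canonical),
                "r": self.r,
                "log2_r": self.log2_r,
            }
        )
        for j, b in enumerate(BASES):
            df[f"log2_e_{b}"] = np.log2(self.e[:, j])
        return df


def assemble_full_site(left: EnrichmentProfile, right: EnrichmentProfile) -> FullSiteProfile:
    """Concatenate an L-randomized and an R-randomized profile."""
    if Side(left.side) is not Side.LEFT or Side(right.side) is not Side.RIGHT:
        raise PairingError("assemble_full_site needs a left and a right profile")
    if left.site.sequence != right.site.sequence:
        raise PairingError("left and right profiles come from different sites")
    site = left.site
    labels = left.labels + right.labels
    positions = left.positions + right.positions
    sides = [Side.LEFT] * len(left.positions) + [Side.RIGHT] * len(right.positions)
    canonical = left.canonical_half + right.canonical_half
    r = np.concatenate([left.r, right.r])
    e = np.vstack([left.e, right.e])
    return FullSiteProfile(site, labels, positions, sides, canonical, r, e)


def write_profile_tsv(profile: EnrichmentProfile | FullSiteProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def load_full_site_profile(
    left_path: str | Path, right_path: str | Path, site: TargetSite
) -> FullSiteProfile:
    """Rebuild a full-site profile from two serialized half profiles."""
    halves = []
    for path, side in ((left_path, Side.LEFT), (right_path, Side.RIGHT)):
        df = pd.read_csv(path, sep="\t")
        e = np.exp2(df[[f"log2_e_{b}" for b in BASES]].to_numpy())
        halves.append(
            EnrichmentProfile(
                site,
                side,
                A=df.get("A", pd.Series(np.zeros(len(df)))).to_numpy(float),
                B=df.get("B", pd.Series(np.zeros(len(df)))).to_numpy(float),
                alpha=df.get("alpha", pd.Series(np.full(len(df), 0.5))).to_numpy(float),
                beta=df.get("beta", pd.Series(np.full(len(df), 0.5))).to_numpy(float),
                r=df["r"].to_numpy(float),
                e=e,
            )
        )
    return assemble_full_site(halves[0], halves[1])
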