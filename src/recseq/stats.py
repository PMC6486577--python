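"""Replicate-level significance testing and feature-matrix export.

Per-position differences between an enzyme variant and a reference are
tested with a pooled-variance two-sample t-test on log2 enrichment,
Bonferroni-corrected over all full-site positions.  Whole-profile
differences use a two-sided Mann-Whitney U test on the absolute residuals
around the reference group's positionwise mean (exact by enumeration for
small pooled samples, tie-corrected normal approximation otherwise).
Half-site asymmetry is a paired t-test over mirrored positions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrich import FullSiteProfile
from .targets import Side

ALPHA = 0.05
EXACT_MWU_MAX_POOLED = 12


class InsufficientReplicatesError(ValueError):
    pass


def bonferroni(p: float | np.ndarray, n_comparisons: int) -> float | np.ndarray:
    """Adjusted p = min(1, p * family size)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_comparisons)


@dataclass
class PerPositionResult:
    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    family_size: int

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )
        if labels is not None:
            df.insert(0, "label", list(labels))
        return df


def per_position_test(
    variant: np.ndarray,
    reference: np.ndarray,
    family_size: int | None = None,
    alpha: float = ALPHA,
) -> PerPositionResult:
    """Equal-variance t-test per position on log2 enrichment replicates.

    ``variant`` and ``reference`` are (n_replicates, n_positions) arrays.
    The Bonferroni family defaults to the number of positions.
    """
    variant = np.atleast_2d(np.asarray(variant, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if variant.shape[0] < 2 or reference.shape[0] < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    if variant.shape[1] != reference.shape[1]:
        raise ValueError("groups cover different position sets")
    n_pos = variant.shape[1]
    family = family_size if family_size is not None else n_pos
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(variant, reference, axis=0, equal_var=True)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p))
    p_adj = bonferroni(p, family)
    return PerPositionResult(t, p, p_adj, p_adj <= alpha, family)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for the first sample, ties counted as 1/2."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided MWU p by enumerating all group assignments.

    Handles ties; two-sidedness is the probability of a U at least as far
    from the null mean n1*n2/2 as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    u_obs = _u_statistic(x, y)
    center = len(x) * len(y) / 2.0
    dev = abs(u_obs - center)
    hits = total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


@dataclass
class ProfileTestResult:
    u: float
    p_raw: float
    p_adjusted: float
    method: str
    n_variant: int
    n_reference: int


def profile_test(
    variant: np.ndarray,
    reference: np.ndarray,
    n_variants_in_family: int = 1,
    exact_max_pooled: int = EXACT_MWU_MAX_POOLED,
) -> ProfileTestResult:
    """Whole-profile Mann-Whitney U test on absolute residuals.

    Residuals are each replicate's log2 r minus the *reference* group's
    positionwise mean; the two-sided test compares the pooled |residual|
    samples of the two groups.  Bonferroni corrects over the number of
    enzyme variants compared in the analysis run.
    """
    variant = np.atleast_2d(np.asarray(variant, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if variant.size == 0 or reference.size == 0:
        raise ValueError("both groups must be non-empty")
    ref_mean = reference.mean(axis=0)
    res_var = np.abs(variant - ref_mean).ravel()
    res_ref = np.abs(reference - ref_mean).ravel()
    pooled = len(res_var) + len(res_ref)
    if pooled <= exact_max_pooled:
        u, p = mann_whitney_exact(res_var, res_ref)
        method = "exact"
    else:
        result = sps.mannwhitneyu(res_var, res_ref, alternative="two-sided",
                                  method="asymptotic")
        u, p = float(result.statistic), float(result.pvalue)
        method = "asymptotic"
    return ProfileTestResult(
        u, p, float(bonferroni(p, n_variants_in_family)), method,
        variant.shape[0], reference.shape[0],
    )


@dataclass
class AsymmetryResult:
    t: float
    p: float
    n_pairs: int
    mean_difference: float
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)


def asymmetry_test(
    profiles: Sequence[FullSiteProfile] | FullSiteProfile,
) -> AsymmetryResult:
    """Paired t-test of left vs mirrored right half-site log2 enrichment.

    Pairs (position p, position p') are pooled across the supplied
    replicate profiles.
    """
    if isinstance(profiles, FullSiteProfile):
        profiles = [profiles]
    left = np.concatenate([p.half_log2_r(Side.LEFT) for p in profiles])
    right = np.concatenate([p.half_log2_r(Side.RIGHT) for p in profiles])
    if len(left) != len(right):
        raise ValueError("left and right halves have different position counts")
    if len(left) < 2:
        raise InsufficientReplicatesError("need >= 2 paired observations")
    diffs = left - right
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return AsymmetryResult(0.0, 1.0, len(diffs), 0.0)
        return AsymmetryResult(
            np.inf * np.sign(diffs.mean()), 0.0, len(diffs), float(diffs.mean()),
            degenerate=True,
            warnings=["zero variance in paired differences; p reported as 0"],
        )
    t, p = sps.ttest_rel(left, right)
    return AsymmetryResult(float(t), float(p), len(diffs), float(diffs.mean()))


def feature_matrix(
    experiments: dict[str, Sequence[FullSiteProfile]] | Sequence[tuple[str, FullSiteProfile]],
) -> pd.DataFrame:
    """One row per replicate, columns = log2 r over all full-site positions."""
    if isinstance(experiments, dict):
        pairs = [
            (f"{name}:{i}", prof)
            for name, profs in experiments.items()
            for i, prof in enumerate(profs)
        ]
    else:
        pairs = list(experiments)
    if not pairs:
        raise ValueError("no experiments supplied")
    columns = pairs[0][1].labels
    rows = {}
    for row_id, prof in pairs:
        if prof.labels != columns:
            raise ValueError("inconsistent position sets across experiments")
        rows[row_id] = prof.log2_r
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def embed_feature_matrix(matrix: pd.DataFrame, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Delegated seeded 2-D embedding of the feature matrix (visualization only)."""
    from sklearn.manifold import TSNE

    if perplexity is None:
        perplexity = max(2.0, min(30.0, (len(matrix) - 1) / 3))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(matrix.to_numpy())
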