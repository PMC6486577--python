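"""Synthetic selection-experiment generator with a closed-form oracle.

Emulates the wet-lab workflow: a partially randomized substrate library
(one randomized half-site per experiment, each randomized position holding
the canonical base with probability ``canonical_fraction`` and each other
base with equal shares of the remainder), a multiplicative per-position
selection model with a stringency exponent, exonuclease-escape background,
and read/UMI sampling into FASTQ.

All positions here are indexed in half-site *string order* (5' to 3' of
the read); use :func:`recseq.targets.positions_sequence_order` to map to
center-out numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .targets import Side, TargetSite, resolve_site

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_ARRAY = np.frombuffer(BASES.encode(), dtype="S1")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LibrarySpec:
    """Randomized substrate library design."""

    site: TargetSite
    randomized_side: Side = Side.LEFT
    canonical_fraction: float = 0.79
    umi_length: int = 10
    flank_5p: str = "GCAGTGAACTGACT"
    flank_3p: str = "AGTCAGTTCACAGC"

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", resolve_site(self.site))
        object.__setattr__(self, "randomized_side", Side(self.randomized_side))
        if not 0.0 < self.canonical_fraction <= 1.0:
            raise ValueError("canonical_fraction must be in (0, 1]")
        if self.umi_length < 1:
            raise ValueError("umi_length must be positive")

    @property
    def canonical_half(self) -> str:
        return self.site.half(self.randomized_side)

    def base_probabilities(self) -> np.ndarray:
        """(L, 4) per-position base probabilities in ACGT order."""
        f = self.canonical_fraction
        other = (1.0 - f) / 3.0
        probs = np.full((len(self.canonical_half), 4), other)
        for i, base in enumerate(self.canonical_half):
            probs[i, _BASE_INDEX[base]] = f
        return probs


@dataclass(frozen=True)
class SelectionModel:
    """Multiplicative per-position acceptance model.

    A half-site ``s`` is accepted with probability
    ``p_max * prod_i w[i, s_i] ** gamma``; canonical weights are 1, so the
    canonical half-site is accepted with probability exactly ``p_max``.
    ``gamma`` plays the role of selection stringency (the protein:DNA-ratio
    analog: gamma -> 0 accepts all sequences alike) and ``background_survival``
    is the fraction of non-recombined molecules escaping digestion.
    """

    weights: np.ndarray  # (L, 4), ACGT order, canonical column == 1
    gamma: float = 1.0
    p_max: float = 1.0
    background_survival: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("weights must be an (L, 4) array")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        if not 0.0 <= self.background_survival < 1.0:
            raise ValueError("background_survival must be in [0, 1)")

    @classmethod
    def neutral(cls, half_length: int, **kwargs) -> "SelectionModel":
        return cls(np.ones((half_length, 4)), **kwargs)

    @classmethod
    def from_weight_map(
        cls,
        canonical_half: str,
        noncanonical: float | Sequence[float],
        **kwargs,
    ) -> "SelectionModel":
        """Uniform non-canonical weight(s) per string position."""
        L = len(canonical_half)
        vals = np.broadcast_to(np.asarray(noncanonical, dtype=float), (L,))
        w = np.repeat(vals[:, None], 4, axis=1).copy()
        for i, base in enumerate(canonical_half):
            w[i, _BASE_INDEX[base]] = 1.0
        return cls(w, **kwargs)

    def acceptance_probability(self, half: str) -> float:
        idx = encode(half)
        return float(
            self.p_max
            * np.prod(self.weights[np.arange(len(idx)), idx] ** self.gamma)
        )


@dataclass(frozen=True)
class SimConfig:
    n_molecules: int = 10_000
    n_reads: int = 50_000
    mean_reads_per_molecule: float = 3.0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.n_reads < 1:
            raise ValueError("counts must be positive")
        if self.mean_reads_per_molecule <= 0:
            raise ValueError("mean_reads_per_molecule must be > 0")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")


@dataclass
class Molecule:
    variant: str
    umi: str
    recombined: bool = False
    background: bool = False


@dataclass
class GroundTruthManifest:
    """Per-molecule ground truth plus the generating model and design."""

    molecules: list[Molecule]
    spec: LibrarySpec
    model: SelectionModel | None = None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("umi\tvariant\trecombined\tbackground\n")
            for m in self.molecules:
                fh.write(
                    f"{m.umi}\t{m.variant}\t{int(m.recombined)}\t{int(m.background)}\n"
                )


def encode(seq: str) -> np.ndarray:
    """DNA string -> int array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = np.empty(len(seq), dtype=np.int64)
    for i, b in enumerate(BASES):
        out[arr == b.encode()] = i
    return out


def _decode_rows(idx: np.ndarray) -> list[str]:
    chars = _BASE_ARRAY[idx]
    return [row.tobytes().decode() for row in chars]


def sample_library(
    spec: LibrarySpec, n: int, seed: int | np.random.Generator = 0
) -> list[Molecule]:
    """Draw ``n`` library molecules with independent positions and UMIs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = spec.base_probabilities()
    L = probs.shape[0]
    u = rng.random((n, L))
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    variants = _decode_rows(idx)
    umis = _decode_rows(rng.integers(0, 4, size=(n, spec.umi_length)))
    return [Molecule(v, u_) for v, u_ in zip(variants, umis)]


def select_recombinants(
    molecules: Sequence[Molecule],
    model: SelectionModel,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Molecule], list[Molecule]]:
    """Partition molecules into recombined and surviving-background sets.

    Each molecule recombines independently with probability
    ``p_max * prod w^gamma``; failures survive digestion with probability
    ``background_survival``.  Flags are set on the molecules in place.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not molecules:
        return [], []
    L = model.weights.shape[0]
    idx = np.stack([encode(m.variant) for m in molecules])
    if idx.shape[1] != L:
        raise ValueError("variant length does not match selection model")
    logw = np.log(model.weights)
    p = model.p_max * np.exp(model.gamma * logw[np.arange(L)[None, :], idx].sum(axis=1))
    accept = rng.random(len(molecules)) < p
    background = (~accept) & (rng.random(len(molecules)) < model.background_survival)
    recombined, survivors = [], []
    for m, a, b in zip(molecules, accept, background):
        m.recombined = bool(a)
        m.background = bool(b)
        if a:
            recombined.append(m)
        elif b:
            survivors.append(m)
    return recombined, survivors


def assemble_substrate(spec: LibrarySpec, variant: str) -> str:
    """Full site string with ``variant`` substituted on the randomized side."""
    site = spec.site
    if spec.randomized_side is Side.LEFT:
        return variant + site.core + site.right_half
    return site.left_half + site.core + variant


def _sample_reads(
    pool: Sequence[Molecule],
    spec: LibrarySpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[Molecule, str]]:
    """Sample ~n_reads reads: per-molecule Poisson weights, then draws."""
    weights = rng.poisson(config.mean_reads_per_molecule, size=len(pool)).astype(float)
    total = weights.sum()
    if total == 0:
        weights[:] = 1.0
        total = float(len(pool))
    picks = rng.choice(len(pool), size=config.n_reads, p=weights / total)
    reads = []
    for j in picks:
        mol = pool[j]
        seq = spec.flank_5p + mol.umi + assemble_substrate(spec, mol.variant) + spec.flank_3p
        if config.seq_error_rate > 0:
            arr = encode(seq)
            hit = rng.random(len(arr)) < config.seq_error_rate
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                arr[hit] = (arr[hit] + shift) % 4
                seq = _decode_rows(arr[None, :])[0]
        reads.append((mol, seq))
    return reads


def _write_fastq(path: Path, reads: list[tuple[Molecule, str]], tag: str) -> None:
    with open(path, "w") as fh:
        for i, (_, seq) in enumerate(reads):
            fh.write(f"@{tag}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def emit_fastq(
    pre_pool: Sequence[Molecule],
    post_pool: Sequence[Molecule],
    spec: LibrarySpec,
    config: SimConfig,
    out_dir: str | Path,
    model: SelectionModel | None = None,
) -> GroundTruthManifest:
    """Write ``pre.fastq``, ``post.fastq``, ``manifest.tsv``, ``truth.json``.

    Deterministic for a fixed config seed; reads are
    flank + UMI + substrate + flank with constant quality.
    """
    if not pre_pool or not post_pool:
        raise SimulationError("cannot emit reads from an empty pool")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pre_reads = _sample_reads(pre_pool, spec, config, rng)
    post_reads = _sample_reads(post_pool, spec, config, rng)
    _write_fastq(out_dir / "pre.fastq", pre_reads, "pre")
    _write_fastq(out_dir / "post.fastq", post_reads, "post")
    manifest = GroundTruthManifest(list(pre_pool), spec, model)
    manifest.write_tsv(out_dir / "manifest.tsv")
    truth = {
        "site": spec.site.name,
        "randomized_side": spec.randomized_side.value,
        "canonical_fraction": spec.canonical_fraction,
        "umi_length": spec.umi_length,
        "n_molecules": len(pre_pool),
        "n_post_molecules": len(post_pool),
        "config": {
            "n_molecules": config.n_molecules,
            "n_reads": config.n_reads,
            "mean_reads_per_molecule": config.mean_reads_per_molecule,
            "seq_error_rate": config.seq_error_rate,
            "seed": config.seed,
        },
    }
    if model is not None:
        truth["model"] = {
            "weights": model.weights.tolist(),
            "gamma": model.gamma,
            "p_max": model.p_max,
            "background_survival": model.background_survival,
        }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return manifest


def expected_enrichment(model: SelectionModel, spec: LibrarySpec) -> np.ndarray:
    """Closed-form expected per-position enrichment ratio r*_i.

    Under independent positions, multiplicative selection and no
    background: r*_i = beta / sum_{b != canonical} alpha_b * w[i,b]^gamma
    with alpha_b = (1 - canonical_fraction)/3 and beta = 1 - canonical_fraction.
    Independent of p_max and of the other positions.  Indexed in half-site
    string order.
    """
    f = spec.canonical_fraction
    alpha_b = (1.0 - f) / 3.0
    beta = 1.0 - f
    half = spec.canonical_half
    r = np.empty(len(half))
    for i, base in enumerate(half):
        noncanon = [j for j in range(4) if j != _BASE_INDEX[base]]
        denom = sum(alpha_b * model.weights[i, j] ** model.gamma for j in noncanon)
        r[i] = beta / denom
    return r


def simulate_experiment(
    spec: LibrarySpec,
    model: SelectionModel,
    config: SimConfig,
    out_dir: str | Path,
) -> GroundTruthManifest:
    """Full simulation: library -> selection -> FASTQ emission."""
    rng = np.random.default_rng(config.seed)
    molecules = sample_library(spec, config.n_molecules, rng)
    recombined, background = select_recombinants(molecules, model, rng)
    post_pool = recombined + background
    if not post_pool:
        raise SimulationError("selection left no molecules in the post pool")
    return emit_fastq(molecules, post_pool, spec, config, out_dir, model=model)
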