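"""UMI-based experiment quality score (kappa) and power classification.

For each distinct half-site variant in the post-selection reads, the
number of distinct UMIs is regressed on its percent abundance; kappa is
the fitted slope divided by 10^4.  Large kappa means the profile rests on
many independent recombination events; replicate-averaged kappa above 1.5
marks a well-powered experiment, below 0.5 one dominated by background.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .readio import ExtractedRead

KAPPA_SCALE = 1e4
WELL_POWERED_THRESHOLD = 1.5
HEAVY_BACKGROUND_THRESHOLD = 0.5


class QualityError(ValueError):
    pass


class DegenerateFitError(QualityError):
    pass


@dataclass(frozen=True)
class VariantUmiStats:
    variant: str
    reads: int
    percent_abundance: float
    distinct_umis: int


@dataclass(frozen=True)
class KappaResult:
    slope: float
    intercept: float
    r_squared: float
    kappa: float
    n_variants: int


class PowerLabel(str, Enum):
    WELL_POWERED = "well_powered"
    MODEST_BACKGROUND = "modest_background"
    HEAVY_BACKGROUND = "heavy_background"


@dataclass(frozen=True)
class PowerClass:
    kappa_avg: float
    label: PowerLabel
    n_replicates: int


def umi_stats(reads: Iterable[ExtractedRead | tuple[str, str]]) -> list[VariantUmiStats]:
    """Per-variant read counts, percent abundance, and distinct-UMI counts.

    UMIs are deduplicated by exact string match (no error-tolerant
    clustering).
    """
    counts: dict[str, int] = {}
    umis: dict[str, set[str]] = {}
    total = 0
    for r in reads:
        variant, umi = (r.variant, r.umi) if isinstance(r, ExtractedRead) else r
        if variant is None or umi is None:
            continue
        counts[variant] = counts.get(variant, 0) + 1
        umis.setdefault(variant, set()).add(umi)
        total += 1
    if total == 0:
        raise QualityError("no reads with variants and UMIs")
    return [
        VariantUmiStats(v, n, 100.0 * n / total, len(umis[v]))
        for v, n in sorted(counts.items())
    ]


def kappa(stats: Sequence[VariantUmiStats], literal_orientation: bool = False) -> KappaResult:
    """Ordinary least-squares kappa from per-variant UMI statistics.

    Default orientation regresses distinct-UMI count on percent abundance,
    so kappa tracks the number of unique recombination events captured
    (about total distinct molecules / 10^6).  ``literal_orientation=True``
    swaps regressor and response.
    """
    if len(stats) < 2:
        raise DegenerateFitError("kappa needs at least two distinct variants")
    x = np.array([s.percent_abundance for s in stats], dtype=float)
    y = np.array([s.distinct_umis for s in stats], dtype=float)
    if literal_orientation:
        x, y = y, x
    if np.allclose(x, x[0]):
        raise DegenerateFitError("zero variance in the regressor")
    fit = sps.linregress(x, y)
    return KappaResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        kappa=float(fit.slope) / KAPPA_SCALE,
        n_variants=len(stats),
    )


def classify(kappas: Sequence[float | KappaResult]) -> PowerClass:
    """Power label from replicate kappas: mean vs the 1.5 / 0.5 thresholds."""
    if not kappas:
        raise QualityError("classify needs at least one replicate kappa")
    values = [k.kappa if isinstance(k, KappaResult) else float(k) for k in kappas]
    kavg = float(np.mean(values))
    if kavg > WELL_POWERED_THRESHOLD:
        label = PowerLabel.WELL_POWERED
    elif kavg >= HEAVY_BACKGROUND_THRESHOLD:
        label = PowerLabel.MODEST_BACKGROUND
    else:
        label = PowerLabel.HEAVY_BACKGROUND
    return PowerClass(kavg, label, len(values))
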