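"""Recombinase target-site model with center-out half-site numbering.

A target site is two half-sites flanking a central core where strand
exchange occurs.  Half-site positions are numbered outward from the core:
the innermost base of each half-site (adjacent to the core) carries
``numbering_start`` and the index grows toward the outer edge of the site.
Right-half positions are conventionally rendered with a prime (``10'``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import yaml

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_BASES = frozenset("ACGT")

PRIME = "′"


class Side(str, Enum):
    """Which half-site of a target site is being referred to."""

    LEFT = "left"
    RIGHT = "right"


class CoordinateError(ValueError):
    """Raised for a half-site position outside the numbered range."""


class IncompatibleSitesError(ValueError):
    """Raised when two sites cannot be compared position-by-position."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """A recombinase recognition site: left half, core, right half.

    Parameters
    ----------
    name
        Short identifier (e.g. ``"loxP"``).
    left_half, core, right_half
        DNA strings over {A, C, G, T}; case-folded to uppercase on load.
    numbering_start
        Index assigned to the innermost half-site base.  Defaults to
        ``len(core) // 2 + 1`` which reproduces the 5..17 numbering of
        Cre-family sites (8-bp core, 13-bp half-sites).
    """

    name: str
    left_half: str
    core: str
    right_half: str
    numbering_start: int | None = None

    def __post_init__(self) -> None:
        for field in ("left_half", "core", "right_half"):
            seq = getattr(self, field).upper()
            if not seq:
                raise ValueError(f"{self.name}: {field} must be non-empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"{self.name}: {field} contains non-ACGT characters {sorted(bad)}"
                )
            object.__setattr__(self, field, seq)
        if self.numbering_start is None:
            object.__setattr__(self, "numbering_start", len(self.core) // 2 + 1)

    @property
    def sequence(self) -> str:
        """Full site: left half + core + right half."""
        return self.left_half + self.core + self.right_half

    def __len__(self) -> int:
        return len(self.sequence)

    def half(self, side: Side | str) -> str:
        side = Side(side)
        return self.left_half if side is Side.LEFT else self.right_half

    def positions(self, side: Side | str) -> range:
        """Numbered positions of one half-site, innermost first."""
        n = len(self.half(side))
        return range(self.numbering_start, self.numbering_start + n)


def position_base(site: TargetSite, side: Side | str, index: int) -> str:
    """Canonical base at a numbered half-site position.

    The left half is read outward toward the 5' end (right-to-left in the
    site string); the right half outward toward the 3' end.
    """
    side = Side(side)
    half = site.half(side)
    offset = index - site.numbering_start
    if not 0 <= offset < len(half):
        raise CoordinateError(
            f"{site.name}/{side.value}: position {index} outside "
            f"{site.numbering_start}..{site.numbering_start + len(half) - 1}"
        )
    if side is Side.LEFT:
        return half[len(half) - 1 - offset]
    return half[offset]


def percent_divergence(a: TargetSite, b: TargetSite, include_core: bool = True) -> float:
    """Fraction of positions at which two sites differ (gap-free).

    Symmetric in its arguments; with ``include_core=False`` only the
    half-sites are compared.
    """
    if (
        len(a.left_half) != len(b.left_half)
        or len(a.core) != len(b.core)
        or len(a.right_half) != len(b.right_half)
    ):
        raise IncompatibleSitesError(
            f"{a.name} and {b.name} have different segment lengths"
        )
    if include_core:
        sa, sb = a.sequence, b.sequence
    else:
        sa = a.left_half + a.right_half
        sb = b.left_half + b.right_half
    mismatches = sum(x != y for x, y in zip(sa, sb))
    return mismatches / len(sa)


def invert_core(site: TargetSite) -> TargetSite:
    """Site with the core reverse-complemented, half-sites unchanged."""
    return dataclasses.replace(site, core=revcomp(site.core))


@dataclass(frozen=True)
class HalfSiteSelector:
    """Selects one half-site of a site and renders position labels."""

    site: TargetSite
    side: Side
    label_style: str = "plain"  # "plain" or "primed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", Side(self.side))
        if self.label_style not in ("plain", "primed"):
            raise ValueError(f"unknown label style {self.label_style!r}")

    @property
    def sequence(self) -> str:
        return self.site.half(self.side)

    def label(self, index: int) -> str:
        if index not in self.site.positions(self.side):
            raise CoordinateError(
                f"{self.site.name}/{self.side.value}: no position {index}"
            )
        suffix = PRIME if self.label_style == "primed" else ""
        return f"{index}{suffix}"

    def labels_sequence_order(self) -> list[str]:
        """Labels for each base of the half-site string, 5' to 3'."""
        positions = list(self.site.positions(self.side))
        if self.side is Side.LEFT:
            positions = positions[::-1]
        return [self.label(p) for p in positions]


def positions_sequence_order(site: TargetSite, side: Side | str) -> list[int]:
    """Numbered positions for each base of the half-site string, 5' to 3'."""
    side = Side(side)
    positions = list(site.positions(side))
    return positions[::-1] if side is Side.LEFT else positions


# Bundled sites.  Cre-family sites: 13-bp inverted-repeat half-sites
# flanking an asymmetric 8-bp core, numbered 5..17 outward.
LOXP = TargetSite("loxP", "ATAACTTCGTATA", "ATGTATGC", "TATACGAAGTTAT")
LOXLTR = TargetSite("loxLTR", "ACAACATCCTATT", "ACACCCTA", "TATGCCAACATGG")
LOXBTR = TargetSite("loxBTR", "AACCCACTGCTTA", "AGCCTCAA", "TAAAGCTTGCCTT")

BUILTIN_SITES: dict[str, TargetSite] = {s.name: s for s in (LOXP, LOXLTR, LOXBTR)}


def load_sites(source: str | Path) -> dict[str, TargetSite]:
    """Load site definitions from a YAML file or YAML text.

    Expected layout::

        loxP:
          left_half: ATAACTTCGTATA
          core: ATGTATGC
          right_half: TATACGAAGTTAT
          numbering_start: 5   # optional
    """
    if isinstance(source, Path) or "\n" not in str(source) and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("site config must be a mapping of name -> fields")
    sites = {}
    for name, fields in data.items():
        sites[name] = TargetSite(
            name=name,
            left_half=fields["left_half"],
            core=fields["core"],
            right_half=fields["right_half"],
            numbering_start=fields.get("numbering_start"),
        )
    return sites


def resolve_site(spec: str | dict | TargetSite) -> TargetSite:
    """Resolve a site from a builtin name, a field mapping, or pass through."""
    if isinstance(spec, TargetSite):
        return spec
    if isinstance(spec, str):
        try:
            return BUILTIN_SITES[spec]
        except KeyError:
            raise KeyError(
                f"unknown builtin site {spec!r}; available: {sorted(BUILTIN_SITES)}"
            ) from None
    return TargetSite(
        name=spec.get("name", "site"),
        left_half=spec["left_half"],
        core=spec["core"],
        right_half=spec["right_half"],
        numbering_start=spec.get("numbering_start"),
    )
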