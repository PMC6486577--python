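"""FASTQ parsing, core-anchored extraction, and the mismatch filter.

Reads are anchored by an exact match to the constant core sequence (on the
forward strand first, then the reverse complement when enabled); the
randomized half-site and the UMI are sliced at fixed offsets relative to
the core, with no gaps permitted anywhere.  Reads whose half-site carries
more than ``max_mismatches`` substitutions relative to the canonical
sequence are filtered out, which also discards indel-bearing reads via
gap-free mismatch inflation.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .targets import Side, TargetSite, revcomp

DEFAULT_MAX_MISMATCHES = 6


class AlignmentError(ValueError):
    pass


class Status(str, Enum):
    PASS = "pass"
    FAIL_NO_CORE = "fail_no_core"
    FAIL_TOO_MANY_MISMATCHES = "fail_too_many_mismatches"
    FAIL_MALFORMED = "fail_malformed"


@dataclass(frozen=True)
class ReadLayout:
    """Expected read structure: flank + UMI + left + core + right + flank."""

    site: TargetSite
    randomized_side: Side = Side.LEFT
    umi_length: int = 10
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "randomized_side", Side(self.randomized_side))

    @property
    def canonical_half(self) -> str:
        return self.site.half(self.randomized_side)


@dataclass
class ExtractedRead:
    status: Status
    variant: str | None = None
    umi: str | None = None
    mismatches: int | None = None
    strand: str = "+"


def hamming(variant: str, reference: str) -> int:
    """Gap-free mismatch count between equal-length strings."""
    if len(variant) != len(reference):
        raise AlignmentError(
            f"length mismatch: {len(variant)} vs {len(reference)}"
        )
    return sum(a != b for a, b in zip(variant, reference))


def extract(read: str, layout: ReadLayout) -> ExtractedRead:
    """Locate the core and slice out the randomized half-site and UMI.

    The core must match exactly; if it occurs more than once the leftmost
    occurrence on the matched strand is used.
    """
    site = layout.site
    core = site.core
    seq = read.upper()
    strand = "+"
    k = seq.find(core)
    if k < 0 and layout.search_both_strands:
        seq = revcomp(seq)
        k = seq.find(core)
        strand = "-"
    if k < 0:
        return ExtractedRead(Status.FAIL_NO_CORE, strand="+")
    L_left = len(site.left_half)
    L_right = len(site.right_half)
    left_start = k - L_left
    umi_start = left_start - layout.umi_length
    right_end = k + len(core) + L_right
    if umi_start < 0 or right_end > len(seq):
        return ExtractedRead(Status.FAIL_MALFORMED, strand=strand)
    left = seq[left_start:k]
    right = seq[k + len(core):right_end]
    umi = seq[umi_start:left_start]
    variant = left if layout.randomized_side is Side.LEFT else right
    if set(variant) - set("ACGT") or set(umi) - set("ACGT"):
        return ExtractedRead(Status.FAIL_MALFORMED, strand=strand)
    mm = hamming(variant, layout.canonical_half)
    return ExtractedRead(Status.PASS, variant=variant, umi=umi, mismatches=mm,
                         strand=strand)


@dataclass
class FilterReport:
    n_total: int = 0
    n_kept: int = 0
    fail_no_core: int = 0
    fail_too_many_mismatches: int = 0
    fail_malformed: int = 0
    multi_core: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_total": self.n_total,
                "n_kept": self.n_kept,
                "fail_no_core": self.fail_no_core,
                "fail_too_many_mismatches": self.fail_too_many_mismatches,
                "fail_malformed": self.fail_malformed,
                "multi_core": self.multi_core,
                "warnings": self.warnings,
            },
            indent=2,
        )


def filter_reads(
    reads: Iterable[ExtractedRead],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[ExtractedRead], FilterReport]:
    """Keep status-pass reads with at most ``max_mismatches`` mismatches."""
    report = FilterReport()
    kept: list[ExtractedRead] = []
    for r in reads:
        report.n_total += 1
        if r.status is Status.FAIL_NO_CORE:
            report.fail_no_core += 1
        elif r.status is Status.FAIL_MALFORMED:
            report.fail_malformed += 1
        elif r.mismatches is not None and r.mismatches > max_mismatches:
            r.status = Status.FAIL_TOO_MANY_MISMATCHES
            report.fail_too_many_mismatches += 1
        else:
            kept.append(r)
            report.n_kept += 1
    if report.n_total == 0:
        report.warnings.append("no reads in input")
    return kept, report


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a plain or gzipped 4-line FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq


def extract_fastq(
    path: str | Path,
    layout: ReadLayout,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[ExtractedRead], FilterReport]:
    """Parse, extract, and filter a FASTQ file in one pass."""
    core = layout.site.core
    extracted = []
    multi = 0
    for _rid, seq in read_fastq(path):
        s = seq.upper()
        if s.count(core) + revcomp(s).count(core) > 1:
            multi += 1
        extracted.append(extract(s, layout))
    kept, report = filter_reads(extracted, max_mismatches)
    report.multi_core = multi
    return kept, report
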