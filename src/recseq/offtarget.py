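"""Degenerate motif construction and genome scanning for pseudosites.

A specificity motif keeps the canonical target base at every full-site
position whose aggregate enrichment exceeds a threshold (strictly), masks
everything else — including the whole core — with N, and trims
uninformative all-N runs at the outer edges.  The scanner tests every
window of motif length on both strands of a FASTA genome; N matches any
of A/C/G/T, genome ambiguity codes match nothing.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .enrich import FullSiteProfile
from .targets import Side, TargetSite, revcomp

DEFAULT_THRESHOLD = 2.0


class EmptyMotifError(ValueError):
    pass


class FrameError(ValueError):
    pass


@dataclass(frozen=True)
class SpecificityMotif:
    """Degenerate search pattern derived from a full-site profile."""

    site: TargetSite
    pattern_full: str  # untrimmed: one symbol per full-site position
    pattern: str  # outer all-N runs trimmed
    left_trim: int
    right_trim: int
    threshold: float
    labels: list[str]  # label of each untrimmed position ('' for core)

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def n_specified(self) -> int:
        return sum(1 for c in self.pattern if c != "N")

    @property
    def labelled(self) -> str:
        """Printed form: base+position for specified cells, N elsewhere."""
        out = []
        for sym, label in zip(self.pattern_full, self.labels):
            if sym == "N":
                out.append("N")
            else:
                out.append(f"{sym}{label}")
        return "".join(out[self.left_trim: len(out) - self.right_trim or None])


@dataclass(frozen=True)
class PseudositeHit:
    """A genomic window matching a specificity motif."""

    sequence_name: str
    start: int  # 0-based, half-open, forward strand, trimmed-motif frame
    end: int
    strand: str  # '+' or '-'
    matched: str  # motif-oriented sequence of the trimmed window
    site_frame: str | None  # motif-oriented untrimmed full-site window
    noncore_mismatches: int | None


def build_motif(
    profile: FullSiteProfile, threshold: float = DEFAULT_THRESHOLD
) -> SpecificityMotif:
    """Motif from positions with aggregate enrichment strictly above threshold."""
    site = profile.site
    half_syms = [
        c if r > threshold else "N" for c, r in zip(profile.canonical, profile.r)
    ]
    n_left = sum(1 for s in profile.sides if s is Side.LEFT)
    core_n = "N" * len(site.core)
    full = "".join(half_syms[:n_left]) + core_n + "".join(half_syms[n_left:])
    labels = profile.labels[:n_left] + [""] * len(site.core) + profile.labels[n_left:]
    stripped = full.strip("N")
    if not stripped:
        raise EmptyMotifError(
            f"no position exceeds enrichment threshold {threshold}"
        )
    left_trim = len(full) - len(full.lstrip("N"))
    right_trim = len(full) - len(full.rstrip("N"))
    # trim only positions outside the outermost specified half-site cells
    return SpecificityMotif(
        site=site,
        pattern_full=full,
        pattern=stripped,
        left_trim=left_trim,
        right_trim=right_trim,
        threshold=threshold,
        labels=labels,
    )


def _motif_regex(pattern: str) -> re.Pattern:
    parts = ["[ACGT]" if c == "N" else c for c in pattern]
    return re.compile(f"(?=({''.join(parts)}))")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, uppercase sequence) from plain or gzipped FASTA."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq).upper()


def _frame_window(seq: str, start: int, end: int, strand: str, motif: SpecificityMotif) -> str | None:
    """Untrimmed full-site window around a hit, motif-oriented."""
    if strand == "+":
        s, e = start - motif.left_trim, end + motif.right_trim
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = start - motif.right_trim, end + motif.left_trim
    if s < 0 or e > len(seq):
        return None
    return revcomp(seq[s:e])


def noncore_mismatches(oriented_site_frame: str, cognate: TargetSite) -> int:
    """Hamming distance to the cognate full site, core positions excluded."""
    if len(oriented_site_frame) != len(cognate):
        raise FrameError(
            f"frame length {len(oriented_site_frame)} != site length {len(cognate)}"
        )
    n_left = len(cognate.left_half)
    n_core = len(cognate.core)
    mm = 0
    for i, (a, b) in enumerate(zip(oriented_site_frame, cognate.sequence)):
        if n_left <= i < n_left + n_core:
            continue
        if a != b:
            mm += 1
    return mm


def scan_sequence(
    motif: SpecificityMotif, name: str, seq: str
) -> list[PseudositeHit]:
    """All (overlapping) matches of the motif on both strands of one sequence."""
    seq = seq.upper()
    m = len(motif.pattern)
    hits: list[PseudositeHit] = []
    for strand, pattern in (("+", motif.pattern), ("-", revcomp(motif.pattern))):
        regex = _motif_regex(pattern)
        for match in regex.finditer(seq):
            start = match.start()
            end = start + m
            window = seq[start:end]
            oriented = window if strand == "+" else revcomp(window)
            frame = _frame_window(seq, start, end, strand, motif)
            mm = noncore_mismatches(frame, motif.site) if frame is not None else None
            hits.append(
                PseudositeHit(name, start, end, strand, oriented, frame, mm)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan(motif: SpecificityMotif, genome: str | Path | Iterable[tuple[str, str]]) -> list[PseudositeHit]:
    """Scan a FASTA file (or (name, seq) pairs) for pseudosite hits."""
    if not motif.pattern or set(motif.pattern) == {"N"}:
        raise EmptyMotifError("cannot scan with an unconstrained motif")
    if isinstance(genome, (str, Path)):
        records = read_fasta(genome)
    else:
        records = genome
    hits: list[PseudositeHit] = []
    empty = True
    for name, seq in records:
        empty = False
        hits.extend(scan_sequence(motif, name, seq))
    if empty:
        raise IOError("genome FASTA contained no sequences")
    return hits


def hits_to_bed(hits: Iterable[PseudositeHit], motif_id: str = "motif") -> str:
    """6-column BED: name = motif id, score = non-core mismatch count."""
    lines = []
    for h in hits:
        score = h.noncore_mismatches if h.noncore_mismatches is not None else "."
        lines.append(
            f"{h.sequence_name}\t{h.start}\t{h.end}\t{motif_id}\t{score}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: Iterable[PseudositeHit]) -> str:
    """Annotated report with 1-based inclusive coordinates."""
    header = "sequence\tstart_1based\tend_1based\tstrand\tmatched\tnoncore_mismatches\n"
    rows = [
        f"{h.sequence_name}\t{h.start + 1}\t{h.end}\t{h.strand}\t{h.matched}\t"
        f"{'' if h.noncore_mismatches is None else h.noncore_mismatches}"
        for h in hits
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")
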