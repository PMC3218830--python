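"""Genomic intervals, BED I/O and interval algebra.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; 1-based positions appear only at VCF / samtools-depth boundaries.

The algebra here is deliberately self-contained: subregion construction
depends on an exact "bookended intervals merge" semantics (``[0,5)`` and
``[5,10)`` become ``[0,10)``) so that subregion spans are well defined, and
the sweep-line implementations below guarantee it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "SubregionSet",
    "SUBREGION_LABELS",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "subtract",
    "intersect",
    "build_specific_regions",
    "filter_by_score",
    "total_span",
]

#: Canonical functional classes used throughout the pipeline.
SUBREGION_LABELS = (
    "CCDS",
    "refseq_vega_specific",
    "conserved_UTR",
    "nonconserved_UTR",
    "regulome",
    "predicted_exons",
    "miRNA",
    "intron",
    "whole_genome",
)


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``score`` carries whatever numeric annotation the source track provides
    (phastCons LOD score, ChIP-seq enrichment, ...); ``name`` is a free-form
    label.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def total_span(intervals: Iterable[GenomicInterval]) -> int:
    """Sum of interval lengths (meaningful on merged sets)."""
    return sum(iv.length for iv in intervals)


@dataclass
class SubregionSet:
    """A labelled, merged, sorted collection of intervals.

    Construction merges overlapping and bookended intervals, so ``span``
    equals the number of distinct bases covered. Subregion classes may
    overlap *each other* (a base can be both CCDS and conserved UTR); each
    set is summarised independently downstream.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def span(self) -> int:
        return total_span(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED4/BED5 file into intervals.

    Column 4 (name) and column 5 (score) are kept when present. Lines
    starting with ``#``, ``track`` or ``browser`` and blank lines are
    skipped. Malformed lines raise :class:`BedParseError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates: {exc}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as sorted BED (0-based half-open).

    Emits BED3 when no interval carries a name or score, BED4 when names
    only, BED5 when any score is present (missing names become ``.``).
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    any_name = any(iv.name is not None for iv in ivs)
    any_score = any(iv.score is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if any_name or any_score:
                cols.append(iv.name if iv.name is not None else ".")
            if any_score:
                cols.append(format(iv.score, "g") if iv.score is not None else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Interval algebra (sweep-line; bookended intervals merge)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and touching intervals into a sorted, disjoint set.

    Names and scores are dropped on merged output, as the result represents
    a base set rather than annotated features.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in ivs:
        if iv.chrom != cur_chrom or iv.start > cur_end:
            if cur_chrom is not None:
                merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-set difference a \\ b. Inputs are merged internally."""
    a = merge_intervals(a)
    b_map = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a:
        cursor = iv.start
        for cut in b_map.get(iv.chrom, ()):
            if cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-set intersection. Inputs are merged internally."""
    a = merge_intervals(a)
    b_map = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a:
        for other in b_map.get(iv.chrom, ()):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return out


# ---------------------------------------------------------------------------
# Rule-based subregion construction


def build_specific_regions(
    refseq_vega: Sequence[GenomicInterval],
    ccds: Sequence[GenomicInterval],
    min_len: int = 50,
) -> list[GenomicInterval]:
    """Exonic regions specific to RefSeq/Vega: subtract CCDS, drop short bits.

    Fragments shorter than ``min_len`` are discarded (length exactly
    ``min_len`` is kept — the exclusion is strictly "< min_len"): very small
    derived fragments sit at target edges where coverage is unreliable.
    """
    return [iv for iv in subtract(refseq_vega, ccds) if iv.length >= min_len]


def filter_by_score(
    intervals: Sequence[GenomicInterval],
    min_score: float | None = None,
    max_len: int | None = None,
) -> list[GenomicInterval]:
    """Select intervals by annotation score and/or length.

    ``min_score`` keeps intervals with ``score >= min_score`` (inclusive:
    conserved-UTR LOD >= 100, ChIP-seq enrichment >= 300). ``max_len`` keeps
    intervals strictly shorter than ``max_len`` (the "< 50 bp" rule for
    transcription-factor-binding-site-sized annotations). Both conditions
    apply when both are given.
    """
    if min_score is None and max_len is None:
        return list(intervals)
    out: list[GenomicInterval] = []
    for iv in intervals:
        if min_score is not None:
            if iv.score is None:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} has no score "
                    "but a score filter was requested"
                )
            if iv.score < min_score:
                continue
        if max_len is not None and iv.length >= max_len:
            continue
        out.append(iv)
    return out
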