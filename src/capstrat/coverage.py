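"""Coverage stratification across genomic subregions.

Implements the "capture-ability" framework: each subregion's pooled mean
depth is expressed relative to the CCDS baseline, and the capture/WGS ratio
of those relative coverages separates hybridisation-capture effects from
sequencing-platform bias (a value of 1 means capture behaves exactly like
whole-genome sequencing for that subregion).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ReferenceGenome, gc_content
from .regions import GenomicInterval, SubregionSet

__all__ = [
    "DepthTrack",
    "CoverageSummary",
    "RelativeCoverage",
    "EnrichmentRatio",
    "DepthParseError",
    "read_depth_track",
    "write_depth_track",
    "summarize_coverage",
    "capture_ability",
    "relative_enrichment",
    "gc_binned_coverage",
    "rank_sum_test",
    "kmer_uniqueness",
]


class DepthParseError(ValueError):
    """Raised for malformed depth-track lines; names the line number."""


@dataclass
class DepthTrack:
    """Per-base read depth over the reference for one sequencing mode.

    ``depths`` maps chromosome name to a non-negative integer array covering
    the whole chromosome; positions never listed in the source file are 0.
    """

    depths: dict[str, np.ndarray]
    mode: str = "capture"

    def __post_init__(self) -> None:
        self.depths = {c: np.asarray(a, dtype=np.int64) for c, a in self.depths.items()}
        for chrom, arr in self.depths.items():
            if arr.size and int(arr.min()) < 0:
                raise ValueError(f"negative depth on {chrom}")

    def pooled(self, intervals: Iterable[GenomicInterval]) -> np.ndarray:
        """Concatenated per-base depths over the given intervals."""
        parts = []
        for iv in intervals:
            arr = self.depths.get(iv.chrom)
            if arr is None:
                raise KeyError(f"chromosome {iv.chrom!r} not in depth track")
            if iv.end > len(arr):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds track "
                    f"length {len(arr)}"
                )
            parts.append(arr[iv.start : iv.end])
        if not parts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(parts)


@dataclass(frozen=True)
class CoverageSummary:
    """Pooled per-base depth summary for one subregion."""

    label: str
    bases: int
    mean_depth: float
    median_depth: float
    frac_ge_10x: float


@dataclass(frozen=True)
class RelativeCoverage:
    """Subregion mean depth as a proportion of the CCDS mean ("capture-ability")."""

    label: str
    ratio: float


@dataclass(frozen=True)
class EnrichmentRatio:
    """Capture relative coverage over WGS relative coverage.

    Values > 1 indicate the capture step enriches the subregion beyond what
    the sequencing platform alone would give; < 1 indicates depletion.
    """

    label: str
    value: float


# ---------------------------------------------------------------------------
# Depth track I/O


def read_depth_track(
    path: str | Path,
    dialect: str = "samtools-depth",
    mode: str = "capture",
    chrom_sizes: dict[str, int] | None = None,
) -> DepthTrack:
    """Read per-base depth from a samtools-depth TSV or a bedGraph.

    samtools-depth lines are ``chrom <tab> pos(1-based) <tab> depth``;
    bedGraph lines are ``chrom start end depth`` (0-based half-open).
    Positions absent from the file get depth 0. Without ``chrom_sizes`` each
    chromosome array extends to the last listed position.
    """
    if dialect not in ("samtools-depth", "bedgraph"):
        raise ValueError(f"unknown depth dialect {dialect!r}")
    records: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "samtools-depth":
                    if len(fields) < 3:
                        raise ValueError("expected 3 columns")
                    chrom, pos, depth = fields[0], int(fields[1]), int(fields[2])
                    start, end = pos - 1, pos
                else:
                    if len(fields) < 4:
                        raise ValueError("expected 4 columns")
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    depth = int(float(fields[3]))
                if depth < 0:
                    raise ValueError(f"negative depth {depth}")
                if start < 0 or end <= start:
                    raise ValueError(f"bad coordinates {start}-{end}")
            except ValueError as exc:
                raise DepthParseError(f"{path}:{lineno}: {exc}") from None
            records.setdefault(chrom, []).append((start, end, depth))

    sizes = dict(chrom_sizes or {})
    for chrom, recs in records.items():
        needed = max(end for _, end, _ in recs)
        sizes[chrom] = max(sizes.get(chrom, 0), needed)
    depths = {chrom: np.zeros(size, dtype=np.int64) for chrom, size in sizes.items()}
    for chrom, recs in records.items():
        arr = depths[chrom]
        for start, end, depth in recs:
            arr[start:end] = depth
    return DepthTrack(depths=depths, mode=mode)


def write_depth_track(
    track: DepthTrack, path: str | Path, dialect: str = "bedgraph"
) -> None:
    """Write a depth track; bedGraph is run-length compressed, the
    samtools-depth dialect lists only non-zero positions."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if dialect == "bedgraph":
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = int(arr[s])
                    if v:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
            elif dialect == "samtools-depth":
                for pos in np.flatnonzero(arr):
                    fh.write(f"{chrom}\t{pos + 1}\t{int(arr[pos])}\n")
            else:
                raise ValueError(f"unknown depth dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Summaries and ratios


def summarize_coverage(track: DepthTrack, subregion: SubregionSet) -> CoverageSummary:
    """Pooled per-base mean/median depth and fraction of bases at >= 10x.

    Pooling across all bases (rather than averaging per-target means)
    matches how a handful of extremely deep targets can skew a subregion's
    mean while leaving the median representative.
    """
    depths = track.pooled(subregion.intervals)
    if depths.size == 0:
        raise ValueError(f"subregion {subregion.label!r} contains no bases")
    return CoverageSummary(
        label=subregion.label,
        bases=int(depths.size),
        mean_depth=float(depths.mean()),
        median_depth=float(np.median(depths)),
        frac_ge_10x=float(np.mean(depths >= 10)),
    )


def capture_ability(
    summary: CoverageSummary, ccds_summary: CoverageSummary
) -> RelativeCoverage:
    """Mean depth of a subregion as a proportion of the CCDS mean depth."""
    if ccds_summary.mean_depth <= 0:
        raise ValueError("CCDS mean depth is zero; relative coverage undefined")
    return RelativeCoverage(
        label=summary.label, ratio=summary.mean_depth / ccds_summary.mean_depth
    )


def relative_enrichment(
    capture_rel: RelativeCoverage, wgs_rel: RelativeCoverage
) -> EnrichmentRatio:
    """Capture-ability divided by the WGS relative coverage of the same subregion."""
    if wgs_rel.ratio <= 0:
        raise ValueError("WGS relative coverage is zero; enrichment undefined")
    return EnrichmentRatio(label=capture_rel.label, value=capture_rel.ratio / wgs_rel.ratio)


def gc_binned_coverage(
    track: DepthTrack,
    targets: Sequence[GenomicInterval],
    genome: ReferenceGenome,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Mean of per-target mean depths, binned by target GC content.

    Returns a DataFrame with columns ``gc_bin`` (left edge), ``mean_depth``
    and ``n_targets``, one row per occupied bin.
    """
    rows = []
    for iv in targets:
        gc = gc_content(genome, iv)
        if math.isnan(gc):
            continue
        depth = float(track.pooled([iv]).mean())
        bin_left = min(math.floor(gc / bin_width), int(round(1 / bin_width)) - 1)
        rows.append((bin_left * bin_width, depth))
    frame = pd.DataFrame(rows, columns=["gc_bin", "depth"])
    grouped = (
        frame.groupby("gc_bin")["depth"]
        .agg(mean_depth="mean", n_targets="size")
        .reset_index()
    )
    grouped["n_targets"] = grouped["n_targets"].astype(int)
    return grouped


# ---------------------------------------------------------------------------
# Statistics


def rank_sum_test(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test; returns ``(U, two-sided p)``.

    ``U`` is the statistic for ``x``. For total sample size <= 20 the
    permutation null is enumerated exactly (correct under ties); larger
    samples use the tie-corrected normal approximation. The exact two-sided
    p-value is the probability, over all equally likely assignments of the
    pooled values, of a U at least as far from its null mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= 20:
        mu = n1 * n2 / 2
        dev = abs(u_obs - mu)
        total = 0
        extreme = 0
        base = n1 * (n1 + 1) / 2
        rank_list = ranks.tolist()
        for combo in itertools.combinations(rank_list, n1):
            u = sum(combo) - base
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# Mappability proxy

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit-packed k-mers and a validity mask for one sequence.

    Returns arrays of length ``len(arr) - k + 1``; a k-mer containing any
    non-ACGT base is flagged invalid.
    """
    codes = _CODE[arr]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        bad = window == 255
        invalid |= bad
        w = np.where(bad, 0, window).astype(np.uint64)
        fwd |= w << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - w) << np.uint64(2 * j)
    canonical = np.minimum(fwd, rev)
    return canonical, ~invalid


def kmer_uniqueness(
    genome: ReferenceGenome,
    intervals: Sequence[GenomicInterval],
    k: int = 21,
) -> float:
    """Fraction of interval k-mers occurring exactly once genome-wide.

    A k-mer and its reverse complement are counted as the same sequence.
    This is a stand-in for read-simulation mappability experiments: a region
    whose k-mers are unique in the genome maps unambiguously at the k scale.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    for iv in intervals:
        if iv.length < k:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} shorter than k={k}"
            )
    genome_kmers = []
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in genome.sequences.items():
        km, valid = _kmer_codes(arr, k)
        per_chrom[chrom] = (km, valid)
        genome_kmers.append(km[valid])
    allk = np.concatenate(genome_kmers) if genome_kmers else np.zeros(0, dtype=np.uint64)
    uniq, counts = np.unique(allk, return_counts=True)

    n_total = 0
    n_unique = 0
    for iv in intervals:
        km, valid = per_chrom[iv.chrom]
        hi = min(iv.end, len(genome[iv.chrom]) - k + 1)
        sel = slice(iv.start, hi)
        kms = km[sel][valid[sel]]
        if kms.size == 0:
            continue
        idx = np.searchsorted(uniq, kms)
        n_total += kms.size
        n_unique += int(np.count_nonzero(counts[idx] == 1))
    if n_total == 0:
        raise ValueError("no valid k-mers in the given intervals")
    return n_unique / n_total
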