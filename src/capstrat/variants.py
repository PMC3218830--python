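"""Variant filtering, per-subregion density, mutation spectrum and MAF classes.

Variant sites pass a quality filter (phred site quality >= 30), an allele
support filter (alt reads must be at least 15% of covering reads) and an
optional low-mapping-quality filter; densities are computed per *callable*
base (depth >= 10x within the subregion) and normalised to the CCDS
subregion, which is the baseline for all relative statistics in this
package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

import pysam

from .coverage import DepthTrack
from .regions import GenomicInterval, SubregionSet

__all__ = [
    "VariantCall",
    "FilterTally",
    "DensitySummary",
    "SpectrumSummary",
    "MafSummary",
    "SUBSTITUTION_TYPES",
    "TRANSITIONS",
    "read_vcf",
    "write_vcf",
    "apply_variant_filters",
    "callable_bases",
    "variant_density",
    "relative_density",
    "restrict_calls",
    "mutation_spectrum",
    "maf_classify",
    "conservation_distribution",
    "rate_ratio_test",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: The 12 directed single-nucleotide substitution types, no strand collapse.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in _BASES for a in _BASES if a != r
)

#: Transitions are purine<->purine and pyrimidine<->pyrimidine changes.
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide variant site.

    ``pos`` is 0-based internally; VCF I/O converts to/from 1-based.
    ``low_mapq_fraction`` is the fraction of covering reads with mapping
    quality < 11; ``panel_maf`` is the allele frequency in a reference
    population panel (``None`` when the site was never looked up).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: float
    depth: int
    alt_depth: int
    low_mapq_fraction: float = 0.0
    panel_maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError("require 0 <= alt_depth <= depth")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def alt_fraction(self) -> float:
        return self.alt_depth / self.depth if self.depth > 0 else math.nan


@dataclass
class FilterTally:
    """Per-rule removal counts; rules are applied in a fixed order
    (quality, zero depth, alt fraction, low-MAPQ fraction) and a call is
    attributed to the first rule it fails."""

    input: int = 0
    retained: int = 0
    removed_quality: int = 0
    removed_zero_depth: int = 0
    removed_alt_fraction: int = 0
    removed_low_mapq: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_quality
            + self.removed_zero_depth
            + self.removed_alt_fraction
            + self.removed_low_mapq
        )


@dataclass(frozen=True)
class DensitySummary:
    """Variant density over callable bases of one subregion.

    ``one_in_x`` is callable bp per retained variant (NaN when no variant
    was retained); ``relative_density`` is density / CCDS density and is NaN
    until normalised.
    """

    label: str
    retained: int
    callable_bases: int
    density: float
    one_in_x: float
    relative_density: float = math.nan


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts over the 12 directed substitution types with Ts:Tv."""

    counts: dict[str, int]
    transitions: int
    transversions: int
    ts_tv: float  # NaN when no transversions
    proportions: dict[str, float]


@dataclass(frozen=True)
class MafSummary:
    """Panel minor-allele-frequency classes for one subregion's variants.

    A variant is *private* when it is absent from the panel (missing or
    frequency 0) and *fixed* when the panel frequency is 1; everything else
    is histogrammed over the supplied bins.
    """

    label: str
    n: int
    frac_private: float
    frac_fixed: float
    bin_edges: tuple[float, ...]
    bin_fractions: tuple[float, ...]


# ---------------------------------------------------------------------------
# VCF I/O

_INFO_ALT_DEPTH = "VD"
_INFO_LOW_MAPQ = "LMQ"
_INFO_PANEL_AF = "PAF"


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write calls as uncompressed VCF 4.2, sorted, one record per site."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=capstrat\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
        )
        fh.write(
            f'##INFO=<ID={_INFO_ALT_DEPTH},Number=1,Type=Integer,'
            'Description="Reads supporting the alternate allele">\n'
        )
        fh.write(
            f'##INFO=<ID={_INFO_LOW_MAPQ},Number=1,Type=Float,'
            'Description="Fraction of covering reads with mapping quality < 11">\n'
        )
        fh.write(
            f'##INFO=<ID={_INFO_PANEL_AF},Number=1,Type=Float,'
            'Description="Allele frequency in the reference population panel">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"DP={c.depth};{_INFO_ALT_DEPTH}={c.alt_depth};"
                f"{_INFO_LOW_MAPQ}={c.low_mapq_fraction:.6g}"
            )
            if c.panel_maf is not None:
                info += f";{_INFO_PANEL_AF}={c.panel_maf:.6g}"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t"
                f"{c.quality:.6g}\t.\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read SNV calls from a VCF 4.x file.

    Requires INFO keys ``DP``, ``VD`` (alt-allele read depth) and ``LMQ``
    (low-mapping-quality read fraction); ``PAF`` (panel allele frequency) is
    optional. Non-SNV records (indels, multi-allelic, symbolic) are skipped
    and the skipped count is logged.
    """
    calls: list[VariantCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for key in ("DP", _INFO_ALT_DEPTH, _INFO_LOW_MAPQ):
            if key not in vcf.header.info:
                raise ValueError(f"VCF {path} is missing required INFO key {key!r}")
        has_paf = _INFO_PANEL_AF in vcf.header.info
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                skipped += 1
                continue
            info = rec.info
            paf = info.get(_INFO_PANEL_AF) if has_paf else None
            # htslib stores INFO floats as float32; restore the 6-significant-
            # digit precision the writer emits
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref.upper(),
                    alt=alts[0].upper(),
                    quality=float(rec.qual if rec.qual is not None else 0.0),
                    depth=int(info["DP"]),
                    alt_depth=int(info[_INFO_ALT_DEPTH]),
                    low_mapq_fraction=float(f"{float(info[_INFO_LOW_MAPQ]):.6g}"),
                    panel_maf=float(f"{float(paf):.6g}") if paf is not None else None,
                )
            )
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV record(s)", path, skipped)
    return calls


# ---------------------------------------------------------------------------
# Filtering and callable-base accounting


def apply_variant_filters(
    calls: Sequence[VariantCall],
    min_qual: float = 30.0,
    min_alt_fraction: float = 0.15,
    max_low_mapq_fraction: float = 1.0,
) -> tuple[list[VariantCall], FilterTally]:
    """Apply site-level variant filters; thresholds are inclusive.

    A call is retained iff quality >= ``min_qual`` AND alt reads make up at
    least ``min_alt_fraction`` of covering reads AND the low-MAPQ read
    fraction is <= ``max_low_mapq_fraction``. The MAPQ filter defaults to
    off (1.0) because low-mapping-quality reads are normally removed
    upstream before depth and allele counts are formed; it is exposed for
    sensitivity analysis.
    """
    retained: list[VariantCall] = []
    tally = FilterTally(input=len(calls))
    for c in calls:
        if c.quality < min_qual:
            tally.removed_quality += 1
        elif c.depth == 0:
            tally.removed_zero_depth += 1
        elif c.alt_fraction < min_alt_fraction:
            tally.removed_alt_fraction += 1
        elif c.low_mapq_fraction > max_low_mapq_fraction:
            tally.removed_low_mapq += 1
        else:
            retained.append(c)
    tally.retained = len(retained)
    return retained, tally


def callable_bases(
    track: DepthTrack, subregion: SubregionSet, min_depth: int = 10
) -> int:
    """Number of subregion bases covered at >= ``min_depth`` reads."""
    depths = track.pooled(subregion.intervals)
    return int(np.count_nonzero(depths >= min_depth))


def variant_density(
    calls: Sequence[VariantCall],
    callable_bp: int,
    label: str,
) -> DensitySummary:
    """Variants per callable bp and the 'one-in-X' bp-per-variant statistic.

    ``calls`` must already be restricted to the subregion's callable bases;
    a variant sitting at an under-covered position belongs in neither the
    numerator nor the denominator.
    """
    if callable_bp <= 0:
        raise ValueError(f"subregion {label!r} has no callable bases")
    n = len(calls)
    density = n / callable_bp
    one_in_x = callable_bp / n if n > 0 else math.nan
    return DensitySummary(
        label=label,
        retained=n,
        callable_bases=callable_bp,
        density=density,
        one_in_x=one_in_x,
    )


def relative_density(sub: DensitySummary, ccds: DensitySummary) -> DensitySummary:
    """Return ``sub`` with its density expressed relative to the CCDS density."""
    if ccds.density <= 0:
        raise ValueError("CCDS density is zero; relative density undefined")
    return DensitySummary(
        label=sub.label,
        retained=sub.retained,
        callable_bases=sub.callable_bases,
        density=sub.density,
        one_in_x=sub.one_in_x,
        relative_density=sub.density / ccds.density,
    )


def restrict_calls(
    calls: Iterable[VariantCall],
    subregion: SubregionSet,
    track: DepthTrack | None = None,
    min_depth: int = 10,
) -> list[VariantCall]:
    """Calls within a subregion, optionally only at callable (>=10x) positions."""
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subregion.intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in per_chrom.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in per_chrom.items()}
    out: list[VariantCall] = []
    for c in calls:
        if c.chrom not in starts:
            continue
        i = int(np.searchsorted(starts[c.chrom], c.pos, side="right")) - 1
        if i < 0 or c.pos >= ends[c.chrom][i]:
            continue
        if track is not None and track.depths[c.chrom][c.pos] < min_depth:
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Spectrum, MAF, conservation, rate comparison


def mutation_spectrum(calls: Sequence[VariantCall]) -> SpectrumSummary:
    """Count the 12 directed substitution types and form the Ts:Tv ratio.

    Strands are *not* collapsed: C>T and G>A are reported separately, since
    their relative weights differ between CpG-rich regulatory sequence and
    coding sequence. Ts:Tv is NaN when there are no transversions.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for c in calls:
        counts[c.substitution] += 1
    ts = sum(counts[t] for t in SUBSTITUTION_TYPES if t in TRANSITIONS)
    tv = sum(counts[t] for t in SUBSTITUTION_TYPES if t not in TRANSITIONS)
    total = ts + tv
    proportions = {
        t: (counts[t] / total if total else 0.0) for t in SUBSTITUTION_TYPES
    }
    return SpectrumSummary(
        counts=counts,
        transitions=ts,
        transversions=tv,
        ts_tv=(ts / tv) if tv > 0 else math.nan,
        proportions=proportions,
    )


def maf_classify(
    calls: Sequence[VariantCall],
    bin_edges: Sequence[float] = (0.01, 0.05, 0.10, 0.25, 0.50),
    label: str = "",
) -> MafSummary:
    """Classify calls by panel minor-allele frequency.

    Private = panel frequency missing or 0; fixed = panel frequency 1. The
    remainder is histogrammed over ``(0,1)`` using the given interior bin
    edges (a value falls in the bin whose left edge it reaches). Fractions
    over {private, fixed, bins} sum to 1.
    """
    edges = list(bin_edges)
    if any(not (0 < e < 1) for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("bin edges must be strictly increasing within (0, 1)")
    full_edges = [0.0] + edges + [1.0]
    n = len(calls)
    if n == 0:
        raise ValueError("no calls to classify")
    n_private = n_fixed = 0
    rest: list[float] = []
    for c in calls:
        maf = c.panel_maf
        if maf is not None and not (0.0 <= maf <= 1.0):
            raise ValueError(f"panel MAF {maf} outside [0, 1]")
        if maf is None or maf == 0.0:
            n_private += 1
        elif maf == 1.0:
            n_fixed += 1
        else:
            rest.append(maf)
    hist, _ = np.histogram(rest, bins=full_edges)
    return MafSummary(
        label=label,
        n=n,
        frac_private=n_private / n,
        frac_fixed=n_fixed / n,
        bin_edges=tuple(full_edges),
        bin_fractions=tuple(float(h) / n for h in hist),
    )


def conservation_distribution(
    scores: dict[str, np.ndarray],
    subregion: SubregionSet,
    bin_edges: Sequence[float],
) -> np.ndarray:
    """Per-bin proportion of subregion bases by conservation score.

    ``scores`` maps chromosome to a per-base float array with NaN at
    unscored positions. Scores beyond the outer edges are clipped into the
    first/last bin so that proportions always sum to 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    pooled = []
    for iv in subregion.intervals:
        arr = scores.get(iv.chrom)
        if arr is None:
            continue
        pooled.append(arr[iv.start : iv.end])
    if not pooled:
        raise ValueError(f"no scores available for subregion {subregion.label!r}")
    vals = np.concatenate(pooled)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"no scored bases in subregion {subregion.label!r}")
    clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
    hist, _ = np.histogram(clipped, bins=edges)
    return hist / vals.size


def rate_ratio_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exact conditional test that two Poisson per-bp rates are equal.

    Conditional on the total count ``k1 + k2``, ``k1`` is binomial with
    success probability ``n1 / (n1 + n2)`` under the null of equal rates.
    The two-sided p-value doubles the smaller tail, capped at 1 — simple and
    conservative. ``k1 + k2 == 0`` gives p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("span sizes must be positive")
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    total = k1 + k2
    if total == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    lower = stats.binom.cdf(k1, total, p0)
    upper = stats.binom.sf(k1 - 1, total, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))
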