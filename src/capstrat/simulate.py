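"""Seeded generator of synthetic capture-sequencing datasets.

Emulates the observable structure of a region-stratified capture study:

* a reference genome whose functional subregion classes carry distinct GC
  content (conserved UTRs AT-rich, coding near-balanced, regulome GC-rich);
* capture and WGS depth tracks with a unimodal GC-dependent bias,
  exacerbated under capture by an exponent on the bias curve;
* SNV calls as per-class marked Poisson processes with class-specific
  substitution spectra, site annotations and panel allele frequencies;
* a per-base conservation-score track with class-specific distributions.

All randomness flows from one master seed through named substreams (genome,
depth-capture, depth-wgs, variants, conservation), so identical config and
seed reproduce byte-identical outputs and individual components can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import DepthTrack, write_depth_track
from .genome import ReferenceGenome, windowed_gc_fraction
from .regions import GenomicInterval, SubregionSet, write_bed
from .simconfig import SimulationConfig, SubregionModel
from .variants import VariantCall, write_vcf

__all__ = [
    "SyntheticDataset",
    "substream",
    "simulate_genome",
    "simulate_depth",
    "simulate_variants",
    "simulate_conservation",
    "simulate_dataset",
    "draw_substitutions",
    "draw_panel_mafs",
    "poisson_positions",
    "write_conservation_track",
    "read_conservation_track",
]

_STREAMS = {
    "genome": 0,
    "depth-capture": 1,
    "depth-wgs": 2,
    "variants": 3,
    "conservation": 4,
}

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_BASE_CODES = np.array([_A, _C, _G, _T], dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for one named component."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


# ---------------------------------------------------------------------------
# Genome


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """n iid bases with P(G or C) = gc, G/C and A/T split evenly."""
    is_gc = rng.random(n) < gc
    pick = rng.random(n) < 0.5
    out = np.empty(n, dtype=np.uint8)
    out[is_gc & pick] = _G
    out[is_gc & ~pick] = _C
    out[~is_gc & pick] = _A
    out[~is_gc & ~pick] = _T
    return out


def _allocate_counts(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    raw = [total * w / sum(weights) for w in weights]
    counts = [int(x) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_genome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ReferenceGenome, dict[str, SubregionSet]]:
    """Draw the reference and place the subregion targets.

    Targets of each class are apportioned across chromosomes by chromosome
    length, placed without overlap (across all classes) with random gaps,
    and their sequence is redrawn at the class GC fraction over a
    background-GC genome.
    """
    config.require_valid()
    rng = substream(config.seed if seed is None else seed, "genome")
    chrom_names = list(config.genome.chromosomes)
    chrom_sizes = [config.genome.chromosomes[c] for c in chrom_names]

    # Assign (label, length) target tuples to chromosomes.
    per_chrom: list[list[tuple[str, int]]] = [[] for _ in chrom_names]
    for label, model in config.subregions.items():
        counts = _allocate_counts(model.n_targets, [float(s) for s in chrom_sizes])
        for ci, cnt in enumerate(counts):
            per_chrom[ci].extend([(label, model.target_length)] * cnt)

    sequences: dict[str, np.ndarray] = {}
    placed: dict[str, list[GenomicInterval]] = {lbl: [] for lbl in config.subregions}
    for ci, chrom in enumerate(chrom_names):
        size = chrom_sizes[ci]
        seq = _random_bases(size, config.genome.background_gc, rng)
        targets = per_chrom[ci]
        used = sum(length for _, length in targets)
        if used > size:
            raise ValueError(
                f"requested target span {used} exceeds chromosome {chrom} "
                f"size {size}"
            )
        order = rng.permutation(len(targets))
        free = size - used
        gaps = rng.multinomial(free, np.full(len(targets) + 1, 1 / (len(targets) + 1)))
        cursor = 0
        for gi, oi in enumerate(order):
            cursor += int(gaps[gi])
            label, length = targets[oi]
            seq[cursor : cursor + length] = _random_bases(
                length, config.subregions[label].gc, rng
            )
            placed[label].append(GenomicInterval(chrom, cursor, cursor + length))
            cursor += length
        sequences[chrom] = seq

    genome = ReferenceGenome(sequences)
    subregions = {lbl: SubregionSet(lbl, ivs) for lbl, ivs in placed.items()}
    return genome, subregions


# ---------------------------------------------------------------------------
# Depth


def simulate_depth(
    genome: ReferenceGenome,
    config: SimulationConfig,
    mode: str = "capture",
    seed: int | None = None,
) -> DepthTrack:
    """GC-biased per-base depth for one sequencing mode.

    Expected depth is ``d0 * m(g_i)^e`` with the Gaussian-in-GC bias curve
    ``m`` and ``e = capture_exponent`` under capture, 1 under WGS; realised
    depth is Poisson (or negative-binomial when a dispersion is configured).
    """
    if mode not in ("capture", "wgs"):
        raise ValueError(f"mode must be 'capture' or 'wgs', got {mode!r}")
    d = config.depth
    if d.gc_width <= 0:
        raise ValueError("depth.gc_width must be positive")
    rng = substream(config.seed if seed is None else seed, f"depth-{mode}")
    exponent = d.capture_exponent if mode == "capture" else 1.0
    depths: dict[str, np.ndarray] = {}
    for chrom in genome.sequences:
        g = windowed_gc_fraction(genome, chrom, window=d.gc_window)
        m = np.exp(-((g - d.gc_optimum) ** 2) / (2 * d.gc_width**2))
        lam = d.baseline_depth * m**exponent
        if d.dispersion is None:
            depths[chrom] = rng.poisson(lam)
        else:
            theta = d.dispersion
            depths[chrom] = rng.negative_binomial(theta, theta / (theta + lam))
    return DepthTrack(depths=depths, mode=mode)


# ---------------------------------------------------------------------------
# Variants


def poisson_positions(
    intervals: list[GenomicInterval], one_in_x: float, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Distinct positions of a homogeneous Poisson process over intervals.

    The process has rate ``1/one_in_x`` per bp restricted to the interval
    union; duplicate draws (rare at realistic densities) are collapsed so a
    site appears at most once.
    """
    if one_in_x <= 0:
        raise ValueError("one_in_x must be positive")
    span = sum(iv.length for iv in intervals)
    if span == 0:
        return []
    count = rng.poisson(span / one_in_x)
    if count == 0:
        return []
    offsets = np.unique(rng.integers(0, span, size=count))
    bounds = np.cumsum([iv.length for iv in intervals])
    idx = np.searchsorted(bounds, offsets, side="right")
    out = []
    for off, i in zip(offsets, idx):
        iv = intervals[i]
        prev = bounds[i - 1] if i > 0 else 0
        out.append((iv.chrom, iv.start + int(off - prev)))
    return out


def draw_substitutions(
    refs: np.ndarray, spectrum: dict[str, float], rng: np.random.Generator
) -> np.ndarray:
    """Alt-base codes for given ref-base codes, conditional on the ref base.

    For each reference base the three possible directed substitutions are
    drawn with probability proportional to their spectrum weights.
    """
    refs = np.asarray(refs, dtype=np.uint8)
    alts = np.zeros_like(refs)
    for ref_code in _BASE_CODES:
        mask = refs == ref_code
        n = int(mask.sum())
        if n == 0:
            continue
        ref_b = chr(ref_code)
        alt_codes = np.array([c for c in _BASE_CODES if c != ref_code], dtype=np.uint8)
        weights = np.array([spectrum[f"{ref_b}>{chr(c)}"] for c in alt_codes])
        if weights.sum() <= 0:
            raise ValueError(f"spectrum assigns zero mass to all changes of {ref_b}")
        choice = rng.choice(3, size=n, p=weights / weights.sum())
        alts[mask] = alt_codes[choice]
    return alts


def draw_panel_mafs(
    n: int,
    private_prob: float,
    fixed_prob: float,
    low: float,
    high: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Panel allele frequencies: point masses at 0 (private) and 1 (fixed),
    remainder Uniform(low, high)."""
    u = rng.random(n)
    rest = rng.uniform(low, high, n)
    out = np.where(
        u < private_prob, 0.0, np.where(u < private_prob + fixed_prob, 1.0, rest)
    )
    return out


def simulate_variants(
    genome: ReferenceGenome,
    subregions: dict[str, SubregionSet],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[VariantCall]:
    """Per-class marked Poisson SNV processes over the subregion targets.

    Classes are processed in configuration order; when classes overlap, the
    first class to claim a site keeps it (one record per site). Site
    quality, depth, alt fraction, low-MAPQ fraction and panel MAF are drawn
    from the shared annotation model and the class MAF point masses.
    """
    rng = substream(config.seed if seed is None else seed, "variants")
    ann = config.annotations
    seen: dict[tuple[str, int], VariantCall] = {}
    for label, model in config.subregions.items():
        if model.one_in_x is None or label not in subregions:
            continue
        positions = poisson_positions(
            subregions[label].intervals, model.one_in_x, rng
        )
        if not positions:
            continue
        refs = np.array(
            [genome[chrom][pos] for chrom, pos in positions], dtype=np.uint8
        )
        valid = np.isin(refs, _BASE_CODES)
        positions = [p for p, v in zip(positions, valid) if v]
        refs = refs[valid]
        n = len(positions)
        if n == 0:
            continue
        alts = draw_substitutions(refs, model.spectrum, rng)
        quality = np.clip(rng.normal(ann.quality_mean, ann.quality_sd, n), 0, None)
        depth = np.maximum(rng.poisson(ann.depth_mean, n), 1)
        alt_frac = rng.beta(ann.alt_fraction_a, ann.alt_fraction_b, n)
        alt_depth = np.maximum(rng.binomial(depth, alt_frac), 1)
        low_mapq = rng.beta(ann.low_mapq_a, ann.low_mapq_b, n)
        mafs = draw_panel_mafs(
            n, model.private_prob, model.fixed_prob, ann.maf_low, ann.maf_high, rng
        )
        for i, (chrom, pos) in enumerate(positions):
            key = (chrom, pos)
            if key in seen:
                continue
            seen[key] = VariantCall(
                chrom=chrom,
                pos=pos,
                ref=chr(refs[i]),
                alt=chr(alts[i]),
                quality=float(quality[i]),
                depth=int(depth[i]),
                alt_depth=int(alt_depth[i]),
                low_mapq_fraction=float(low_mapq[i]),
                panel_maf=float(mafs[i]),
            )
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# Conservation


def _draw_scores(
    n: int, model: SubregionModel, rng: np.random.Generator
) -> np.ndarray:
    spec = model.conservation
    if spec.kind == "point":
        return np.full(n, spec.value)
    if spec.kind == "normal":
        return rng.normal(spec.mean, spec.sd, n)
    if spec.kind == "mixture":
        weights = np.array([c["weight"] for c in spec.components])
        means = np.array([c["mean"] for c in spec.components])
        sds = np.array([c["sd"] for c in spec.components])
        comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
        return rng.normal(means[comp], sds[comp])
    raise ValueError(f"unknown conservation kind {spec.kind!r}")


def simulate_conservation(
    genome: ReferenceGenome,
    subregions: dict[str, SubregionSet],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-base conservation scores over subregion bases (NaN elsewhere)."""
    rng = substream(config.seed if seed is None else seed, "conservation")
    scores = {
        chrom: np.full(length, np.nan) for chrom, length in genome.lengths.items()
    }
    for label, model in config.subregions.items():
        if label not in subregions:
            continue
        for iv in subregions[label].intervals:
            scores[iv.chrom][iv.start : iv.end] = _draw_scores(iv.length, model, rng)
    return scores


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SyntheticDataset:
    """All artefacts of one simulated study, in memory."""

    reference: ReferenceGenome
    subregions: dict[str, SubregionSet]
    depth_capture: DepthTrack
    depth_wgs: DepthTrack
    variants: list[VariantCall]
    conservation: dict[str, np.ndarray]
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write FASTA, per-class BEDs, depth bedGraphs, VCF and the
        conservation bedGraph; returns a name -> path manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        ref_path = outdir / "reference.fa"
        self.reference.to_fasta(ref_path)
        paths["reference"] = str(ref_path)

        targets_dir = outdir / "targets"
        targets_dir.mkdir(exist_ok=True)
        for label, sub in self.subregions.items():
            p = targets_dir / f"{label}.bed"
            write_bed(sub.intervals, p)
            paths[f"targets/{label}"] = str(p)

        for mode, track in (("capture", self.depth_capture), ("wgs", self.depth_wgs)):
            p = outdir / f"depth_{mode}.bedgraph"
            write_depth_track(track, p, dialect="bedgraph")
            paths[f"depth_{mode}"] = str(p)

        vcf_path = outdir / "variants.vcf"
        write_vcf(self.variants, vcf_path, contigs=self.reference.lengths)
        paths["variants"] = str(vcf_path)

        cons_path = outdir / "conservation.bedgraph"
        write_conservation_track(self.conservation, cons_path)
        paths["conservation"] = str(cons_path)

        cfg_path = outdir / "config.yaml"
        self.config.to_yaml(cfg_path)
        paths["config"] = str(cfg_path)
        return paths


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SyntheticDataset:
    """Run the full generator: genome, both depth tracks, variants, scores."""
    if seed is not None:
        config.seed = int(seed)
    genome, subregions = simulate_genome(config)
    return SyntheticDataset(
        reference=genome,
        subregions=subregions,
        depth_capture=simulate_depth(genome, config, "capture"),
        depth_wgs=simulate_depth(genome, config, "wgs"),
        variants=simulate_variants(genome, subregions, config),
        conservation=simulate_conservation(genome, subregions, config),
        config=config,
    )


def write_conservation_track(
    scores: dict[str, np.ndarray], path: str | Path
) -> None:
    """bedGraph of per-base conservation scores (NaN positions omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(scores):
            arr = scores[chrom]
            finite = np.flatnonzero(~np.isnan(arr))
            if finite.size == 0:
                continue
            frame = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": finite,
                    "end": finite + 1,
                    "score": np.round(arr[finite], 4),
                }
            )
            frame.to_csv(fh, sep="\t", header=False, index=False)


def read_conservation_track(
    path: str | Path, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Read a conservation bedGraph into per-base arrays (NaN = unscored)."""
    scores = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    for chrom, grp in frame.groupby("chrom", sort=False):
        if chrom not in scores:
            raise ValueError(f"chromosome {chrom!r} not in chrom_sizes")
        arr = scores[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["score"].to_numpy()
        if np.all(ends - starts == 1):
            arr[starts] = vals
        else:
            for s, e, v in zip(starts, ends, vals):
                arr[s:e] = v
    return scores
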