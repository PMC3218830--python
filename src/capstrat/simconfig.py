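"""Generative parameterisation of the synthetic capture-sequencing study.

One :class:`SimulationConfig` describes everything the generator needs: the
genome, the functional subregion classes with their GC content and variant
processes, the GC-dependent depth-bias model, and the distributions behind
per-site annotations. The shipped defaults encode the study conditions this
package is built around: subregion classes with distinct GC modes (~30%
conserved UTR, ~50% CCDS, ~70% regulome), per-class variant densities in
the 1/660-1/2,300 bp range, a 3:1 coding vs 1.6:1 regulome Ts:Tv, and
private-variant fractions of 9-16%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "DepthModel",
    "AnnotationModel",
    "ConservationSpec",
    "SubregionModel",
    "GenomeModel",
    "SimulationConfig",
    "tstv_spectrum",
    "SUBSTITUTION_KEYS",
]

_BASES = ("A", "C", "G", "T")
SUBSTITUTION_KEYS = tuple(f"{r}>{a}" for r in _BASES for a in _BASES if a != r)
_TRANSITION_KEYS = ("A>G", "G>A", "C>T", "T>C")


def tstv_spectrum(ts_tv: float) -> dict[str, float]:
    """Uniform 12-type spectrum realising a given Ts:Tv ratio.

    The four transition types share the transition mass equally, the eight
    transversion types likewise; the implied Ts:Tv (sum of transition
    weights over sum of transversion weights) equals ``ts_tv``.
    """
    if ts_tv <= 0:
        raise ValueError("ts_tv must be positive")
    w_ts = ts_tv / (4 * (ts_tv + 1))
    w_tv = 1 / (8 * (ts_tv + 1))
    return {
        k: (w_ts if k in _TRANSITION_KEYS else w_tv) for k in SUBSTITUTION_KEYS
    }


@dataclass
class DepthModel:
    """Unimodal GC-dependent depth bias.

    Expected depth at base i is ``d0 * m(g_i)^e`` with
    ``m(g) = exp(-(g - g0)^2 / (2 sigma^2))``, ``g_i`` the GC fraction of a
    centred window, and exponent ``e = beta`` under capture, 1 under WGS:
    hybridisation capture exacerbates the platform's GC bias. ``dispersion``
    of ``None`` draws Poisson noise; a finite value draws negative-binomial
    with that shape parameter (smaller = more overdispersed).
    """

    baseline_depth: float = 100.0
    gc_optimum: float = 0.50
    gc_width: float = 0.17
    capture_exponent: float = 1.5
    dispersion: float | None = None
    gc_window: int = 100


@dataclass
class AnnotationModel:
    """Distributions for per-site call annotations (shared across classes).

    Site quality is Normal(mean, sd) truncated at 0; total depth is
    Poisson(depth_mean) conditioned positive; the alt-read fraction is
    Beta(a, b) (defaults centre it near 0.5, a heterozygous-like call); the
    low-MAPQ read fraction is Beta(a, b) with mean ~0.05, matching the
    typical 5-10% of reads removed by mapping-quality filtering.
    """

    quality_mean: float = 80.0
    quality_sd: float = 20.0
    depth_mean: float = 100.0
    alt_fraction_a: float = 8.0
    alt_fraction_b: float = 8.0
    low_mapq_a: float = 1.0
    low_mapq_b: float = 19.0
    maf_low: float = 0.01
    maf_high: float = 0.99


@dataclass
class ConservationSpec:
    """Per-class conservation-score distribution.

    ``kind`` is ``normal`` (mean, sd), ``point`` (value) or ``mixture``
    (components = list of {weight, mean, sd}).
    """

    kind: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    value: float = 0.0
    components: list[dict[str, float]] = field(default_factory=list)


@dataclass
class SubregionModel:
    """One functional class of capture targets.

    ``one_in_x`` sets the variant density as bp per variant (e.g. 1500
    means one variant per 1,500 callable bp); ``None`` disables variants
    for the class. ``spectrum`` holds the 12 directed substitution weights.
    ``private_prob`` / ``fixed_prob`` set the panel-MAF point masses at 0
    and 1; the remainder is Uniform(maf_low, maf_high).
    """

    n_targets: int
    target_length: int
    gc: float
    one_in_x: float | None = None
    spectrum: dict[str, float] = field(default_factory=lambda: tstv_spectrum(2.0))
    private_prob: float = 0.10
    fixed_prob: float = 0.05
    conservation: ConservationSpec = field(default_factory=ConservationSpec)


@dataclass
class GenomeModel:
    """Synthetic reference: chromosome sizes and background GC."""

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    background_gc: float = 0.40


@dataclass
class SimulationConfig:
    genome: GenomeModel = field(default_factory=GenomeModel)
    subregions: dict[str, SubregionModel] = field(default_factory=dict)
    depth: DepthModel = field(default_factory=DepthModel)
    annotations: AnnotationModel = field(default_factory=AnnotationModel)
    seed: int = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def default(cls) -> "SimulationConfig":
        """The shipped study-defaults configuration.

        Classes realise distinct GC modes and the per-class densities,
        spectra and panel-MAF point masses the package's analyses are
        calibrated around. Densities are bp-per-variant; conserved classes
        are sparse (purifying selection), predicted exons and the regulome
        dense.
        """
        mix_heavy_tails = ConservationSpec(
            kind="mixture",
            components=[
                {"weight": 0.70, "mean": 0.0, "sd": 1.0},
                {"weight": 0.15, "mean": 2.5, "sd": 1.0},
                {"weight": 0.15, "mean": -2.5, "sd": 1.0},
            ],
        )
        sub = {
            "CCDS": SubregionModel(
                n_targets=1500, target_length=200, gc=0.50, one_in_x=1500,
                spectrum=tstv_spectrum(3.0), private_prob=0.09, fixed_prob=0.06,
                conservation=ConservationSpec(kind="normal", mean=1.5, sd=1.0),
            ),
            "refseq_vega_specific": SubregionModel(
                n_targets=600, target_length=150, gc=0.48, one_in_x=1200,
                spectrum=tstv_spectrum(2.5), private_prob=0.10, fixed_prob=0.05,
                conservation=ConservationSpec(kind="normal", mean=1.0, sd=1.0),
            ),
            "conserved_UTR": SubregionModel(
                n_targets=800, target_length=150, gc=0.30, one_in_x=2300,
                spectrum=tstv_spectrum(2.0), private_prob=0.09, fixed_prob=0.06,
                conservation=ConservationSpec(kind="normal", mean=1.2, sd=1.0),
            ),
            "nonconserved_UTR": SubregionModel(
                n_targets=800, target_length=200, gc=0.40, one_in_x=925,
                spectrum=tstv_spectrum(2.0), private_prob=0.11, fixed_prob=0.05,
                conservation=ConservationSpec(kind="normal", mean=0.2, sd=1.0),
            ),
            "regulome": SubregionModel(
                n_targets=1200, target_length=100, gc=0.70, one_in_x=750,
                spectrum=tstv_spectrum(1.6), private_prob=0.12, fixed_prob=0.05,
                conservation=ConservationSpec(kind="normal", mean=0.5, sd=1.0),
            ),
            "predicted_exons": SubregionModel(
                n_targets=800, target_length=150, gc=0.55, one_in_x=714,
                spectrum=tstv_spectrum(2.3), private_prob=0.16, fixed_prob=0.04,
                conservation=mix_heavy_tails,
            ),
            "miRNA": SubregionModel(
                n_targets=200, target_length=100, gc=0.55, one_in_x=1500,
                spectrum=tstv_spectrum(2.0), private_prob=0.10, fixed_prob=0.05,
                conservation=ConservationSpec(kind="normal", mean=1.0, sd=1.0),
            ),
            "intron": SubregionModel(
                n_targets=300, target_length=2000, gc=0.40, one_in_x=850,
                spectrum=tstv_spectrum(2.0), private_prob=0.12, fixed_prob=0.05,
                conservation=ConservationSpec(kind="normal", mean=0.0, sd=1.0),
            ),
        }
        return cls(subregions=sub)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for model in d["subregions"].values():
            if model["conservation"]["kind"] != "mixture":
                model["conservation"].pop("components")
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        def pick(klass, payload):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(
                    f"unknown field(s) for {klass.__name__}: {sorted(unknown)}"
                )
            return klass(**payload)

        genome = pick(GenomeModel, data.get("genome", {}))
        depth = pick(DepthModel, data.get("depth", {}))
        ann = pick(AnnotationModel, data.get("annotations", {}))
        subs: dict[str, SubregionModel] = {}
        for label, payload in data.get("subregions", {}).items():
            payload = dict(payload)
            cons = payload.pop("conservation", None)
            model = pick(SubregionModel, payload)
            if cons is not None:
                model.conservation = pick(ConservationSpec, cons)
            subs[label] = model
        return cls(
            genome=genome,
            subregions=subs,
            depth=depth,
            annotations=ann,
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- validation ----------------------------------------------------------

    def validate(self) -> list[str]:
        """Check every invariant; return violations as dotted field paths."""
        bad: list[str] = []

        def check(cond: bool, path: str, msg: str) -> None:
            if not cond:
                bad.append(f"{path}: {msg}")

        check(bool(self.genome.chromosomes), "genome.chromosomes", "must be non-empty")
        for chrom, size in self.genome.chromosomes.items():
            check(size > 0, f"genome.chromosomes.{chrom}", "length must be positive")
        check(
            0.0 <= self.genome.background_gc <= 1.0,
            "genome.background_gc", "must be in [0, 1]",
        )
        d = self.depth
        check(d.baseline_depth > 0, "depth.baseline_depth", "must be positive")
        check(d.gc_width > 0, "depth.gc_width", "must be positive")
        check(0.0 <= d.gc_optimum <= 1.0, "depth.gc_optimum", "must be in [0, 1]")
        check(d.capture_exponent >= 1, "depth.capture_exponent", "must be >= 1")
        check(
            d.dispersion is None or d.dispersion > 0,
            "depth.dispersion", "must be positive or null",
        )
        check(d.gc_window > 0, "depth.gc_window", "must be positive")
        a = self.annotations
        check(a.quality_sd > 0, "annotations.quality_sd", "must be positive")
        check(a.depth_mean > 0, "annotations.depth_mean", "must be positive")
        check(
            0 <= a.maf_low < a.maf_high <= 1,
            "annotations.maf_low/maf_high", "must satisfy 0 <= low < high <= 1",
        )
        total_demand = 0
        for label, m in self.subregions.items():
            p = f"subregions.{label}"
            check(m.n_targets > 0, f"{p}.n_targets", "must be positive")
            check(m.target_length > 0, f"{p}.target_length", "must be positive")
            check(0.0 <= m.gc <= 1.0, f"{p}.gc", "must be in [0, 1]")
            check(
                m.one_in_x is None or m.one_in_x > 0,
                f"{p}.one_in_x", "must be positive or null",
            )
            check(
                0.0 <= m.private_prob <= 1.0 and 0.0 <= m.fixed_prob <= 1.0
                and m.private_prob + m.fixed_prob <= 1.0,
                f"{p}.private_prob/fixed_prob",
                "must be probabilities with sum <= 1",
            )
            spec = m.spectrum
            check(
                set(spec) == set(SUBSTITUTION_KEYS),
                f"{p}.spectrum", "must have exactly the 12 directed substitution keys",
            )
            if set(spec) == set(SUBSTITUTION_KEYS):
                check(
                    all(w >= 0 for w in spec.values()),
                    f"{p}.spectrum", "weights must be non-negative",
                )
                check(
                    abs(sum(spec.values()) - 1.0) <= 1e-9,
                    f"{p}.spectrum", "weights must sum to 1",
                )
            cons = m.conservation
            check(
                cons.kind in ("normal", "point", "mixture"),
                f"{p}.conservation.kind", "must be normal, point or mixture",
            )
            if cons.kind == "normal":
                check(cons.sd > 0, f"{p}.conservation.sd", "must be positive")
            if cons.kind == "mixture":
                check(bool(cons.components), f"{p}.conservation.components",
                      "must be non-empty")
                wsum = sum(comp.get("weight", 0.0) for comp in cons.components)
                check(
                    abs(wsum - 1.0) <= 1e-9,
                    f"{p}.conservation.components", "weights must sum to 1",
                )
            total_demand += m.n_targets * m.target_length
        genome_size = sum(self.genome.chromosomes.values())
        check(
            total_demand <= genome_size,
            "subregions",
            f"total target span {total_demand} exceeds genome size {genome_size}",
        )
        check(self.seed >= 0, "seed", "must be non-negative")
        return bad

    def require_valid(self) -> None:
        bad = self.validate()
        if bad:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(bad))
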