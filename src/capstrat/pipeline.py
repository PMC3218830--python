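"""End-to-end orchestration: simulate -> coverage -> variant reports.

One call produces the full study readout on a synthetic dataset: per
subregion, capture and WGS coverage relative to the CCDS baseline, the
capture/WGS enrichment ratio, variant densities per callable base with
CCDS-normalisation, the mutation spectrum with Ts:Tv, panel-MAF classes and
conservation histograms, plus a machine-readable run manifest. Identical
config and seed reproduce byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .coverage import (
    capture_ability,
    relative_enrichment,
    summarize_coverage,
)
from .simconfig import SimulationConfig
from .simulate import SyntheticDataset, simulate_dataset
from .variants import (
    apply_variant_filters,
    callable_bases,
    conservation_distribution,
    maf_classify,
    mutation_spectrum,
    rate_ratio_test,
    relative_density,
    restrict_calls,
    variant_density,
)

__all__ = ["run_pipeline", "validate_config", "build_reports"]

logger = logging.getLogger("capstrat.pipeline")

BASELINE = "CCDS"
CONSERVATION_EDGES = [-6.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 6.0]
MAF_EDGES = (0.01, 0.05, 0.10, 0.25, 0.50)


def validate_config(path: str | Path) -> list[str]:
    """Validate a YAML config file; returns violations (empty = ok)."""
    config = SimulationConfig.from_yaml(path)
    return config.validate()


def _config_hash(config: SimulationConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_reports(dataset: SyntheticDataset, min_depth: int = 10) -> dict:
    """Compute all report tables from an in-memory dataset.

    Returns a dict with ``coverage`` and ``variants`` DataFrames plus a
    nested JSON-ready ``bundle``. The CCDS subregion is the normalisation
    baseline for relative coverage and relative density.
    """
    subregions = dataset.subregions
    if BASELINE not in subregions:
        raise ValueError(f"dataset lacks the {BASELINE} baseline subregion")

    # --- coverage stage ---
    cap_sums = {l: summarize_coverage(dataset.depth_capture, s) for l, s in subregions.items()}
    wgs_sums = {l: summarize_coverage(dataset.depth_wgs, s) for l, s in subregions.items()}
    cov_rows = []
    for label in subregions:
        cap_rel = capture_ability(cap_sums[label], cap_sums[BASELINE])
        wgs_rel = capture_ability(wgs_sums[label], wgs_sums[BASELINE])
        enrich = relative_enrichment(cap_rel, wgs_rel)
        s = cap_sums[label]
        cov_rows.append(
            {
                "label": label,
                "bases": s.bases,
                "mean_depth": s.mean_depth,
                "median_depth": s.median_depth,
                "frac_ge_10x": s.frac_ge_10x,
                "capture_relative": cap_rel.ratio,
                "wgs_relative": wgs_rel.ratio,
                "enrichment": enrich.value,
            }
        )
    coverage_df = pd.DataFrame(cov_rows)

    # --- variant stage ---
    retained, tally = apply_variant_filters(dataset.variants)
    densities = {}
    var_rows = []
    spectra = {}
    mafs = {}
    cons_hists = {}
    for label, sub in subregions.items():
        callable_bp = callable_bases(dataset.depth_capture, sub, min_depth=min_depth)
        calls = restrict_calls(retained, sub, dataset.depth_capture, min_depth=min_depth)
        if callable_bp == 0:
            continue
        densities[label] = variant_density(calls, callable_bp, label)
        spectra[label] = mutation_spectrum(calls)
        mafs[label] = maf_classify(calls, MAF_EDGES, label=label) if calls else None
        try:
            cons_hists[label] = conservation_distribution(
                dataset.conservation, sub, CONSERVATION_EDGES
            ).tolist()
        except ValueError:
            cons_hists[label] = None
    for label, dens in densities.items():
        dens = relative_density(dens, densities[BASELINE])
        densities[label] = dens
        spec = spectra[label]
        maf = mafs[label]
        var_rows.append(
            {
                "label": label,
                "retained": dens.retained,
                "callable_bases": dens.callable_bases,
                "density": dens.density,
                "one_in_x": dens.one_in_x,
                "relative_density": dens.relative_density,
                "ts_tv": spec.ts_tv,
                "frac_private": maf.frac_private if maf else math.nan,
                "frac_fixed": maf.frac_fixed if maf else math.nan,
            }
        )
    variants_df = pd.DataFrame(var_rows)

    # rate-difference check: intron vs predicted exons, when both exist
    rate_p = None
    if "intron" in densities and "predicted_exons" in densities:
        d1, d2 = densities["predicted_exons"], densities["intron"]
        rate_p = rate_ratio_test(
            d1.retained, d1.callable_bases, d2.retained, d2.callable_bases
        )

    bundle = {
        "filter_tally": {
            "input": tally.input,
            "retained": tally.retained,
            "removed_quality": tally.removed_quality,
            "removed_zero_depth": tally.removed_zero_depth,
            "removed_alt_fraction": tally.removed_alt_fraction,
            "removed_low_mapq": tally.removed_low_mapq,
        },
        "coverage": cov_rows,
        "variants": var_rows,
        "spectrum_proportions": {
            l: spectra[l].proportions for l in densities if l in spectra
        },
        "maf": {
            l: (
                {
                    "frac_private": mafs[l].frac_private,
                    "frac_fixed": mafs[l].frac_fixed,
                    "bin_edges": list(mafs[l].bin_edges),
                    "bin_fractions": list(mafs[l].bin_fractions),
                }
                if mafs.get(l)
                else None
            )
            for l in densities
        },
        "conservation": {
            "bin_edges": CONSERVATION_EDGES,
            "proportions": cons_hists,
        },
        "rate_test_predicted_exons_vs_intron_p": rate_p,
    }
    return {"coverage": coverage_df, "variants": variants_df, "bundle": bundle}


def run_pipeline(
    config: SimulationConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Simulate a dataset, write all artefacts and the report tables.

    Returns the run manifest. Reports land in ``outdir/report`` as
    ``coverage.tsv``, ``variants.tsv`` and ``report.json``; the manifest in
    ``outdir/manifest.json`` records the config hash, seed, package version,
    per-stage outputs and wall time.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    config.require_valid()
    if seed is not None:
        config.seed = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "ok": False,
    }

    t0 = time.perf_counter()
    logger.info("[simulate] generating dataset (seed=%d)", config.seed)
    dataset = simulate_dataset(config)
    paths = dataset.write(outdir / "data")
    manifest["stages"]["simulate"] = {
        "outputs": paths,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t1 = time.perf_counter()
    logger.info("[report] summarising coverage and variants")
    reports = build_reports(dataset)
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    cov_path = report_dir / "coverage.tsv"
    var_path = report_dir / "variants.tsv"
    json_path = report_dir / "report.json"
    reports["coverage"].to_csv(cov_path, sep="\t", index=False, float_format="%.6g")
    reports["variants"].to_csv(var_path, sep="\t", index=False, float_format="%.6g")
    with open(json_path, "w") as fh:
        json.dump(reports["bundle"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["stages"]["report"] = {
        "outputs": {
            "coverage": str(cov_path),
            "variants": str(var_path),
            "bundle": str(json_path),
        },
        "seconds": round(time.perf_counter() - t1, 3),
    }
    manifest["ok"] = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
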