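"""End-to-end pipeline orchestration.

A run is described by a config (YAML or dict): a root seed, an output
directory and an ordered list of stages.  Each stage writes its tables to
the output directory; a manifest records inputs, per-stage seeds, file
checksums and package version, and the report is regenerated from the
manifest plus the written files alone.

Supported stages and their parameter blocks:

``simulate_counts``
    model (coin_flip | all_or_none | bursting) plus the generator
    parameters of :mod:`allelesim.synthetic`.
``models``
    tests: any of coin_flip, all_or_none, bursting, paired_correlation;
    n_sims; false-detection rates for the all-or-none test.
``simulate_tissue`` / ``spatial``
    tissue-layout generation and the seed-size estimate.
``simulate_spots`` / ``colocalize``
    spot-field generation, radius scan and per-cell aggregation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colocalization as coloc
from . import models as mdl
from . import spatial as spat
from . import synthetic as syn
from .counts import read_counts_tsv, write_counts_tsv

__all__ = ["run_pipeline", "write_report", "load_config"]

log = logging.getLogger("allelesim")

STAGES = (
    "simulate_counts",
    "models",
    "simulate_tissue",
    "spatial",
    "simulate_spots",
    "colocalize",
)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if "stages" not in cfg or not cfg["stages"]:
        raise ValueError("config must list at least one stage")
    produces_counts = False
    produces_layout = False
    produces_spots = False
    for block in cfg["stages"]:
        (name, params), = block.items() if isinstance(block, dict) else [(block, {})]
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
        params = params or {}
        if name == "simulate_counts":
            produces_counts = True
        elif name == "models" and not (produces_counts or params.get("counts")):
            raise ValueError("'models' stage needs simulate_counts before it "
                             "or an explicit counts path")
        elif name == "simulate_tissue":
            produces_layout = True
        elif name == "spatial" and not (produces_layout or params.get("foci")):
            raise ValueError("'spatial' stage needs simulate_tissue before it "
                             "or an explicit foci path")
        elif name == "simulate_spots":
            produces_spots = True
        elif name == "colocalize" and not produces_spots:
            raise ValueError("'colocalize' stage needs simulate_spots before it")
        if name == "models" and params.get("counts"):
            if not Path(params["counts"]).exists():
                raise ValueError(f"counts file not found: {params['counts']}")
        if name == "spatial" and params.get("foci"):
            if not Path(params["foci"]).exists():
                raise ValueError(f"foci file not found: {params['foci']}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in order; return the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config.get("out_dir", "allelesim_run"))
    out.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    manifest: dict = {"seed": seed, "out_dir": str(out), "stages": [], "files": {}}
    for i, block in enumerate(config["stages"]):
        (name, params), = block.items() if isinstance(block, dict) else [(block, {})]
        params = dict(params or {})
        stage_seed = seed + i
        log.info("stage %d: %s (seed %d)", i, name, stage_seed)
        try:
            written = _STAGE_FN[name](params, state, out, stage_seed)
        except Exception:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.exception("stage %s failed; partial outputs preserved in %s", name, out)
            raise
        manifest["stages"].append({"name": name, "seed": stage_seed, "params": params})
        for f in written:
            manifest["files"][f.name] = _sha256(f)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    write_report(manifest)
    manifest["files"]["report.txt"] = _sha256(out / "report.txt")
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate_counts(params, state, out: Path, seed):
    model = params.get("model", "coin_flip")
    if model == "bursting":
        pb = syn.NegBinParams.from_bursting(
            params.get("burst_size_bl6", 1.0), params.get("burst_frequency_bl6", 1.5)
        )
        pj = syn.NegBinParams.from_bursting(
            params.get("burst_size_jf1", 1.0), params.get("burst_frequency_jf1", 1.5)
        )
        counts = syn.gen_bursting_population(
            params.get("n_cells", 1000), pb, pj, rng_seed=seed
        )
    else:
        cfg = syn.GeneratorConfig(
            n_cells=params.get("n_cells", 1000),
            p_bl6=params.get("p_bl6", 0.5),
            lam=params.get("lam", 3.0),
            fdr_bl6=params.get("fdr_bl6", 0.0),
            fdr_jf1=params.get("fdr_jf1", 0.0),
            rng_seed=seed,
        )
        gen = (
            syn.gen_coin_flip_population
            if model == "coin_flip"
            else syn.gen_all_or_none_population
        )
        counts = gen(cfg)
    rate = params.get("detection_rate", 1.0)
    if rate < 1.0:
        counts = syn.apply_detection_downsampling(counts, rate, rng_seed=seed)
    path = out / "counts.tsv"
    write_counts_tsv(counts, path)
    state["counts"] = counts
    state["counts_model"] = model
    return [path]


def _result_record(res: mdl.ModelTestResult) -> dict:
    return {
        "model": res.model,
        "statistic": res.statistic,
        "observed": res.observed,
        "percentile": res.percentile,
        "p_value": res.p_value,
        "n_sims": res.n_sims,
        "rejected_95": res.rejects(95.0),
    }


def _stage_models(params, state, out: Path, seed):
    counts = (
        read_counts_tsv(params["counts"]) if params.get("counts") else state["counts"]
    )
    n_sims = params.get("n_sims", 10_000)
    fdr_b = params.get("fdr_bl6", 0.02)
    fdr_j = params.get("fdr_jf1", 0.02)
    tests = params.get("tests", ["coin_flip", "all_or_none"])
    written = []
    records = []
    st = mdl.population_stats(counts)
    for t in tests:
        if t == "coin_flip":
            res = mdl.coin_flip_test(counts, n_sims=n_sims, rng_seed=seed)
        elif t == "all_or_none":
            res = mdl.all_or_none_test(
                counts, fdr_b, fdr_j, n_sims=n_sims, rng_seed=seed
            )
        elif t == "bursting":
            res = mdl.bursting_fit_test(counts, "BL6", n_sims=n_sims, rng_seed=seed)
        elif t == "paired_correlation":
            pb = mdl.fit_negbin_moments(counts["n_bl6"])
            pj = mdl.fit_negbin_moments(counts["n_jf1"])
            res = mdl.paired_correlation_test(
                counts, pb, pj, n_sims=n_sims, rng_seed=seed
            )
        else:
            raise ValueError(f"unknown model test {t!r}")
        records.append(_result_record(res))
        null_path = out / f"null_{res.model}.tsv"
        pd.DataFrame({"value": res.null}).to_csv(null_path, sep="\t", index=False)
        written.append(null_path)
    summary = {
        "p_bl6_hat": st.p_bl6_hat,
        "correlation": st.correlation,
        "n_cells": st.n_cells,
        "tests": records,
    }
    path = out / "model_tests.json"
    path.write_text(json.dumps(summary, indent=2))
    state["model_summary"] = summary
    return written + [path]


def _stage_simulate_tissue(params, state, out: Path, seed):
    layout = syn.gen_tissue_layout(
        n_cells=params.get("n_cells", 2000),
        p_bl6=params.get("p_bl6", 0.5),
        seed_size=params.get("seed_size", 1),
        extent=tuple(params.get("extent", (1000.0, 1000.0))),
        rng_seed=seed,
    )
    path = out / "tissue.tsv"
    layout.to_frame().to_csv(path, sep="\t", index=False)
    state["layout"] = layout
    return [path]


def _stage_spatial(params, state, out: Path, seed):
    if params.get("foci"):
        df = pd.read_csv(params["foci"], sep="\t")
        layout = syn.TissueLayout(
            positions=df[["x", "y"]].to_numpy(),
            identities=df["assignment"].to_numpy(),
        )
    else:
        layout = state["layout"]
    gmin, gmax = params.get("grid_min", 4), params.get("grid_max", 16)
    grids = [(g, g) for g in range(gmin, gmax + 1)]
    result = spat.estimate_seed_size(
        layout,
        grids=grids,
        seed_sizes=range(params.get("seed_min", 1), params.get("seed_max", 10) + 1),
        n_sim=params.get("n_sim", 500),
        rng_seed=seed,
    )
    per_grid_path = out / "spatial_per_grid.tsv"
    result.per_grid.to_csv(per_grid_path, sep="\t", index=False)
    nulls_path = out / "spatial_null_means.tsv"
    result.null_means.to_csv(nulls_path, sep="\t")
    summary = {"mean_seed": result.mean_seed, "sd_seed": result.sd_seed}
    jpath = out / "spatial.json"
    jpath.write_text(json.dumps(summary, indent=2))
    state["spatial_summary"] = summary
    return [per_grid_path, nulls_path, jpath]


def _stage_simulate_spots(params, state, out: Path, seed):
    spec = syn.SpotFieldSpec(
        image_extent=tuple(params.get("image_extent", (512.0, 512.0))),
        n_guide=params.get("n_guide", 1000),
        chromatic_shift=tuple(params.get("chromatic_shift", (0.4, -0.3))),
        localization_jitter_sd=params.get("localization_jitter_sd", 0.15),
        coloc_prob_bl6=params.get("coloc_prob_bl6", 0.3),
        coloc_prob_jf1=params.get("coloc_prob_jf1", 0.3),
        spurious_density=params.get("spurious_density", 1e-4),
        rng_seed=seed,
    )
    guide, bl6, jf1, truth = syn.gen_spot_field(spec)
    written = []
    for name, df in (("guide", guide), ("bl6", bl6), ("jf1", jf1), ("truth", truth)):
        p = out / f"spots_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    state["spots"] = (guide, bl6, jf1, truth)
    return written


def _stage_colocalize(params, state, out: Path, seed):
    guide, bl6, jf1, _ = state["spots"]
    disp = coloc.estimate_displacement(guide, bl6, window=params.get("window", 2.5))
    if params.get("scan", True):
        radius, table = coloc.select_radius(guide, bl6, jf1, displacement=disp)
        scan_path = out / "radius_scan.tsv"
        table.to_csv(scan_path, sep="\t", index=False)
        written = [scan_path]
    else:
        radius = params.get("radius", 1.0)
        written = []
    result = coloc.colocalize_spots(guide, bl6, jf1, radius, displacement=disp)
    null = coloc.pixel_shift_null(guide, bl6, jf1, radius, displacement=disp)
    result.shifted_coloc = null.overall_coloc
    apath = out / "colocalization.tsv"
    result.assignments.to_csv(apath, sep="\t", index=False)
    summary = {
        "radius": radius,
        "displacement": list(map(float, result.displacement)),
        "overall_coloc": result.overall_coloc,
        "unique_coloc": result.unique_coloc,
        "shifted_coloc": result.shifted_coloc,
    }
    jpath = out / "colocalization.json"
    jpath.write_text(json.dumps(summary, indent=2))
    state["coloc_summary"] = summary
    return written + [apath, jpath]


_STAGE_FN = {
    "simulate_counts": _stage_simulate_counts,
    "models": _stage_models,
    "simulate_tissue": _stage_simulate_tissue,
    "spatial": _stage_spatial,
    "simulate_spots": _stage_simulate_spots,
    "colocalize": _stage_colocalize,
}


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


def write_report(manifest: dict | str | Path) -> Path:
    """Render the human-readable run summary from the manifest and files."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    out = Path(manifest["out_dir"])
    lines = [
        "allelesim run report",
        "====================",
        f"root seed: {manifest['seed']}",
        f"stages: {', '.join(s['name'] for s in manifest['stages'])}",
        "",
    ]
    coloc_json = out / "colocalization.json"
    if coloc_json.exists():
        s = json.loads(coloc_json.read_text())
        lines += [
            "Colocalization",
            "--------------",
            f"radius: {s['radius']:.2f} px; displacement: "
            f"({s['displacement'][0]:+.3f}, {s['displacement'][1]:+.3f}) px",
            f"overall rate: {s['overall_coloc']:.3f}; unique: "
            f"{s['unique_coloc']:.3f}; pixel-shifted: {s['shifted_coloc']:.3f}",
            "",
        ]
    model_json = out / "model_tests.json"
    if model_json.exists():
        s = json.loads(model_json.read_text())
        lines += [
            "Allelic models",
            "--------------",
            f"pooled BL6 fraction: {s['p_bl6_hat']:.3f}; allele correlation: "
            f"{s['correlation']:.3f} ({s['n_cells']} cells)",
        ]
        for t in s["tests"]:
            verdict = "rejected" if t["rejected_95"] else "not rejected"
            lines.append(
                f"  {t['model']} ({t['statistic']}): observed "
                f"{t['observed']:.2f} at percentile {t['percentile']:.1f} "
                f"-> {verdict} (p={t['p_value']:.4f})"
            )
        lines.append("")
    else:
        lines += ["Allelic models", "--------------", "  not run", ""]
    spatial_json = out / "spatial.json"
    if spatial_json.exists():
        s = json.loads(spatial_json.read_text())
        lines += [
            "Spatial clustering",
            "------------------",
            f"estimated seed size: {s['mean_seed']:.2f} +/- {s['sd_seed']:.2f}",
            "",
        ]
    path = out / "report.txt"
    path.write_text("\n".join(lines))
    return path
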