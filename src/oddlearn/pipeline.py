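"""End-to-end orchestration: simulate -> screen -> truncate -> fit -> compare -> report.

A run is described by a configuration mapping (YAML/JSON file or dict) and
produces a run manifest recording the config snapshot, input hashes, the
per-stage seeds derived from the top-level seed, stage timings and output
paths, so a rerun of the same manifest reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import DesignSpec, GroundTruth, simulate_experiment, save_simulation
from .screening import exclude_at_chance, apply_screening, truncate_trials, screening_summary
from .model import LearningModel, ModelSpec
from .bridge import run_comparison_suite

__all__ = ["ConfigError", "default_config", "load_config", "validate_config", "run_pipeline", "render_tables"]


class ConfigError(ValueError):
    """Raised when the run configuration violates the schema."""


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "oddlearn_run",
        "input": None,                      # CSV path; None -> simulate
        "simulate": {"n_per_cell": 8, "n_blocks": 2, "trials_per_block": 210},
        "ground_truth": {},                 # overrides of GroundTruth defaults
        "screening": {"alpha": 0.05, "max_trial": 200},
        "fit": {"draws": 400, "warmup": 300, "chains": 2, "target_accept": 0.85, "lapse": 0.01},
        "comparisons": True,
    }


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = default_config()
    for key, val in (cfg or {}).items():
        if key not in merged:
            raise ConfigError(f"unknown config field: {key}")
        if isinstance(merged[key], dict) and val is not None:
            if not isinstance(val, dict):
                raise ConfigError(f"{key}: expected a mapping")
            for sub in val:
                if key in ("simulate", "ground_truth"):
                    valid = set(DesignSpec.__dataclass_fields__ if key == "simulate"
                                else GroundTruth.__dataclass_fields__)
                    if sub not in valid:
                        raise ConfigError(f"{key}.{sub}: unknown field")
                elif sub not in merged[key]:
                    raise ConfigError(f"{key}.{sub}: unknown field")
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    scr = merged["screening"]
    if not (0 < scr["alpha"] < 1):
        raise ConfigError("screening.alpha must lie in (0, 1)")
    if scr["max_trial"] is not None and scr["max_trial"] < 1:
        raise ConfigError("screening.max_trial must be >= 1 or null (all trials)")
    fit = merged["fit"]
    for f in ("draws", "warmup", "chains"):
        if fit[f] < 1:
            raise ConfigError(f"fit.{f} must be >= 1")
    return merged


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full analysis; returns the run manifest (also written to disk).

    Stages: (optional) simulation, at-chance screening over all trials,
    truncation to the analysis window, the full hierarchical model, the four
    per-age effect/null comparison pairs with bridge-sampled base-3 log
    Bayes factors, and rendered tables.  A stage failure is recorded in the
    manifest together with the completed stages' outputs.
    """
    cfg = validate_config(config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("simulate", "fit", "compare"), seed_root.spawn(3))}
    manifest = {
        "oddlearn_version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": stage_seeds,
        "config": cfg,
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        except Exception as exc:  # noqa: BLE001 - failure point recorded for resumption
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "seconds": round(time.time() - t0, 2)}
            _write_manifest(manifest, outdir)
            raise

    def _data():
        if cfg["input"] is not None:
            records = pd.read_csv(cfg["input"])
            manifest["outputs"]["input_csv"] = str(cfg["input"])
            manifest["input_sha256"] = _sha256(cfg["input"])
        else:
            design = DesignSpec(**{**cfg["simulate"], "seed": stage_seeds["simulate"]})
            truth = GroundTruth(**cfg["ground_truth"])
            records, participants = simulate_experiment(design, truth)
            sim_manifest = save_simulation(records, participants, outdir, design, truth)
            manifest["outputs"]["trials_csv"] = sim_manifest["trials_csv"]
            manifest["outputs"]["ground_truth_csv"] = sim_manifest["ground_truth_csv"]
            manifest["input_sha256"] = _sha256(sim_manifest["trials_csv"])
        state["records"] = records

    def _screen():
        scr = exclude_at_chance(state["records"], alpha=cfg["screening"]["alpha"])
        scr.to_csv(outdir / "screening.csv", index=False)
        screening_summary(scr, state["records"]).to_csv(outdir / "sample_sizes.csv")
        manifest["outputs"]["screening_csv"] = str(outdir / "screening.csv")
        manifest["outputs"]["sample_sizes_csv"] = str(outdir / "sample_sizes.csv")
        kept = apply_screening(state["records"], scr)
        state["modelled"] = truncate_trials(kept, cfg["screening"]["max_trial"])
        manifest["n_included"] = int(scr["included"].sum())
        manifest["n_screened_out"] = int((~scr["included"]).sum())

    def _fit_full():
        fit_cfg = cfg["fit"]
        model = LearningModel(state["modelled"], ModelSpec.full(lapse=fit_cfg["lapse"]))
        res = model.fit(draws=fit_cfg["draws"], warmup=fit_cfg["warmup"], chains=fit_cfg["chains"],
                        seed=stage_seeds["fit"], target_accept=fit_cfg["target_accept"])
        state["full_fit"] = res
        state["tables"] = {"full_model": res.summary()}
        state["diagnostics"] = {"full": res.diagnostics()}
        mag = res.learning_magnitude()
        mag["contrasts"].to_csv(outdir / "learning_magnitude_contrasts.csv", index=False)
        manifest["outputs"]["learning_magnitude_csv"] = str(outdir / "learning_magnitude_contrasts.csv")

    def _compare():
        if not cfg["comparisons"]:
            state["comparisons"] = []
            return
        fit_cfg = cfg["fit"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparisons, fits = run_comparison_suite(
                state["modelled"], draws=fit_cfg["draws"], warmup=fit_cfg["warmup"],
                chains=fit_cfg["chains"], seed=stage_seeds["compare"],
                target_accept=fit_cfg["target_accept"], lapse=fit_cfg["lapse"],
            )
        state["comparisons"] = comparisons
        for label, fit in fits.items():
            if not label.endswith("-null"):
                state["tables"][label.replace("-", "_")] = fit.summary()
                state["diagnostics"][label] = fit.diagnostics()

    def _report():
        paths = render_tables(state.get("tables", {}), state.get("comparisons", []), outdir)
        manifest["outputs"].update(paths)
        manifest["diagnostics"] = state.get("diagnostics", {})

    run_stage("data", _data)
    run_stage("screen", _screen)
    run_stage("fit_full", _fit_full)
    run_stage("compare", _compare)
    run_stage("report", _report)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def render_tables(tables: dict, comparisons: list, outdir) -> dict:
    """Write coefficient tables (CSV) and the comparison report (JSON + text).

    Coefficient tables carry the columns ``Estimate / lower 95% CI /
    upper 95% CI / reliable``; every cell comes straight from the stored
    posterior summaries (no recomputation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        out = table.copy()
        out["reliable"] = np.where(out["reliable"], "*", "")
        path = outdir / f"coefficients_{name}.csv"
        out.to_csv(path, index_label="coefficient")
        paths[f"coefficients_{name}"] = str(path)

    comp_dicts = [c.to_dict() for c in comparisons]
    comp_path = outdir / "comparisons.json"
    with open(comp_path, "w") as fh:
        json.dump(comp_dicts, fh, indent=2)
    paths["comparisons_json"] = str(comp_path)

    lines = []
    if not comp_dicts:
        lines.append("No model comparisons were run.")
    for c in comp_dicts:
        lines.append(
            f"{c['label']}: log3(BF) = {c['log3_bf']:+.2f} (MC error {c['mc_error']:.2f}) -> {c['verdict']}"
        )
    report_path = outdir / "comparison_report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    paths["comparison_report"] = str(report_path)
    return paths
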