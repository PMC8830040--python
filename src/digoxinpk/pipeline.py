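"""End-to-end analysis pipeline: generate/load -> fit -> select -> evaluate
-> simulate, with a manifest making every run reproducible.

Each stage draws its randomness from a sub-seed derived as a stable hash
of (global seed, stage name), so re-running one stage reproduces its
artifact and adding a stage never perturbs the others' streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data import read_dataset, write_dataset
from .evaluation import BootstrapSummary, bootstrap, gof_table
from .nlme import FitResult, compare_error_models, fit_population
from .selection import (DEFAULT_CANDIDATES, DEFAULT_COLLINEAR,
                        DEFAULT_PRIORITY, forward_select)
from .simulation import dosing_grid, grid_report
from .structural import base_digoxin_model, final_digoxin_model
from .synthetic import CohortConfig, generate_dataset

__all__ = ["RunConfig", "run_full_analysis", "report_final_model", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across platforms, < 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full analysis run (YAML/JSON serialisable)."""

    output_dir: str = "results"
    dataset_path: str | None = None       # read this CSV ...
    generate: bool = False                # ... or generate synthetically
    n_patients: int = 391
    seed: int = 0
    method: str = "agq"
    nodes: int = 21
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    threshold: float = 3.84
    run_selection: bool = True
    run_gof: bool = True
    bootstrap_n: int = 1000
    run_bootstrap: bool = True
    run_simulation: bool = True
    sim_n_draws: int = 100_000
    sim_weight: float = 57.0
    sim_include_residual: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "candidates" in d:
            d["candidates"] = tuple(d["candidates"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidates"] = list(d["candidates"])
        return d


def report_final_model(fit: FitResult,
                       bootstrap_summary: BootstrapSummary | None = None) -> str:
    """Human-readable final-model table: estimate, RSE%, bootstrap mean and
    95% CI per parameter, fixed parameters marked."""
    labels = {"tv_cl": "CL/F, L/h", "beta_clcr": "CLcr on CL/F",
              "beta_amiodarone": "Amiodarone on CL/F",
              "beta_egfr": "eGFR on CL/F", "beta_age": "Age on CL/F",
              "beta_bmi": "BMI on CL/F", "beta_sex": "Female on CL/F",
              "beta_diltiazem": "Diltiazem on CL/F",
              "beta_verapamil": "Verapamil on CL/F",
              "omega_cl": "IIV omega CL/F (SD scale)",
              "sigma": "Residual sigma"}
    bp = bootstrap_summary.params if bootstrap_summary is not None else None
    if bp is not None:
        missing = [p for p in fit.estimates if p not in bp.index]
        if missing:
            raise ValueError(f"bootstrap summary lacks parameter(s) {missing}")
    rows = [f"{'Parameter':<28} {'Estimate':>9} {'RSE %':>7} "
            f"{'Boot mean':>10} {'95% CI':>19}"]
    for name, est in fit.estimates.items():
        rse = fit.rse.get(name)
        rse_s = f"{rse:7.1f}" if rse is not None else f"{'NA':>7}"
        if bp is not None:
            row = bp.loc[name]
            bs = f"{row['mean']:10.3f} {row['ci_lower']:8.3f}-{row['ci_upper']:8.3f}"
        else:
            bs = f"{'NA':>10} {'NA':>19}"
        rows.append(f"{labels.get(name, name):<28} {est:9.3f} {rse_s} {bs}")
    rows.append(f"{'Vd/F, L/kg (fixed)':<28} {fit.model.vd_per_kg:9.3f} {'NA':>7}")
    rows.append(f"{'ka, 1/h (fixed)':<28} {fit.model.ka:9.3f} {'NA':>7}")
    rows.append(f"OFV {fit.ofv:.3f}  ({fit.n_patients} patients, "
                f"{fit.n_obs} observations)")
    return "\n".join(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every enabled stage, writing one artifact per stage plus a
    manifest; returns the manifest dict.  A stage failure aborts with a
    stage-named error after writing the partial manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": {},
        "stages": {},
    }

    def finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            info = fn() or {}
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        finish_stage(name, t0, **info)

    state: dict = {}

    def s_data():
        if config.generate:
            sd = stage_seed(config.seed, "generate")
            manifest["stage_seeds"]["generate"] = sd
            cohort = CohortConfig(n_patients=config.n_patients)
            ds = generate_dataset(final_digoxin_model(), cohort, seed=sd)
            write_dataset(ds, out / "dataset.csv")
        elif config.dataset_path:
            ds = read_dataset(config.dataset_path)
        else:
            raise FileNotFoundError(
                "no input: set dataset_path or enable generation")
        state["data"] = ds
        return {"n_patients": ds.n_patients, "n_observations": ds.n_observations}

    def s_base():
        chosen, ofvs, fits = compare_error_models(
            state["data"], base_digoxin_model(), method=config.method,
            nodes=config.nodes)
        state["base_fit"] = fits[chosen]
        with open(out / "error_model.json", "w") as fh:
            json.dump({"chosen": chosen, "ofv": ofvs}, fh, indent=2)
        return {"chosen_error_model": chosen, "ofv": ofvs}

    def s_select():
        trace = forward_select(
            state["base_fit"].model, config.candidates, state["data"],
            threshold=config.threshold, method=config.method,
            nodes=config.nodes)
        state["final_fit"] = trace.final_fit
        trace.to_json(out / "selection_trace.json")
        (out / "selection_report.txt").write_text(trace.report() + "\n")
        return {"selected": trace.selected, "final_ofv": trace.final_fit.ofv}

    def s_gof():
        fit = state.get("final_fit", state["base_fit"])
        gof = gof_table(fit, state["data"])
        gof.to_csv(out / "gof.csv", index=False)
        return {"n": len(gof),
                "cwres_mean": float(gof["cwres"].mean()),
                "cwres_sd": float(gof["cwres"].std())}

    def s_bootstrap():
        fit = state.get("final_fit", state["base_fit"])
        sd = stage_seed(config.seed, "bootstrap")
        manifest["stage_seeds"]["bootstrap"] = sd
        bs = bootstrap(state["data"], fit.model, n=config.bootstrap_n,
                       seed=sd, init=dict(fit.estimates),
                       method=config.method, nodes=config.nodes)
        state["bootstrap"] = bs
        bs.to_json(out / "bootstrap.json")
        return {"success_rate": bs.success_rate}

    def s_report():
        fit = state.get("final_fit", state["base_fit"])
        text = report_final_model(fit, state.get("bootstrap"))
        (out / "final_model.txt").write_text(text + "\n")
        with open(out / "fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        return {}

    def s_simulate():
        fit = state.get("final_fit", state["base_fit"])
        sd = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sd
        grid = dosing_grid(fit.model, n_draws=config.sim_n_draws, seed=sd,
                           weight=config.sim_weight,
                           include_residual=config.sim_include_residual)
        grid.to_csv(out / "dosing_grid.csv", index=False)
        (out / "dosing_grid.txt").write_text(grid_report(grid) + "\n")
        return {"cells": len(grid)}

    run_stage("data", s_data)
    run_stage("base_fit", s_base)
    if config.run_selection:
        run_stage("selection", s_select)
    if config.run_gof:
        run_stage("gof", s_gof)
    if config.run_bootstrap:
        run_stage("bootstrap", s_bootstrap)
    run_stage("report", s_report)
    if config.run_simulation:
        run_stage("simulation", s_simulate)
    return manifest
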