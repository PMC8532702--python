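"""Pipeline stages and the run manifest.

Stages (generate -> fit -> vpc/bootstrap -> pta) can be run individually or
as ``full``; every stage records its seed and input hashes in
``manifest.json`` so any table can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import read_dataset, write_dataset
from .diagnostics import bootstrap, gof, pc_vpc
from .dosing import (
    AUC_TARGET,
    TROUGH_TARGET,
    default_grid,
    paper_strata,
    recommend,
)
from .estimation import FINAL_STRUCTURE, FitResult, fit
from .pk_core import PopulationModel
from .synthetic import CohortSpec, default_table1_spec, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("generate", "fit", "vpc", "bootstrap", "pta", "full")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """What to run and where to put it."""

    stage: str = "full"
    out_dir: str = "vancopk_run"
    seed: int = 0
    dataset: str | None = None  # input CSV for fit/vpc/bootstrap
    model: str | None = None  # YAML population model for pta (else fitted/default)
    n_subjects: int = 209
    n_sim_vpc: int = 1000
    n_bootstrap: int = 200
    n_sim_pta: int = 10_000
    target: str = "auc24"  # "auc24" | "trough"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")
        needs_data = self.stage in ("fit", "vpc", "bootstrap")
        if needs_data and not self.dataset:
            raise ConfigError(f"stage {self.stage!r} requires a dataset path")
        for p in (self.dataset, self.model):
            if p and not Path(p).exists():
                raise ConfigError(f"path not found: {p}")
        if self.target not in ("auc24", "trough"):
            raise ConfigError("target must be auc24 or trough")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_report(res: FitResult) -> dict:
    return {
        "theta": res.theta,
        "omega2": res.omega2,
        "sigma2": res.sigma2,
        "ofv": res.ofv,
        "aic": res.aic,
        "n_params": res.n_params,
        "converged": res.converged,
        "rse_pct": res.rse,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage(s); returns {stage: artifact paths}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage": config.stage,
        "inputs": {},
        "outputs": {},
    }
    bundle: dict = {"manifest": str(out / "manifest.json")}
    stages = (
        ["generate", "fit", "vpc", "bootstrap", "pta"]
        if config.stage == "full"
        else [config.stage]
    )
    subjects = None
    fitted: FitResult | None = None
    try:
        if config.dataset:
            manifest["inputs"]["dataset"] = _sha256(Path(config.dataset))
            subjects = read_dataset(config.dataset)

        if "generate" in stages:
            spec = default_table1_spec(seed=config.seed)
            if config.n_subjects != spec.n_subjects:
                from dataclasses import replace
                spec = replace(spec, n_subjects=config.n_subjects)
            subjects = generate_cohort(spec)
            data_path = out / "cohort.csv"
            write_dataset(subjects, data_path)
            spec.to_yaml(out / "cohort_spec.yaml")
            manifest["outputs"]["cohort"] = _sha256(data_path)
            bundle["generate"] = str(data_path)

        if "fit" in stages:
            if subjects is None:
                raise ConfigError("fit stage has no dataset")
            fitted = fit(subjects, FINAL_STRUCTURE)
            report = _fit_report(fitted)
            (out / "fit.json").write_text(json.dumps(report, indent=2))
            rows = [{"parameter": k, "estimate": v, "rse_pct": fitted.rse.get(k)}
                    for k, v in {**fitted.theta,
                                 "omega2_cl": fitted.omega2["cl"],
                                 "omega2_vc": fitted.omega2["vc"],
                                 "sigma2": fitted.sigma2}.items()]
            pd.DataFrame(rows).to_csv(out / "parameters.tsv", sep="\t", index=False)
            gof(subjects, fitted).to_csv(out / "gof.tsv", sep="\t", index=False)
            bundle["fit"] = str(out / "fit.json")

        if "vpc" in stages:
            if fitted is None:
                fitted = fit(subjects, FINAL_STRUCTURE, compute_rse=False)
            vpc = pc_vpc(subjects, fitted, n_sim=config.n_sim_vpc, seed=config.seed)
            rows = [{
                "tad_low": b.tad_low, "tad_high": b.tad_high, "n_obs": b.n_obs,
                "obs_p5": b.obs_p5, "obs_p50": b.obs_p50, "obs_p95": b.obs_p95,
                **{f"sim_{k}_{side}": b.sim_ci[k][i]
                   for k in ("p5", "p50", "p95")
                   for i, side in enumerate(("lo", "hi"))},
            } for b in vpc["bins"]]
            pd.DataFrame(rows).to_csv(out / "vpc.tsv", sep="\t", index=False)
            bundle["vpc"] = str(out / "vpc.tsv")

        if "bootstrap" in stages:
            bs = bootstrap(subjects, FINAL_STRUCTURE,
                           n_replicates=config.n_bootstrap, seed=config.seed)
            rows = [{"parameter": k, **v} for k, v in bs["summary"].items()]
            pd.DataFrame(rows).to_csv(out / "bootstrap.tsv", sep="\t", index=False)
            (out / "bootstrap.json").write_text(json.dumps(
                {"success_rate": bs["success_rate"],
                 "n_success": bs["n_success"],
                 "n_replicates": bs["n_replicates"],
                 "summary": bs["summary"]}, indent=2))
            bundle["bootstrap"] = str(out / "bootstrap.tsv")

        if "pta" in stages:
            if config.model:
                model = PopulationModel.from_yaml(config.model)
                manifest["inputs"]["model"] = _sha256(Path(config.model))
            elif fitted is not None:
                model = fitted.population_model()
            else:
                model = PopulationModel()
            target = AUC_TARGET if config.target == "auc24" else TROUGH_TARGET
            table = recommend(
                paper_strata(merge_arc_tail=True), default_grid(), target,
                model, n_sim=config.n_sim_pta, seed=config.seed,
            )
            table.to_csv(out / "recommended_regimens.tsv", sep="\t", index=False)
            bundle["pta"] = str(out / "recommended_regimens.tsv")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
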