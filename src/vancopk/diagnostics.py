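"""Model qualification: goodness-of-fit records, nonparametric bootstrap, and
the prediction-corrected visual predictive check (pc-VPC).

Conditional weighted residuals (CWRES) use the same first-order-conditional
linearization as the estimation objective: per subject the marginal mean is
f(eta_hat) - G eta_hat and the marginal covariance G Omega G' + R(eta_hat),
with R the proportional residual variance evaluated at the conditional mode;
CWRES are the Cholesky-whitened residuals and are approximately standard
normal when the model is right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Subject
from .estimation import (
    CompiledDesign,
    FitResult,
    _foce_pieces,
    compile_design,
    fit as _fit,
)

__all__ = ["gof", "bootstrap", "pc_vpc", "VpcBin"]


def _pieces_for(design: CompiledDesign, res: FitResult):
    theta = dict(res.theta)
    omega2 = (res.omega2["cl"], res.omega2["vc"])
    pieces = _foce_pieces(design, res.structure, theta, omega2, res.sigma2)
    if pieces is None:
        raise ValueError("model evaluation failed at the fitted parameters")
    return pieces


def gof(subjects, res: FitResult) -> pd.DataFrame:
    """Goodness-of-fit table: PRED (eta = 0), IPRED (eta = eta_hat), CWRES
    and time after dose for every observation.

    Records with non-finite predictions are flagged (``ok = False``) and
    should be excluded from summaries.
    """
    design = compile_design(subjects)
    pieces = _pieces_for(design, res)
    eta = pieces["eta"]
    from .estimation import _predict  # typical and individual predictions

    pred = _predict(design, pieces["cl_typ"], pieces["vc_typ"], pieces["q"], pieces["vp"])
    ipred = pieces["f"]
    G = pieces["G"]
    omega = np.diag([res.omega2["cl"], res.omega2["vc"]])
    cwres = np.full(design.n_obs, np.nan)
    for i in range(design.n_subjects):
        idx = np.flatnonzero(design.obs_subject == i)
        Gi = G[idx]
        fi = ipred[idx]
        yi = design.y[idx]
        Ri = np.diag(res.sigma2 * fi**2)
        Ci = Gi @ omega @ Gi.T + Ri
        mean = fi - Gi @ eta[i]
        try:
            L = np.linalg.cholesky(Ci)
            cwres[idx] = np.linalg.solve(L, yi - mean)
        except np.linalg.LinAlgError:
            pass
    tad = np.concatenate([s.time_after_dose() for s in subjects if s.n_obs > 0])
    df = pd.DataFrame({
        "id": design.subject_ids[design.obs_subject],
        "time": design.obs_time,
        "tad": tad,
        "dv": design.y,
        "pred": pred,
        "ipred": ipred,
        "cwres": cwres,
    })
    df["ok"] = np.isfinite(df["pred"]) & np.isfinite(df["ipred"]) & np.isfinite(df["cwres"])
    return df


def bootstrap(
    subjects,
    structure=None,
    n_replicates: int = 1000,
    seed: int | None = None,
    inits=None,
    **fit_kwargs,
) -> dict:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    A replicate is successful when the refit converges with finite estimates;
    parameter medians and percentile 95% CIs are computed over successful
    replicates only.  Standard errors are not re-derived per replicate (the
    percentile intervals are the product), so success is convergence-based.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .estimation import FINAL_STRUCTURE

    structure = structure or FINAL_STRUCTURE
    fit_kwargs.setdefault("compute_rse", False)
    subjects = [s for s in subjects if s.n_obs > 0]
    rng = np.random.default_rng(seed)
    n = len(subjects)
    rows = []
    n_success = 0
    all_indices = []
    for rep in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        all_indices.append(idx)
        resampled = [
            Subject(id=j + 1, covariates=subjects[i].covariates,
                    doses=subjects[i].doses, obs_times=subjects[i].obs_times,
                    obs_dv=subjects[i].obs_dv)
            for j, i in enumerate(idx)
        ]
        try:
            r = _fit(resampled, structure, inits, **fit_kwargs)
        except Exception as exc:
            warnings.warn(f"bootstrap replicate {rep} failed: {exc}")
            continue
        values = {**r.theta, "omega2_cl": r.omega2["cl"],
                  "omega2_vc": r.omega2["vc"], "sigma2": r.sigma2}
        success = r.converged and all(np.isfinite(v) for v in values.values())
        if success:
            n_success += 1
            rows.append(values)
    success_rate = n_success / n_replicates
    if success_rate < 0.5:
        warnings.warn(f"bootstrap success rate {100 * success_rate:.1f}% is below 50%")
    table = pd.DataFrame(rows)
    summary = {}
    for col in table.columns:
        v = table[col].to_numpy()
        summary[col] = {
            "median": float(np.median(v)),
            "ci_low": float(np.percentile(v, 2.5)),
            "ci_high": float(np.percentile(v, 97.5)),
        }
    return {
        "summary": summary,
        "replicates": table,
        "success_rate": success_rate,
        "n_success": n_success,
        "n_replicates": n_replicates,
        "resample_indices": np.array(all_indices),
    }


@dataclass(frozen=True)
class VpcBin:
    """One time-after-dose bin of the pc-VPC."""

    tad_low: float
    tad_high: float
    n_obs: int
    obs_p5: float
    obs_p50: float
    obs_p95: float
    sim_ci: dict  # {"p5": (lo, hi), "p50": (lo, hi), "p95": (lo, hi)}

    def observed_inside(self) -> dict:
        return {
            k: self.sim_ci[k][0] <= v <= self.sim_ci[k][1]
            for k, v in (("p5", self.obs_p5), ("p50", self.obs_p50), ("p95", self.obs_p95))
        }


def pc_vpc(
    subjects,
    res: FitResult,
    n_sim: int = 1000,
    n_bins: int = 8,
    seed: int | None = None,
    ci: float = 90.0,
) -> dict:
    """Prediction-corrected visual predictive check.

    Observed and simulated concentrations are rescaled by
    bin-median(PRED) / PRED, binned on time after dose (equal-count bins),
    and the observed 5/50/95th percentiles are compared with the ``ci``%%
    interval of the same percentiles over ``n_sim`` datasets simulated from
    the fitted model on the original design.
    """
    design = compile_design(subjects)
    pieces = _pieces_for(design, res)
    from .estimation import _predict_eta

    cl_typ, vc_typ, q, vp = pieces["cl_typ"], pieces["vc_typ"], pieces["q"], pieces["vp"]
    pred = _predict_eta(design, cl_typ, vc_typ, q, vp, np.zeros((design.n_subjects, 2)))
    usable = pred > 0
    if not np.all(usable):
        warnings.warn(f"{np.sum(~usable)} record(s) with PRED = 0 excluded from the VPC")
    tad = np.concatenate([s.time_after_dose() for s in subjects if s.n_obs > 0])

    # equal-count bins on TAD
    order = np.argsort(tad[usable], kind="stable")
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(tad[usable], qs)
    edges[0] -= 1e-9
    edges = np.unique(edges)
    bin_of = np.digitize(tad, edges[1:-1], right=True)

    # prediction correction factor per record
    pc_factor = np.ones(design.n_obs)
    for b in range(len(edges) - 1):
        m = usable & (bin_of == b)
        if m.any():
            pc_factor[m] = np.median(pred[m]) / pred[m]

    def percentiles(values):
        out = np.full((len(edges) - 1, 3), np.nan)
        for b in range(len(edges) - 1):
            m = usable & (bin_of == b)
            if m.any():
                out[b] = np.percentile(values[m] * pc_factor[m], [5, 50, 95])
        return out

    obs_pct = percentiles(design.y)

    rng = np.random.default_rng(seed)
    sim_pct = np.empty((n_sim, len(edges) - 1, 3))
    w1 = np.sqrt(res.omega2["cl"])
    w2 = np.sqrt(res.omega2["vc"])
    sd = np.sqrt(res.sigma2)
    for k in range(n_sim):
        eta = np.column_stack([
            rng.normal(0, w1, design.n_subjects),
            rng.normal(0, w2, design.n_subjects),
        ])
        f = _predict_eta(design, cl_typ, vc_typ, q, vp, eta)
        ysim = np.maximum(f * (1.0 + rng.normal(0, sd, design.n_obs)), 0.0)
        sim_pct[k] = percentiles(ysim)

    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    bins = []
    inside = 0
    total = 0
    for b in range(len(edges) - 1):
        ci_d = {}
        for j, name in enumerate(("p5", "p50", "p95")):
            ci_d[name] = (
                float(np.percentile(sim_pct[:, b, j], lo_q)),
                float(np.percentile(sim_pct[:, b, j], hi_q)),
            )
        vb = VpcBin(
            tad_low=float(edges[b]), tad_high=float(edges[b + 1]),
            n_obs=int(np.sum(usable & (bin_of == b))),
            obs_p5=float(obs_pct[b, 0]), obs_p50=float(obs_pct[b, 1]),
            obs_p95=float(obs_pct[b, 2]),
            sim_ci=ci_d,
        )
        bins.append(vb)
        for hit in vb.observed_inside().values():
            inside += hit
            total += 1
    return {"bins": bins, "coverage": inside / total if total else float("nan")}
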