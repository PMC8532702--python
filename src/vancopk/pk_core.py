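"""Deterministic pharmacokinetic engine for vancomycin.

Covariate models (saturable renal-function effect on clearance, ICU shift on
central volume), individual parameter realization with lognormal
inter-individual variability, closed-form two-compartment zero-order-infusion
kinetics with superposition over dosing histories, and steady-state exposure
metrics (AUC over 24 h, trough concentration).

Concentrations are mg/L, amounts mg, times h, volumes L, clearances L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Covariates",
    "PopulationModel",
    "PKParameters",
    "Regimen",
    "DoseEvent",
    "cockcroft_gault",
    "clearance_typical",
    "vc_typical",
    "realize_individual",
    "concentration",
    "auc24_steady_state",
    "trough_steady_state",
    "default_infusion_duration",
]

#: serum creatinine unit conversion: 1 mg/dL = 88.4 umol/L
UMOL_PER_MGDL = 88.4

#: relative root separation below which the repeated-root limit form is used
_DEGENERATE_TOL = 1e-9


class InvalidCovariateError(ValueError):
    """Raised for physiologically impossible covariate values."""


@dataclass(frozen=True)
class Covariates:
    """Per-patient covariates.

    ``scr`` may be given in mg/dL or umol/L; ``scr_unit`` must say which.
    ``clcr`` (creatinine clearance, mL/min) may be supplied directly, in which
    case ``scr`` is optional; otherwise it is derived by Cockcroft-Gault.
    """

    age: float
    sex: str  # "male" | "female"
    tbw: float  # total body weight, kg
    scr: float | None = None
    scr_unit: str = "mg/dL"
    icu: bool = False
    clcr: float | None = None
    shock: bool = False
    mof: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidCovariateError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise InvalidCovariateError(f"adult cohort only: age {self.age} < 18")
        if self.tbw <= 0:
            raise InvalidCovariateError(f"non-positive body weight {self.tbw}")
        if self.scr is None and self.clcr is None:
            raise InvalidCovariateError("either scr or clcr must be provided")
        if self.scr is not None and self.scr <= 0:
            raise InvalidCovariateError(f"non-positive serum creatinine {self.scr}")
        if self.scr_unit not in ("mg/dL", "umol/L"):
            raise InvalidCovariateError(f"unknown creatinine unit {self.scr_unit!r}")

    @property
    def scr_mgdl(self) -> float | None:
        """Serum creatinine in mg/dL regardless of the input unit."""
        if self.scr is None:
            return None
        return self.scr / UMOL_PER_MGDL if self.scr_unit == "umol/L" else self.scr

    def creatinine_clearance(self) -> float:
        """CLcr in mL/min: the supplied value, else Cockcroft-Gault."""
        if self.clcr is not None:
            return self.clcr
        return cockcroft_gault(self)

    def in_model_support(self, low: float = 18.4, high: float = 390.7) -> bool:
        """Whether CLcr lies in the renal-function range the model was built on."""
        return low <= self.creatinine_clearance() <= high


def cockcroft_gault(cov: Covariates) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault equation.

    CLcr = (140 - age) * TBW / (72 * SCr[mg/dL]), times 0.85 for women.
    """
    scr = cov.scr_mgdl
    if scr is None or scr <= 0:
        raise InvalidCovariateError("Cockcroft-Gault needs a positive serum creatinine")
    clcr = (140.0 - cov.age) * cov.tbw / (72.0 * scr)
    if cov.sex == "female":
        clcr *= 0.85
    return clcr


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, inter-individual variances and residual variance.

    Defaults are the final-model population estimates: a saturable (Hill)
    dependence of clearance on creatinine clearance with maximum ``cl_max``,
    half-maximal point ``cg50`` and steepness ``s``; a central volume that
    differs between non-ICU and ICU patients; first-order inter-compartmental
    clearance ``q`` into a peripheral volume ``vp``.  ``omega2_*`` are the
    variances of the lognormal random effects on CL and Vc; ``sigma2`` is the
    variance of the proportional residual error.
    """

    cl_max: float = 5.58  # L/h
    cg50: float = 93.8  # mL/min
    s: float = 1.5
    vc_non_icu: float = 8.02  # L
    vc_icu: float = 35.7  # L
    q: float = 2.66  # L/h
    vp: float = 36.8  # L
    omega2_cl: float = 0.0771
    omega2_vc: float = 0.223
    sigma2: float = 0.0466

    def __post_init__(self) -> None:
        for name in ("cl_max", "cg50", "s", "vc_non_icu", "vc_icu", "vp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")
        for name in ("omega2_cl", "omega2_vc", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return {
            "cl_max": self.cl_max, "cg50": self.cg50, "s": self.s,
            "vc_non_icu": self.vc_non_icu, "vc_icu": self.vc_icu,
            "q": self.q, "vp": self.vp,
            "omega2_cl": self.omega2_cl, "omega2_vc": self.omega2_vc,
            "sigma2": self.sigma2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PKParameters:
    """Realized individual parameters of the two-compartment model."""

    cl: float  # elimination clearance, L/h
    vc: float  # central volume, L
    q: float  # inter-compartmental clearance, L/h
    vp: float  # peripheral volume, L

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.vc <= 0 or self.vp <= 0 or self.q < 0:
            raise ValueError("pharmacokinetic parameters must be positive (q >= 0)")


@dataclass(frozen=True, order=True)
class DoseEvent:
    """One zero-order intravenous infusion."""

    start_time: float  # h
    amount: float  # mg
    duration: float  # h

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


def default_infusion_duration(dose: float) -> float:
    """Infusion duration policy: 1 h, extended to 2 h for doses >= 1500 mg."""
    return 2.0 if dose >= 1500.0 else 1.0


@dataclass(frozen=True)
class Regimen:
    """Maintenance regimen: `dose` mg every `interval` h over `infusion_duration` h."""

    dose: float
    interval: float
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        dur = self.infusion_duration
        if dur is None:
            object.__setattr__(self, "infusion_duration", default_infusion_duration(self.dose))
            dur = self.infusion_duration
        if dur <= 0 or dur >= self.interval:
            raise ValueError("infusion duration must lie in (0, interval)")

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.interval

    def events(self, n_doses: int, start: float = 0.0) -> list[DoseEvent]:
        return [
            DoseEvent(start + i * self.interval, self.dose, self.infusion_duration)
            for i in range(n_doses)
        ]


# ---------------------------------------------------------------------------
# covariate models


def clearance_typical(clcr, model: PopulationModel):
    """Typical (eta = 0) vancomycin clearance at creatinine clearance ``clcr``.

    Saturable Hill relationship CLmax * CLcr^s / (CG50^s + CLcr^s): strictly
    increasing in CLcr, half-maximal at CG50, asymptote CLmax.
    Accepts scalars or arrays.
    """
    clcr = np.asarray(clcr, dtype=float)
    if np.any(clcr <= 0):
        raise ValueError("creatinine clearance must be positive")
    num = clcr ** model.s
    out = model.cl_max * num / (model.cg50 ** model.s + num)
    return float(out) if out.ndim == 0 else out


def vc_typical(icu, model: PopulationModel):
    """Typical central volume of distribution: ICU vs non-ICU."""
    icu = np.asarray(icu)
    out = np.where(icu, model.vc_icu, model.vc_non_icu)
    return float(out) if out.ndim == 0 else out


def realize_individual(
    cov: Covariates, model: PopulationModel, eta1: float = 0.0, eta2: float = 0.0
) -> PKParameters:
    """Individual parameters: typical values times exp(eta) random effects."""
    if not (np.isfinite(eta1) and np.isfinite(eta2)):
        raise ValueError("random effects must be finite")
    cl = clearance_typical(cov.creatinine_clearance(), model) * np.exp(eta1)
    vc = vc_typical(cov.icu, model) * np.exp(eta2)
    return PKParameters(cl=float(cl), vc=float(vc), q=model.q, vp=model.vp)


# ---------------------------------------------------------------------------
# disposition: hybrid rate constants and infusion response


def disposition_constants(cl: float, vc: float, q: float, vp: float):
    """Hybrid rate constants (alpha, beta) and bolus coefficients (A, B).

    Unit-bolus central concentration is (1/vc) * (A e^{-alpha t} + B e^{-beta t}).
    With q = 0 the model collapses to one compartment: beta term vanishes.
    """
    k10 = cl / vc
    if q == 0.0:
        return k10, 0.0, 1.0, 0.0
    k12 = q / vc
    k21 = q / vp
    ssum = k10 + k12 + k21
    disc = np.sqrt(max(ssum * ssum - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (ssum + disc)
    beta = 0.5 * (ssum - disc)
    if alpha - beta < _DEGENERATE_TOL * alpha:
        # repeated root; caller switches to the limit form
        return alpha, beta, np.nan, np.nan
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return alpha, beta, A, B


def _cum_exp(t, lam):
    """Integral of exp(-lam u) from 0 to t (t >= 0)."""
    return -np.expm1(-lam * t) / lam


def _cum_texp(t, lam):
    """Integral of u exp(-lam u) from 0 to t."""
    return (-np.expm1(-lam * t) - lam * t * np.exp(-lam * t)) / (lam * lam)


def concentration(t, events: Sequence[DoseEvent], p: PKParameters):
    """Central-compartment concentration at time(s) ``t`` under a dosing history.

    Closed-form superposition of zero-order-infusion two-compartment
    responses; linear in dose.  ``t`` may be a scalar or array; events need
    not be sorted.  Times before the first infusion give 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    alpha, beta, A, B = disposition_constants(p.cl, p.vc, p.q, p.vp)
    degenerate = not np.isfinite(A)
    if degenerate:
        lam = 0.5 * (alpha + beta)
        k21 = p.q / p.vp
        m = k21 - lam
    for ev in events:
        tau = t_arr - ev.start_time
        active = tau > 0.0
        if not np.any(active):
            continue
        ta = tau[active]
        te = np.minimum(ta, ev.duration)
        post = np.maximum(ta - ev.duration, 0.0)
        if degenerate:
            # limit alpha -> beta = lam: bolus response e^{-lam u}(1 + (k21-lam) u)
            def H(x):
                return _cum_exp(x, lam) + m * _cum_texp(x, lam)
            resp = H(ta) - np.where(ta > ev.duration, H(ta - ev.duration), 0.0)
        else:
            resp = A * _cum_exp(te, alpha) * np.exp(-alpha * post)
            if B != 0.0:
                resp = resp + B * _cum_exp(te, beta) * np.exp(-beta * post)
        out[active] += ev.rate / p.vc * resp
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# steady-state exposure metrics


def auc24_steady_state(reg: Regimen, p: PKParameters) -> float:
    """Steady-state 24-h AUC (mg.h/L).

    For linear kinetics the steady-state AUC over one interval equals
    dose / CL, so AUC24 = daily dose / CL exactly.
    """
    return reg.daily_dose / p.cl


def trough_steady_state(reg: Regimen, p: PKParameters) -> float:
    """Steady-state trough: concentration at the end of a dosing interval.

    Uses the geometric-series accumulation factor 1/(1 - e^{-lam tau}) of each
    exponential disposition term (evaluated post-infusion at t = interval).
    """
    tau = reg.interval
    T = reg.infusion_duration
    rate = reg.dose / T
    alpha, beta, A, B = disposition_constants(p.cl, p.vc, p.q, p.vp)
    if not np.isfinite(A):  # repeated root
        lam = 0.5 * (alpha + beta)
        m = (p.q / p.vp) - lam
        # post-infusion single-dose response at u >= T: e^{-lam u} (pc + qc u)
        g = np.expm1(lam * T)  # e^{lam T} - 1
        qc = m / lam * g
        pc = g / lam + m / lam**2 * (g - lam * T * np.exp(lam * T))
        E = np.exp(-lam * tau)
        acc = pc * E / (1.0 - E) + qc * tau * E / (1.0 - E) ** 2
        return rate / p.vc * acc
    total = A / alpha * (-np.expm1(-alpha * T)) * np.exp(-alpha * (tau - T)) / (-np.expm1(-alpha * tau))
    if B != 0.0:
        total += B / beta * (-np.expm1(-beta * T)) * np.exp(-beta * (tau - T)) / (-np.expm1(-beta * tau))
    return rate / p.vc * total
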