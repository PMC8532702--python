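"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's concentrations is approximated by
the first-order conditional method: the joint density of data and random
effects is maximized over the two lognormal random effects (on clearance and
central volume) by a damped Newton search, the prediction function is
linearized around that conditional mode, and the proportional residual
variance is evaluated at the mode (the "interaction" term).  The objective
function value (OFV) is the resulting -2 log-likelihood, including the
2*pi constants, summed over subjects.

Model structures are described by :class:`ModelStructure`: one or two
disposition compartments plus covariate effects on clearance and central
volume (saturable/linear/power/exponential forms in a continuous covariate,
multiplicative shifts for categorical ones).  The stepwise covariate search
uses the conventional chi-square thresholds: a drop in OFV larger than 3.84
(p < 0.05) to enter during forward addition, an increase larger than 10.83
(p < 0.001) on removal to stay during backward elimination.

The inner (per-subject) problem is vectorized across subjects, so one OFV
evaluation costs a handful of vectorized prediction passes regardless of
cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .datasets import Subject
from .pk_core import PopulationModel, disposition_constants

__all__ = [
    "ModelStructure",
    "CovariateCandidate",
    "FitResult",
    "BASE_1CPT",
    "BASE_2CPT",
    "FINAL_STRUCTURE",
    "compile_design",
    "foce_objective",
    "evaluate",
    "fit",
    "compare_structures",
    "covariate_search",
    "compare_cl_forms",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: fixed centering references for continuous covariate effects
COVARIATE_REFERENCE = {"clcr": 86.7, "age": 66.0, "tbw": 63.4}

_CATEGORICAL = {"icu", "sex", "shock", "mof"}
_CONTINUOUS = {"clcr", "age", "tbw"}

FORWARD_THRESHOLD = 3.84  # chi-square 0.95, 1 df
BACKWARD_THRESHOLD = 10.83  # chi-square 0.999, 1 df


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model structures


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate effect on a structural parameter.

    ``form`` is one of saturable | linear | power | exponential for
    continuous covariates, or categorical (a multiplicative shift) for
    binary ones.
    """

    parameter: str  # "cl" | "vc"
    covariate: str  # "clcr" | "age" | "tbw" | "icu" | "sex" | "shock" | "mof"
    form: str

    def __post_init__(self) -> None:
        if self.parameter not in ("cl", "vc"):
            raise ValueError(f"parameter must be cl or vc, got {self.parameter!r}")
        if self.covariate in _CATEGORICAL:
            if self.form != "categorical":
                raise ValueError(f"{self.covariate} admits only a categorical shift")
        elif self.covariate in _CONTINUOUS:
            if self.form not in ("saturable", "linear", "power", "exponential"):
                raise ValueError(f"unknown form {self.form!r}")
        else:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    @property
    def name(self) -> str:
        return f"{self.parameter}~{self.covariate}:{self.form}"


@dataclass(frozen=True)
class ModelStructure:
    """Structural model: compartment count plus covariate effects."""

    n_compartments: int = 2
    effects: tuple[CovariateCandidate, ...] = ()

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        sat = [e for e in self.effects if e.form == "saturable"]
        if len(sat) > 1:
            raise ValueError("at most one saturable effect is supported")
        if sat and sat[0].parameter != "cl":
            raise ValueError("the saturable form is supported on clearance only")
        primary = [e for e in self.effects
                   if e.covariate in _CONTINUOUS and e.parameter == "cl"]
        if len(primary) > 1:
            raise ValueError("one continuous effect per parameter")

    def with_effect(self, e: CovariateCandidate) -> "ModelStructure":
        return replace(self, effects=self.effects + (e,))

    def without_effect(self, e: CovariateCandidate) -> "ModelStructure":
        return replace(self, effects=tuple(x for x in self.effects if x != e))

    # -- parameter layout ---------------------------------------------------

    def param_names(self) -> list[str]:
        """Fixed-effect names, in estimation order."""
        names = []
        saturable = any(e.form == "saturable" for e in self.effects)
        names += ["cl_max", "cg50", "s"] if saturable else ["cl"]
        names.append("vc")
        if self.n_compartments == 2:
            names += ["q", "vp"]
        for e in self.effects:
            if e.form == "saturable":
                continue
            names.append(f"{e.parameter}_{e.covariate}_{e.form[:3]}")
        return names

    def n_params(self) -> int:
        """Total estimated parameters: fixed effects + 2 IIV variances + sigma2."""
        return len(self.param_names()) + 3

    def default_inits(self) -> dict[str, float]:
        inits = {}
        for n in self.param_names():
            if n == "cl_max":
                inits[n] = 6.0
            elif n == "cg50":
                inits[n] = 90.0
            elif n == "s":
                inits[n] = 1.2
            elif n == "cl":
                inits[n] = 3.0
            elif n == "vc":
                inits[n] = 15.0
            elif n == "q":
                inits[n] = 4.0
            elif n == "vp":
                inits[n] = 30.0
            elif n.endswith("_cat"):
                inits[n] = 1.5
            elif n.endswith("_pow"):
                inits[n] = 0.5
            else:  # _lin, _exp coefficients
                inits[n] = 0.001
        return inits

    def transforms(self) -> list[str]:
        """Optimization-scale transform per fixed effect: log for positive
        parameters, identity for sign-free coefficients."""
        out = []
        for n in self.param_names():
            if n.endswith(("_lin", "_exp", "_pow")):
                out.append("id")
            else:
                out.append("log")
        return out

    def typical_values(self, params: Mapping[str, float], cov: "_CovArrays"):
        """Per-subject typical (cl, vc, q, vp) under this structure."""
        saturable = any(e.form == "saturable" for e in self.effects)
        if saturable:
            x = cov.continuous["clcr"]
            # log-space evaluation so extreme trial (cg50, s) saturate
            # instead of overflowing
            s_ = params["s"]
            with np.errstate(divide="ignore"):
                num = np.exp(np.clip(s_ * np.log(x), -300.0, 300.0))
                den = np.exp(np.clip(s_ * np.log(params["cg50"]), -300.0, 300.0))
            cl = params["cl_max"] * num / (den + num)
        else:
            cl = np.full(cov.n, params["cl"])
        vc = np.full(cov.n, params["vc"])
        for e in self.effects:
            if e.form == "saturable":
                continue
            pname = f"{e.parameter}_{e.covariate}_{e.form[:3]}"
            theta = params[pname]
            base = cl if e.parameter == "cl" else vc
            if e.form == "categorical":
                fac = np.where(cov.categorical[e.covariate], theta, 1.0)
            else:
                x = cov.continuous[e.covariate]
                ref = COVARIATE_REFERENCE[e.covariate]
                if e.form == "linear":
                    fac = np.maximum(1.0 + theta * (x - ref), 1e-6)
                elif e.form == "power":
                    fac = np.exp(np.clip(theta * np.log(x / ref), -300.0, 300.0))
                else:  # exponential
                    fac = np.exp(np.clip(theta * (x - ref), -300.0, 300.0))
            base *= fac
        q = params["q"] if self.n_compartments == 2 else 0.0
        vp = params["vp"] if self.n_compartments == 2 else 1.0
        return cl, vc, np.full(cov.n, q), np.full(cov.n, vp)


BASE_1CPT = ModelStructure(n_compartments=1)
BASE_2CPT = ModelStructure(n_compartments=2)
FINAL_STRUCTURE = ModelStructure(
    n_compartments=2,
    effects=(
        CovariateCandidate("cl", "clcr", "saturable"),
        CovariateCandidate("vc", "icu", "categorical"),
    ),
)


# ---------------------------------------------------------------------------
# compiled design: flat arrays for vectorized prediction


@dataclass
class _CovArrays:
    n: int
    continuous: dict[str, np.ndarray]
    categorical: dict[str, np.ndarray]


@dataclass
class CompiledDesign:
    """Dataset flattened into observation and (observation, dose) pair arrays."""

    subject_ids: np.ndarray
    n_subjects: int
    cov: _CovArrays
    # observations
    obs_subject: np.ndarray  # (n_obs,) subject index
    obs_time: np.ndarray
    y: np.ndarray
    n_obs_per_subject: np.ndarray
    # (observation, dose) pairs with positive elapsed time
    pair_obs: np.ndarray
    pair_subject: np.ndarray
    pair_tau: np.ndarray  # time since infusion start
    pair_rate: np.ndarray  # mg/h
    pair_dur: np.ndarray

    def __post_init__(self) -> None:
        # parameter-independent pieces of the infusion response
        self.pair_te = np.minimum(self.pair_tau, self.pair_dur)
        self.pair_post = np.maximum(self.pair_tau - self.pair_dur, 0.0)

    @property
    def n_obs(self) -> int:
        return self.y.size


def compile_design(subjects: Sequence[Subject]) -> CompiledDesign:
    if not subjects:
        raise EstimationError("empty dataset")
    fitted = [s for s in subjects if s.n_obs > 0]
    if len(fitted) < len(subjects):
        warnings.warn(
            f"{len(subjects) - len(fitted)} subject(s) without observations "
            "excluded from estimation"
        )
    if not fitted:
        raise EstimationError("no subjects with observations")
    cont = {k: np.empty(len(fitted)) for k in _CONTINUOUS}
    cat = {k: np.empty(len(fitted), dtype=bool) for k in _CATEGORICAL}
    obs_subject, obs_time, y = [], [], []
    p_obs, p_subj, p_tau, p_rate, p_dur = [], [], [], [], []
    obs_counter = 0
    for i, s in enumerate(fitted):
        c = s.covariates
        cont["clcr"][i] = c.creatinine_clearance()
        cont["age"][i] = c.age
        cont["tbw"][i] = c.tbw
        cat["icu"][i] = c.icu
        cat["sex"][i] = c.sex == "female"
        cat["shock"][i] = c.shock
        cat["mof"][i] = c.mof
        for j, t in enumerate(s.obs_times):
            oi = obs_counter + j
            obs_subject.append(i)
            obs_time.append(t)
            y.append(s.obs_dv[j])
            for d in s.doses:
                tau = t - d.start_time
                if tau > 0:
                    p_obs.append(oi)
                    p_subj.append(i)
                    p_tau.append(tau)
                    p_rate.append(d.rate)
                    p_dur.append(d.duration)
        obs_counter += s.n_obs
    obs_subject = np.array(obs_subject, dtype=np.intp)
    return CompiledDesign(
        subject_ids=np.array([s.id for s in fitted]),
        n_subjects=len(fitted),
        cov=_CovArrays(n=len(fitted), continuous=cont, categorical=cat),
        obs_subject=obs_subject,
        obs_time=np.array(obs_time),
        y=np.array(y),
        n_obs_per_subject=np.bincount(obs_subject, minlength=len(fitted)),
        pair_obs=np.array(p_obs, dtype=np.intp),
        pair_subject=np.array(p_subj, dtype=np.intp),
        pair_tau=np.array(p_tau),
        pair_rate=np.array(p_rate),
        pair_dur=np.array(p_dur),
    )


def _predict(design: CompiledDesign, cl, vc, q, vp) -> np.ndarray:
    """Concentration at every observation given per-subject parameters."""
    with np.errstate(all="ignore"):
        k10 = cl / vc
        k12 = np.where(vc > 0, q / vc, 0.0)
        k21 = np.where(vp > 0, q / vp, 0.0)
        ssum = k10 + k12 + k21
        disc = np.sqrt(np.maximum(ssum * ssum - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (ssum + disc)
        beta = 0.5 * (ssum - disc)
        sep = np.maximum(alpha - beta, 1e-300)
        A = np.where(disc > 0, (alpha - k21) / sep, 1.0)
        B = np.where(disc > 0, (k21 - beta) / sep, 0.0)
        one_cpt = q <= 0.0
        A = np.where(one_cpt, 1.0, A)
        B = np.where(one_cpt, 0.0, B)
        alpha = np.where(one_cpt, k10, alpha)

        si = design.pair_subject
        a_, b_, A_, B_ = alpha[si], beta[si], A[si], B[si]
        te = design.pair_te
        post = design.pair_post
        resp = A_ / a_ * (-np.expm1(-a_ * te)) * np.exp(-a_ * post)
        b_safe = np.where(b_ > 0, b_, 1.0)
        resp += np.where(
            B_ != 0.0,
            B_ / b_safe * (-np.expm1(-b_safe * te)) * np.exp(-b_safe * post),
            0.0,
        )
        contrib = design.pair_rate / vc[si] * resp
    # repeated-root disposition is a measure-zero configuration; nudging beta
    # keeps the vectorized path defined (the scalar engine has the exact limit)
    deg = (q > 0) & (disc < 1e-9 * alpha)
    if np.any(deg):
        return _predict(design, cl, vc * (1.0 + 1e-7), q, vp)
    f = np.bincount(design.pair_obs, weights=contrib, minlength=design.n_obs)
    return f


def _predict_eta(design, cl_typ, vc_typ, q, vp, eta):
    # clip: keeps absurd line-search trial points finite without affecting
    # any plausible random-effect magnitude
    return _predict(
        design,
        cl_typ * np.exp(np.clip(eta[:, 0], -40.0, 40.0)),
        vc_typ * np.exp(np.clip(eta[:, 1], -40.0, 40.0)),
        q,
        vp,
    )


# ---------------------------------------------------------------------------
# FOCE-I objective


def _per_subject_sum(design, values):
    return np.bincount(design.obs_subject, weights=values, minlength=design.n_subjects)


def _inner_objective(design, f, eta, omega2, sigma2):
    """Per-subject -2 log joint density, up to eta-free constants."""
    f = np.maximum(f, 1e-12)
    e = design.y - f
    terms = e * e / (sigma2 * f * f) + 2.0 * np.log(f)
    pen = eta[:, 0] ** 2 / max(omega2[0], 1e-12) + eta[:, 1] ** 2 / max(omega2[1], 1e-12)
    return _per_subject_sum(design, terms) + pen


_FD_ETA = 1e-4


def _eta_gradient_pieces(design, cl_typ, vc_typ, q, vp, eta, f0=None, central=True):
    """f at eta and finite-difference derivatives wrt eta1, eta2."""
    if f0 is None:
        f0 = _predict_eta(design, cl_typ, vc_typ, q, vp, eta)
    G = np.empty((design.n_obs, 2))
    for k in range(2):
        d = np.zeros_like(eta)
        d[:, k] = _FD_ETA
        fp = _predict_eta(design, cl_typ, vc_typ, q, vp, eta + d)
        if central:
            fm = _predict_eta(design, cl_typ, vc_typ, q, vp, eta - d)
            G[:, k] = (fp - fm) / (2.0 * _FD_ETA)
        else:
            G[:, k] = (fp - f0) / _FD_ETA
    return f0, G


def _inner_newton(design, cl_typ, vc_typ, q, vp, omega2, sigma2,
                  max_iter=40, gtol=1e-9, max_halvings=12):
    """Vectorized damped Newton search for the conditional modes of eta.

    A subject stays active while the Newton decrement (the predicted
    objective drop of a full step) exceeds ``gtol``; the objective is
    stationary at the mode, so the residual OFV error is of that order.
    """
    n = design.n_subjects
    eta = np.zeros((n, 2))
    inv_w = np.array([1.0 / max(omega2[0], 1e-12), 1.0 / max(omega2[1], 1e-12)])
    f0 = _predict_eta(design, cl_typ, vc_typ, q, vp, eta)
    obj = _inner_objective(design, f0, eta, omega2, sigma2)
    frozen = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        f, G = _eta_gradient_pieces(
            design, cl_typ, vc_typ, q, vp, eta, f0=f0, central=False
        )
        f = np.maximum(f, 1e-12)
        e = design.y - f
        # gradient of the per-subject objective
        w = (-2.0 * e / (f * f) - 2.0 * e * e / (f ** 3)) / sigma2 + 2.0 / f
        g1 = _per_subject_sum(design, w * G[:, 0]) + 2.0 * eta[:, 0] * inv_w[0]
        g2 = _per_subject_sum(design, w * G[:, 1]) + 2.0 * eta[:, 1] * inv_w[1]
        # Gauss-Newton Hessian 2 G' R^-1 G + 2 Omega^-1
        r_inv = 1.0 / (sigma2 * f * f)
        h11 = 2.0 * _per_subject_sum(design, G[:, 0] ** 2 * r_inv) + 2.0 * inv_w[0]
        h12 = 2.0 * _per_subject_sum(design, G[:, 0] * G[:, 1] * r_inv)
        h22 = 2.0 * _per_subject_sum(design, G[:, 1] ** 2 * r_inv) + 2.0 * inv_w[1]
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = -(h22 * g1 - h12 * g2) / det
        s2 = -(h11 * g2 - h12 * g1) / det
        # Newton decrement: predicted objective drop of the full step
        pred_dec = -0.5 * (g1 * s1 + g2 * s2)
        active = (pred_dec > gtol) & ~frozen
        if not np.any(active):
            break
        # backtracking line search, per subject
        step = np.where(active, 1.0, 0.0)
        improved = ~active
        for _ls in range(max_halvings):
            trial = eta + step[:, None] * np.column_stack([s1, s2])
            f_t = _predict_eta(design, cl_typ, vc_typ, q, vp, trial)
            obj_t = _inner_objective(design, f_t, trial, omega2, sigma2)
            good = active & ~improved & (obj_t < obj - 1e-12)
            eta[good] = trial[good]
            obj[good] = obj_t[good]
            sel = good[design.obs_subject]
            f0[sel] = f_t[sel]
            improved |= good
            if np.all(improved):
                break
            step = np.where(improved, step, step * 0.5)
        # subjects where no step length improves are at (numerical) modes
        frozen |= active & ~improved
    return eta


def _foce_pieces(design, structure, params, omega2, sigma2):
    """Conditional modes and the FOCE-I per-subject -2LL contributions."""
    cl_typ, vc_typ, q, vp = structure.typical_values(params, design.cov)
    if np.any(~np.isfinite(cl_typ)) or np.any(cl_typ <= 0) or np.any(vc_typ <= 0):
        return None
    eta = _inner_newton(design, cl_typ, vc_typ, q, vp, (omega2[0], omega2[1]), sigma2)
    f, G = _eta_gradient_pieces(design, cl_typ, vc_typ, q, vp, eta)
    f = np.maximum(f, 1e-12)
    v_inv = 1.0 / (sigma2 * f * f)
    e = design.y - f
    w0 = max(omega2[0], 1e-12)
    w1 = max(omega2[1], 1e-12)
    # -2 log joint density at the conditional mode
    joint = (
        _per_subject_sum(design, e * e * v_inv + np.log(sigma2 * f * f))
        + design.n_obs_per_subject * LOG2PI
        + eta[:, 0] ** 2 / w0 + eta[:, 1] ** 2 / w1
    )
    # Laplace Hessian of the -log joint with the interaction term: for the
    # proportional error V = sigma2 f^2, the 0.5 (dV/deta)(dV/deta)'/V^2
    # contribution reduces to 2 G G' / f^2
    hw = v_inv + 2.0 / (f * f)
    h11 = _per_subject_sum(design, G[:, 0] ** 2 * hw)
    h12 = _per_subject_sum(design, G[:, 0] * G[:, 1] * hw)
    h22 = _per_subject_sum(design, G[:, 1] ** 2 * hw)
    # log det(Omega) + log det(Omega^-1 + H_data), grouped for stability
    det_scaled = (1.0 + w0 * h11) * (1.0 + w1 * h22) - w0 * w1 * h12 * h12
    if np.any(det_scaled <= 0):
        return None
    neg2ll = joint + np.log(det_scaled)
    return {"eta": eta, "f": f, "G": G, "neg2ll": neg2ll,
            "cl_typ": cl_typ, "vc_typ": vc_typ, "q": q, "vp": vp}


def foce_objective(
    subjects_or_design,
    structure: ModelStructure,
    theta: Mapping[str, float],
    omega2: Sequence[float],
    sigma2: float,
) -> float:
    """FOCE-I objective function value (-2 log-likelihood approximation)."""
    design = (
        subjects_or_design
        if isinstance(subjects_or_design, CompiledDesign)
        else compile_design(subjects_or_design)
    )
    pieces = _foce_pieces(design, structure, dict(theta), tuple(omega2), float(sigma2))
    if pieces is None or not np.all(np.isfinite(pieces["neg2ll"])):
        return float("inf")
    return float(np.sum(pieces["neg2ll"]))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a population fit."""

    structure: ModelStructure
    theta: dict[str, float]
    omega2: dict[str, float]  # keys "cl", "vc"
    sigma2: float
    ofv: float
    aic: float
    n_params: int
    eta: np.ndarray  # (n_subjects, 2) empirical Bayes estimates
    subject_ids: np.ndarray
    converged: bool
    rse: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def population_model(self) -> PopulationModel:
        """Express a final-structure fit as a :class:`PopulationModel`."""
        if set(self.structure.effects) != set(FINAL_STRUCTURE.effects) or (
            self.structure.n_compartments != 2
        ):
            raise ValueError("population_model() requires the final covariate structure")
        t = self.theta
        return PopulationModel(
            cl_max=t["cl_max"], cg50=t["cg50"], s=t["s"],
            vc_non_icu=t["vc"], vc_icu=t["vc"] * t["vc_icu_cat"],
            q=t["q"], vp=t["vp"],
            omega2_cl=self.omega2["cl"], omega2_vc=self.omega2["vc"],
            sigma2=self.sigma2,
        )


def _pack(structure, theta, omega2, sigma2):
    names = structure.param_names()
    trans = structure.transforms()
    x = []
    for n, tr in zip(names, trans):
        v = theta[n]
        x.append(np.log(v) if tr == "log" else v)
    x += [np.log(max(omega2[0], 1e-8)), np.log(max(omega2[1], 1e-8)),
          np.log(max(sigma2, 1e-8))]
    return np.array(x)


def _unpack(structure, x):
    names = structure.param_names()
    trans = structure.transforms()
    k = len(names)
    theta = {}
    for i, (n, tr) in enumerate(zip(names, trans)):
        theta[n] = float(np.exp(x[i])) if tr == "log" else float(x[i])
    omega2 = (float(np.exp(x[k])), float(np.exp(x[k + 1])))
    sigma2 = float(np.exp(x[k + 2]))
    return theta, omega2, sigma2


def _naive_pooled_init(design, structure, inits):
    """Two-stage starting values: least squares on pooled data with eta = 0."""
    names = structure.param_names()
    trans = structure.transforms()
    x0 = np.array([
        np.log(inits[n]) if tr == "log" else inits[n]
        for n, tr in zip(names, trans)
    ])

    def resid(x):
        theta = {
            n: (float(np.exp(v)) if tr == "log" else float(v))
            for n, tr, v in zip(names, trans, x)
        }
        cl, vc, q, vp = structure.typical_values(theta, design.cov)
        f = np.maximum(_predict(design, cl, vc, q, vp), 1e-12)
        return (design.y - f) / f

    try:
        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=400)
        theta = {
            n: (float(np.exp(v)) if tr == "log" else float(v))
            for n, tr, v in zip(names, trans, sol.x)
        }
        if all(np.isfinite(v) for v in theta.values()):
            return theta
    except Exception:
        pass
    return dict(inits)


def fit(
    subjects_or_design,
    structure: ModelStructure = FINAL_STRUCTURE,
    inits: Mapping[str, float] | None = None,
    *,
    fixed: Mapping[str, float] | None = None,
    compute_rse: bool = True,
    pooled_start: bool = True,
    maxfun: int = 4000,
) -> FitResult:
    """Maximum-likelihood fit of ``structure`` by FOCE-I.

    The outer problem optimizes log-transformed positive parameters (identity
    for sign-free covariate coefficients) with L-BFGS-B; relative standard
    errors come from the central finite-difference Hessian of the OFV at the
    optimum (covariance = 2 * H^-1).  ``fixed`` holds named parameters
    (including "omega2_cl"/"omega2_vc"/"sigma2") constant during estimation.
    """
    design = (
        subjects_or_design
        if isinstance(subjects_or_design, CompiledDesign)
        else compile_design(subjects_or_design)
    )
    fixed = dict(fixed or {})
    start = structure.default_inits()
    if inits:
        start.update({k: v for k, v in inits.items() if k in start})
    start.update({k: v for k, v in fixed.items() if k in start})
    omega2_0 = (
        float(fixed.get("omega2_cl", (inits or {}).get("omega2_cl", 0.1))),
        float(fixed.get("omega2_vc", (inits or {}).get("omega2_vc", 0.1))),
    )
    sigma2_0 = float(fixed.get("sigma2", (inits or {}).get("sigma2", 0.05)))

    def _ofv_at(th, om, sg):
        try:
            v = foce_objective(design, structure, th, om, sg)
        except (OverflowError, FloatingPointError):
            return np.inf
        return v if np.isfinite(v) else np.inf

    if pooled_start:
        # candidate starts: the supplied point, the pooled least-squares
        # refinement of it, and (for warm restarts) a cold default start --
        # the least-squares point can diverge on misspecified candidates,
        # while a warm start can sit in the wrong basin (e.g. with inflated
        # random-effect variance masking a covariate effect)
        def _with_fixed(th):
            th = dict(th)
            th.update({k: v for k, v in fixed.items() if k in th})
            return th

        candidates = [
            (start, omega2_0, sigma2_0),
            (_with_fixed(_naive_pooled_init(design, structure, dict(start))),
             omega2_0, sigma2_0),
        ]
        if inits:
            defaults = _with_fixed(structure.default_inits())
            om_d = (float(fixed.get("omega2_cl", 0.1)),
                    float(fixed.get("omega2_vc", 0.1)))
            sg_d = float(fixed.get("sigma2", 0.05))
            candidates.append(
                (_with_fixed(_naive_pooled_init(design, structure, defaults)),
                 om_d, sg_d)
            )
        start, omega2_0, sigma2_0 = min(
            candidates, key=lambda c: _ofv_at(*c)
        )

    all_names = structure.param_names() + ["omega2_cl", "omega2_vc", "sigma2"]
    free = np.array([n not in fixed for n in all_names])
    x_full0 = _pack(structure, start, omega2_0, sigma2_0)

    def expand(x_free):
        x = x_full0.copy()
        x[free] = x_free
        return x

    def objective(x_free):
        theta, omega2, sigma2 = _unpack(structure, expand(x_free))
        try:
            val = foce_objective(design, structure, theta, omega2, sigma2)
        except (OverflowError, FloatingPointError):
            return 1e10
        return val if np.isfinite(val) else 1e10

    res = optimize.minimize(
        objective, x_full0[free], method="L-BFGS-B",
        options={"maxfun": maxfun, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5},
    )
    x_opt = expand(res.x)
    theta, omega2, sigma2 = _unpack(structure, x_opt)
    ofv = float(res.fun)
    k = structure.n_params()
    pieces = _foce_pieces(design, structure, theta, omega2, sigma2)
    eta = pieces["eta"] if pieces is not None else np.zeros((design.n_subjects, 2))
    converged = bool(res.success and np.isfinite(ofv) and ofv < 1e9)
    rse: dict[str, float] = {}
    if compute_rse and converged:
        rse = _relative_standard_errors(design, structure, x_opt, ofv)
    return FitResult(
        structure=structure,
        theta=theta,
        omega2={"cl": omega2[0], "vc": omega2[1]},
        sigma2=sigma2,
        ofv=ofv,
        aic=ofv + 2.0 * k,
        n_params=k,
        eta=eta,
        subject_ids=design.subject_ids,
        converged=converged,
        rse=rse,
        message=str(res.message),
    )


def evaluate(subjects_or_design, structure, theta, omega2, sigma2) -> FitResult:
    """FOCE-I evaluation (OFV + empirical Bayes estimates) at fixed parameters."""
    design = (
        subjects_or_design
        if isinstance(subjects_or_design, CompiledDesign)
        else compile_design(subjects_or_design)
    )
    theta = dict(theta)
    omega2 = tuple(omega2)
    pieces = _foce_pieces(design, structure, theta, omega2, float(sigma2))
    if pieces is None:
        raise EstimationError("model evaluation failed at the supplied parameters")
    ofv = float(np.sum(pieces["neg2ll"]))
    k = structure.n_params()
    return FitResult(
        structure=structure, theta=theta,
        omega2={"cl": omega2[0], "vc": omega2[1]}, sigma2=float(sigma2),
        ofv=ofv, aic=ofv + 2.0 * k, n_params=k,
        eta=pieces["eta"], subject_ids=design.subject_ids,
        converged=True, message="evaluated at fixed parameters",
    )


def _relative_standard_errors(design, structure, x_opt, f0, step=1e-4):
    """RSE%% per parameter from the finite-difference Hessian on the
    optimization scale, transformed to the natural scale by the delta method."""
    n = x_opt.size

    def obj(x):
        theta, omega2, sigma2 = _unpack(structure, x)
        v = foce_objective(design, structure, theta, omega2, sigma2)
        return v if np.isfinite(v) else 1e10

    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = step
        fp[i] = obj(x_opt + e)
        fm[i] = obj(x_opt - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            fpp = obj(x_opt + ei + ej)
            fmm = obj(x_opt - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * step**2)
    names = structure.param_names() + ["omega2_cl", "omega2_vc", "sigma2"]
    trans = structure.transforms() + ["log", "log", "log"]
    theta, omega2, sigma2 = _unpack(structure, x_opt)
    natural = [theta[n] for n in structure.param_names()] + [omega2[0], omega2[1], sigma2]
    try:
        cov_x = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}
    rse = {}
    for i, (n, tr, v) in enumerate(zip(names, trans, natural)):
        var_x = cov_x[i, i]
        if var_x <= 0:
            rse[n] = float("nan")
            continue
        # delta method: on log scale sd(log p) ~= sd(p)/p directly
        sd_nat = np.sqrt(var_x) * (abs(v) if tr == "log" else 1.0)
        rse[n] = float(100.0 * sd_nat / abs(v)) if v != 0 else float("nan")
    return rse


# ---------------------------------------------------------------------------
# structural and covariate model selection


def compare_structures(subjects, inits=None, **fit_kwargs) -> dict:
    """Fit one- and two-compartment base models; select by AIC."""
    design = compile_design(subjects)
    results = {}
    for key, structure in (("one_cpt", BASE_1CPT), ("two_cpt", BASE_2CPT)):
        try:
            results[key] = fit(design, structure, inits, compute_rse=False, **fit_kwargs)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"{key} fit failed: {exc}")
            results[key] = None
    ok = {k: r for k, r in results.items() if r is not None and np.isfinite(r.aic)}
    if not ok:
        raise EstimationError("both structural fits failed")
    selected = min(ok, key=lambda k: ok[k].aic)
    results["selected"] = selected
    return results


def covariate_search(
    subjects,
    candidates: Sequence[CovariateCandidate],
    base: ModelStructure = BASE_2CPT,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    **fit_kwargs,
) -> dict:
    """Forward-addition / backward-elimination covariate search.

    Forward: at each round the candidate with the largest OFV drop is added
    if the drop exceeds ``forward_threshold``.  Backward: from the full model,
    effects whose removal raises the OFV by at most ``backward_threshold``
    are removed (least significant first).  Returns the final structure, the
    final fit and an audit trail of every tested step.
    """
    fit_kwargs.setdefault("compute_rse", False)
    design = compile_design(subjects)
    trail: list[dict] = []

    def _fit(structure, warm=None):
        inits = dict(warm.theta) if warm is not None else None
        kwargs = dict(fit_kwargs)
        if inits is not None:
            inits.update(omega2_cl=warm.omega2["cl"], omega2_vc=warm.omega2["vc"],
                         sigma2=warm.sigma2)
        return fit(design, structure, inits, **kwargs)

    def _fit_retry(structure, warm, retry_if):
        """Warm-started fit with a cold retry when the verdict looks like an
        optimizer stall rather than a statistical one (warm restarts can sit
        in a basin where inflated random-effect variance masks the effect)."""
        trial = _fit(structure, warm=warm)
        if retry_if(trial.ofv):
            cold = _fit(structure)
            if cold.ofv < trial.ofv:
                trial = cold
        return trial

    current = base
    current_fit = _fit(base)
    trail.append({"phase": "base", "candidate": None, "ofv": current_fit.ofv,
                  "delta": 0.0, "action": "start"})
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                trial = _fit_retry(
                    current.with_effect(cand), current_fit,
                    lambda ofv: current_fit.ofv - ofv <= forward_threshold,
                )
                delta = current_fit.ofv - trial.ofv
            except Exception as exc:
                warnings.warn(f"candidate {cand.name} failed: {exc}")
                trial, delta = None, -np.inf
            trail.append({"phase": "forward", "candidate": cand.name,
                          "ofv": trial.ofv if trial else float("nan"),
                          "delta": delta, "action": "tested"})
            if delta > forward_threshold and (best is None or delta > best[1]):
                best = (cand, delta, trial)
        if best is None:
            break
        cand, delta, trial = best
        current = current.with_effect(cand)
        current_fit = trial
        remaining.remove(cand)
        trail.append({"phase": "forward", "candidate": cand.name,
                      "ofv": current_fit.ofv, "delta": delta, "action": "added"})

    # backward elimination
    while current.effects:
        worst = None
        for eff in current.effects:
            try:
                trial = _fit_retry(
                    current.without_effect(eff), current_fit,
                    lambda ofv: ofv - current_fit.ofv > backward_threshold,
                )
                increase = trial.ofv - current_fit.ofv
            except Exception as exc:
                warnings.warn(f"removal of {eff.name} failed: {exc}")
                trial, increase = None, np.inf
            trail.append({"phase": "backward", "candidate": eff.name,
                          "ofv": trial.ofv if trial else float("nan"),
                          "delta": increase, "action": "tested"})
            if increase <= backward_threshold and (worst is None or increase < worst[1]):
                worst = (eff, increase, trial)
        if worst is None:
            break
        eff, increase, trial = worst
        current = current.without_effect(eff)
        current_fit = trial
        trail.append({"phase": "backward", "candidate": eff.name,
                      "ofv": current_fit.ofv, "delta": increase, "action": "removed"})

    return {"structure": current, "fit": current_fit, "trail": trail}


CL_FORMS = ("saturable", "linear", "exponential", "power")


def compare_cl_forms(subjects, base: ModelStructure | None = None, **fit_kwargs) -> dict:
    """OFV of saturable vs linear vs exponential vs power CL-CLcr relationships.

    Each form is added to ``base`` (default: two-compartment with the ICU
    shift on central volume) and fitted; returns {form: FitResult} plus the
    winning form under "selected"."""
    fit_kwargs.setdefault("compute_rse", False)
    if base is None:
        base = ModelStructure(2, (CovariateCandidate("vc", "icu", "categorical"),))
    design = compile_design(subjects)
    out: dict[str, object] = {}
    for form in CL_FORMS:
        structure = base.with_effect(CovariateCandidate("cl", "clcr", form))
        try:
            out[form] = fit(design, structure, **fit_kwargs)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"{form} fit failed: {exc}")
            out[form] = None
    ok = {k: v for k, v in out.items() if v is not None and np.isfinite(v.ofv)}
    out["selected"] = min(ok, key=lambda k: ok[k].ofv) if ok else None
    return out
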