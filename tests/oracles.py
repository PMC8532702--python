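"""Independent oracles used by the test suite.

These deliberately avoid the package's fast paths: concentrations are checked
against direct numerical integration of the compartmental ODEs, and the FOCE
objective against adaptive Gauss-Hermite quadrature of the exact marginal
likelihood (product rule over the two random effects).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.integrate import solve_ivp

from vancopk.pk_core import (
    PKParameters,
    clearance_typical,
    concentration,
    vc_typical,
)


def ode_concentration(t_eval, events, p: PKParameters, rtol=1e-10, atol=1e-12):
    """Two-compartment infusion model solved as an ODE initial-value problem."""

    def rhs(t, x):
        rate = sum(
            e.rate for e in events if e.start_time <= t < e.start_time + e.duration
        )
        a_c, a_p = x
        d_ac = rate - (p.cl + p.q) / p.vc * a_c + (p.q / p.vp) * a_p
        d_ap = (p.q / p.vc) * a_c - (p.q / p.vp) * a_p
        return [d_ac, d_ap]

    t_end = float(np.max(t_eval))
    switch = sorted(
        {e.start_time for e in events} | {e.start_time + e.duration for e in events}
    )
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, 0.0], t_eval=np.atleast_1d(t_eval),
        method="LSODA", rtol=rtol, atol=atol, max_step=0.25,
    )
    assert sol.success
    del switch
    return sol.y[0] / p.vc


def agq_neg2ll(subjects, model, n_nodes=15):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Per subject: locate the mode of the joint density of data and random
    effects, scale a 2-D product Gauss-Hermite grid by the inverse Hessian
    square root at the mode, and integrate the exact joint density.
    """
    z, w = hermgauss(n_nodes)
    Z1, Z2 = np.meshgrid(z, z, indexing="ij")
    W = np.outer(w, w).ravel()
    Zs = np.column_stack([Z1.ravel(), Z2.ravel()])
    omega = np.diag([model.omega2_cl, model.omega2_vc])
    omega_inv = np.linalg.inv(omega)
    log_norm = 0.5 * np.log((2.0 * np.pi) ** 2 * np.linalg.det(omega))
    total = 0.0
    for s in subjects:
        cl_typ = clearance_typical(s.covariates.creatinine_clearance(), model)
        vc_typ = vc_typical(s.covariates.icu, model)
        y = s.obs_dv

        def neg_log_joint(eta):
            p = PKParameters(
                cl=cl_typ * np.exp(eta[0]), vc=vc_typ * np.exp(eta[1]),
                q=model.q, vp=model.vp,
            )
            f = np.maximum(concentration(s.obs_times, s.doses, p), 1e-12)
            ll = -0.5 * np.sum(
                (y - f) ** 2 / (model.sigma2 * f * f)
                + np.log(2.0 * np.pi * model.sigma2 * f * f)
            )
            lp = -0.5 * float(eta @ omega_inv @ eta) - log_norm
            return -(ll + lp)

        sol = optimize.minimize(
            neg_log_joint, [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        h = 1e-4
        H = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                ea = np.zeros(2); ea[a] = h
                eb = np.zeros(2); eb[b] = h
                H[a, b] = (
                    neg_log_joint(sol.x + ea + eb)
                    - neg_log_joint(sol.x + ea - eb)
                    - neg_log_joint(sol.x - ea + eb)
                    + neg_log_joint(sol.x - ea - eb)
                ) / (4.0 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        pts = sol.x + np.sqrt(2.0) * (Zs @ L.T)
        vals = np.array([-neg_log_joint(p_) for p_ in pts])
        lse = vals + np.sum(Zs**2, axis=1)
        mx = np.max(lse)
        integral = (
            2.0 * abs(np.linalg.det(L)) * np.exp(mx) * np.sum(W * np.exp(lse - mx))
        )
        total += -2.0 * np.log(integral)
    return total
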