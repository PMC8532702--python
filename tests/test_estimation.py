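"""FOCE-I objective, population fitting and model selection."""

import warnings

import numpy as np
import pytest
from dataclasses import replace

from vancopk import PopulationModel, default_table1_spec, generate_cohort
from vancopk.datasets import Subject
from vancopk.estimation import (
    BASE_2CPT,
    FINAL_STRUCTURE,
    CovariateCandidate,
    ModelStructure,
    compare_cl_forms,
    compare_structures,
    compile_design,
    covariate_search,
    evaluate,
    fit,
    foce_objective,
)
from vancopk.pk_core import (
    Covariates,
    DoseEvent,
    PKParameters,
    clearance_typical,
    concentration,
    vc_typical,
)

from conftest import TABLE2_THETA
from oracles import agq_neg2ll


def _pooled_neg2ll(subjects, model):
    """Naive-pooled -2 log-likelihood with proportional error, computed from
    the scalar concentration engine (independent of the estimation path)."""
    total = 0.0
    for s in subjects:
        p = PKParameters(
            cl=clearance_typical(s.covariates.creatinine_clearance(), model),
            vc=vc_typical(s.covariates.icu, model),
            q=model.q, vp=model.vp,
        )
        f = np.maximum(concentration(s.obs_times, s.doses, p), 1e-12)
        total += np.sum(
            (s.obs_dv - f) ** 2 / (model.sigma2 * f * f)
            + np.log(2 * np.pi * model.sigma2 * f * f)
        )
    return total


class TestFoceObjective:
    def test_zero_iiv_limit_is_naive_pooled(self, small_cohort, model):
        ofv = foce_objective(
            small_cohort, FINAL_STRUCTURE, TABLE2_THETA, (0.0, 0.0), model.sigma2
        )
        assert ofv == pytest.approx(_pooled_neg2ll(small_cohort, model), abs=1e-3)

    def test_duplicating_subjects_doubles_ofv(self, small_cohort, model):
        ofv1 = foce_objective(
            small_cohort, FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        dup = small_cohort + [
            Subject(id=1000 + s.id, covariates=s.covariates, doses=s.doses,
                    obs_times=s.obs_times, obs_dv=s.obs_dv)
            for s in small_cohort
        ]
        ofv2 = foce_objective(
            dup, FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        assert ofv2 == pytest.approx(2.0 * ofv1, rel=1e-9)

    def test_invariant_to_subject_order(self, small_cohort, model):
        ofv = foce_objective(
            small_cohort, FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        ofv_rev = foce_objective(
            list(reversed(small_cohort)), FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        assert ofv == pytest.approx(ofv_rev, rel=1e-12)

    def test_matches_quadrature_oracle_three_subjects(self, dense_cohort, model):
        subs = dense_cohort[:3]
        foce = foce_objective(
            subs, FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        assert foce == pytest.approx(agq_neg2ll(subs, model), abs=0.5)

    def test_matches_quadrature_oracle_ten_subjects(self, dense_cohort, model):
        foce = foce_objective(
            dense_cohort, FINAL_STRUCTURE, TABLE2_THETA,
            (model.omega2_cl, model.omega2_vc), model.sigma2,
        )
        assert foce == pytest.approx(agq_neg2ll(dense_cohort, model), abs=1.0)


class TestFit:
    def test_deterministic_curve_fit_limit(self):
        # one subject, dense noise-free sampling, vanishing variances: the
        # fixed effects must reproduce the generating parameters
        truth = PKParameters(cl=2.5, vc=12.0, q=3.0, vp=30.0)
        doses = tuple(DoseEvent(12.0 * k, 1000.0, 1.0) for k in range(4))
        t = np.linspace(0.25, 60.0, 40)
        y = concentration(t, doses, truth)
        sub = Subject(
            id=1,
            covariates=Covariates(age=60, sex="male", tbw=70, clcr=90.0),
            doses=doses, obs_times=t, obs_dv=y,
        )
        res = fit(
            [sub], BASE_2CPT, compute_rse=False, maxfun=2500,
            fixed={"omega2_cl": 1e-8, "omega2_vc": 1e-8, "sigma2": 1e-6},
        )
        assert res.theta["cl"] == pytest.approx(truth.cl, rel=1e-3)
        assert res.theta["vc"] == pytest.approx(truth.vc, rel=1e-3)
        assert res.theta["q"] == pytest.approx(truth.q, rel=1e-3)
        assert res.theta["vp"] == pytest.approx(truth.vp, rel=1e-3)

    def test_refit_from_solution_is_fixed_point(self, small_cohort):
        first = fit(small_cohort, FINAL_STRUCTURE, compute_rse=False)
        inits = dict(first.theta)
        inits.update(omega2_cl=first.omega2["cl"], omega2_vc=first.omega2["vc"],
                     sigma2=first.sigma2)
        second = fit(small_cohort, FINAL_STRUCTURE, inits=inits,
                     compute_rse=False, pooled_start=False)
        assert second.ofv == pytest.approx(first.ofv, abs=1e-3)

    def test_evaluate_reports_ofv_and_ebes(self, small_cohort, model):
        res = evaluate(small_cohort, FINAL_STRUCTURE, TABLE2_THETA,
                       (model.omega2_cl, model.omega2_vc), model.sigma2)
        assert np.isfinite(res.ofv)
        assert res.eta.shape == (len(small_cohort), 2)
        assert np.all(np.isfinite(res.eta))
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_params)


class TestModelSelection:
    def test_two_compartment_truth_selects_two_compartment(self, model):
        subs = generate_cohort(
            replace(default_table1_spec(seed=31), n_subjects=60), model
        )
        out = compare_structures(subs)
        assert out["selected"] == "two_cpt"
        assert out["two_cpt"].aic < out["one_cpt"].aic
        for key in ("one_cpt", "two_cpt"):
            assert out[key].aic == pytest.approx(
                out[key].ofv + 2 * out[key].n_params
            )

    def test_one_compartment_truth_is_not_overfit(self):
        # q = 0 collapses the kinetics to one compartment; the base structural
        # comparison is covariate-free, so the generating model is too
        # (flat clearance via cg50 ~ 0, a single central volume)
        model = PopulationModel(cl_max=3.0, cg50=1e-3, vc_non_icu=15.0,
                                vc_icu=15.0, q=0.0, vp=1.0, omega2_vc=0.1)
        subs = generate_cohort(
            replace(default_table1_spec(seed=37), n_subjects=60), model
        )
        out = compare_structures(subs)
        if out["selected"] == "two_cpt":
            assert out["one_cpt"].aic - out["two_cpt"].aic <= 2.0


class TestCovariateSearch:
    CANDIDATES = [
        CovariateCandidate("cl", "clcr", "saturable"),
        CovariateCandidate("vc", "icu", "categorical"),
        CovariateCandidate("cl", "sex", "categorical"),
        CovariateCandidate("vc", "tbw", "linear"),
    ]

    def test_recovers_true_covariates(self, model):
        subs = generate_cohort(
            replace(default_table1_spec(seed=41), n_subjects=60), model
        )
        out = covariate_search(subs, self.CANDIDATES, maxfun=2000)
        names = {e.name for e in out["structure"].effects}
        assert "cl~clcr:saturable" in names
        assert "vc~icu:categorical" in names
        assert "cl~sex:categorical" not in names
        assert "vc~tbw:linear" not in names
        assert any(step["action"] == "added" for step in out["trail"])

    def test_no_effect_truth_yields_mostly_empty_models(self):
        # cg50 ~ 0 makes clearance flat in CLcr and the ICU volumes equal:
        # a covariate-free truth; the search should rarely admit noise
        model = PopulationModel(cl_max=3.0, cg50=1e-3, vc_non_icu=15.0,
                                vc_icu=15.0, omega2_vc=0.1)
        candidates = [
            CovariateCandidate("cl", "sex", "categorical"),
            CovariateCandidate("vc", "tbw", "linear"),
        ]
        empty = 0
        for seed in (51, 52, 53):
            subs = generate_cohort(
                replace(default_table1_spec(seed=seed), n_subjects=40), model
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = covariate_search(subs, candidates, maxfun=1200)
            empty += not out["structure"].effects
        assert empty >= 2

    def test_preincluded_true_covariate_retained(self, model):
        subs = generate_cohort(
            replace(default_table1_spec(seed=43), n_subjects=40), model
        )
        base = ModelStructure(2, (CovariateCandidate("cl", "clcr", "saturable"),))
        out = covariate_search(
            subs, [CovariateCandidate("vc", "icu", "categorical")],
            base=base, maxfun=2000,
        )
        names = {e.name for e in out["structure"].effects}
        assert "cl~clcr:saturable" in names


class TestClearanceForms:
    def test_saturable_truth_attains_lowest_ofv(self, model):
        subs = generate_cohort(
            replace(default_table1_spec(seed=61), n_subjects=60), model
        )
        out = compare_cl_forms(subs, maxfun=2500)
        assert out["selected"] == "saturable"
        for form in ("saturable", "linear", "exponential", "power"):
            assert np.isfinite(out[form].ofv)
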