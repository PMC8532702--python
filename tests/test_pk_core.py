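"""Covariate models, closed-form kinetics and steady-state exposure metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vancopk.pk_core import (
    Covariates,
    DoseEvent,
    InvalidCovariateError,
    PKParameters,
    PopulationModel,
    Regimen,
    auc24_steady_state,
    clearance_typical,
    cockcroft_gault,
    concentration,
    default_infusion_duration,
    realize_individual,
    trough_steady_state,
    vc_typical,
)

from oracles import ode_concentration


class TestCockcroftGault:
    @pytest.mark.parametrize(
        "sex,scr,unit,expected",
        [
            ("male", 1.0, "mg/dL", 100.0),
            ("female", 1.0, "mg/dL", 85.0),
            ("male", 88.4, "umol/L", 100.0),
        ],
    )
    def test_reference_cases(self, sex, scr, unit, expected):
        cov = Covariates(age=40, sex=sex, tbw=72, scr=scr, scr_unit=unit)
        assert cockcroft_gault(cov) == pytest.approx(expected)

    def test_invalid_covariates_rejected(self):
        with pytest.raises(InvalidCovariateError):
            Covariates(age=40, sex="male", tbw=72, scr=-1.0)
        with pytest.raises(InvalidCovariateError):
            Covariates(age=40, sex="male", tbw=-5, scr=1.0)
        with pytest.raises(InvalidCovariateError):
            Covariates(age=12, sex="male", tbw=40, scr=1.0)
        with pytest.raises(InvalidCovariateError):
            Covariates(age=40, sex="male", tbw=72, scr=1.0, scr_unit="mol/L")


class TestClearanceModel:
    def test_half_maximal_at_cg50(self, model):
        assert clearance_typical(93.8, model) == pytest.approx(2.79, rel=5e-3)

    def test_arc_threshold_clearance(self, model):
        assert clearance_typical(130.0, model) == pytest.approx(3.46, rel=5e-3)

    def test_low_renal_function_hand_value(self, model):
        # 5.58 * 18.4^1.5 / (93.8^1.5 + 18.4^1.5)
        assert clearance_typical(18.4, model) == pytest.approx(0.44604, rel=1e-4)

    @given(st.floats(min_value=0.5, max_value=500.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_bounded(self, clcr):
        model = PopulationModel()
        cl = clearance_typical(clcr, model)
        assert 0 < cl < model.cl_max
        assert clearance_typical(clcr * 1.01, model) > cl

    def test_domain_error(self, model):
        with pytest.raises(ValueError):
            clearance_typical(0.0, model)


class TestCentralVolume:
    def test_icu_shift(self, model):
        assert vc_typical(False, model) == 8.02
        assert vc_typical(True, model) == 35.7

    def test_fold_increase(self, model):
        fold = (model.vc_icu - model.vc_non_icu) / model.vc_non_icu
        assert round(fold, 1) == 3.5


class TestRealization:
    def test_zero_eta_gives_typical(self, model):
        cov = Covariates(age=60, sex="male", tbw=70, clcr=93.8, icu=True)
        p = realize_individual(cov, model, 0.0, 0.0)
        assert p.cl == pytest.approx(clearance_typical(93.8, model))
        assert p.vc == pytest.approx(35.7)
        assert (p.q, p.vp) == (model.q, model.vp)

    def test_eta_scales_exponentially(self, model):
        cov = Covariates(age=60, sex="male", tbw=70, clcr=100.0)
        base = realize_individual(cov, model, 0.0, 0.0)
        doubled = realize_individual(cov, model, np.log(2.0), 0.0)
        assert doubled.cl == pytest.approx(2.0 * base.cl)

    def test_lognormal_median_is_typical(self, model):
        rng = np.random.default_rng(42)
        cov = Covariates(age=60, sex="male", tbw=70, clcr=100.0)
        typical = realize_individual(cov, model, 0.0, 0.0).cl
        etas = rng.normal(0.0, np.sqrt(model.omega2_cl), size=100_000)
        cls = typical * np.exp(etas)
        assert np.median(cls) == pytest.approx(typical, rel=0.01)


STANDARD_P = PKParameters(cl=3.0, vc=8.02, q=2.66, vp=36.8)
ICU_P = PKParameters(cl=1.2, vc=35.7, q=2.66, vp=36.8)
ONE_CPT_P = PKParameters(cl=3.0, vc=30.0, q=0.0, vp=1.0)

EVENTS = [DoseEvent(0.0, 1000.0, 1.0), DoseEvent(12.0, 1000.0, 1.0),
          DoseEvent(24.0, 500.0, 2.0)]


class TestConcentration:
    def test_zero_before_first_dose(self):
        events = [DoseEvent(5.0, 1000.0, 1.0)]
        assert concentration(2.0, events, STANDARD_P) == 0.0

    def test_linearity_in_dose(self):
        t = np.linspace(0.5, 40, 50)
        c1 = concentration(t, EVENTS, STANDARD_P)
        doubled = [DoseEvent(e.start_time, 2 * e.amount, e.duration) for e in EVENTS]
        np.testing.assert_allclose(concentration(t, doubled, STANDARD_P), 2 * c1,
                                   rtol=1e-12)

    def test_superposition(self):
        t = np.linspace(0.5, 40, 50)
        first, rest = EVENTS[:1], EVENTS[1:]
        np.testing.assert_allclose(
            concentration(t, EVENTS, STANDARD_P),
            concentration(t, first, STANDARD_P) + concentration(t, rest, STANDARD_P),
            rtol=1e-12,
        )

    def test_non_negative(self):
        t = np.linspace(0.0, 100, 500)
        assert np.all(concentration(t, EVENTS, STANDARD_P) >= 0.0)

    @pytest.mark.parametrize("p", [STANDARD_P, ICU_P, ONE_CPT_P],
                             ids=["non_icu", "icu", "one_cpt"])
    def test_matches_ode_integration(self, p):
        t = np.linspace(0.2, 48.0, 60)
        closed = concentration(t, EVENTS, p)
        ode = ode_concentration(t, EVENTS, p)
        np.testing.assert_allclose(closed, ode, rtol=1e-6)

    def test_q_zero_reduces_to_one_compartment(self):
        # single-exponential closed form as the independent reference
        p = ONE_CPT_P
        k = p.cl / p.vc
        ev = DoseEvent(0.0, 1000.0, 1.0)
        t = np.array([0.5, 1.0, 3.0, 12.0])
        expected = np.where(
            t <= ev.duration,
            ev.rate / p.cl * (1 - np.exp(-k * t)),
            ev.rate / p.cl * (1 - np.exp(-k * ev.duration))
            * np.exp(-k * np.maximum(t - ev.duration, 0.0)),
        )
        np.testing.assert_allclose(concentration(t, [ev], p), expected, rtol=1e-10)

    def test_near_repeated_root_limit(self):
        # with q -> 0 and k10 = k21 the hybrid roots coalesce; the limit form
        # must agree with the exactly-one-compartment profile
        k = 0.1
        deg = PKParameters(cl=1.0, vc=10.0, q=1e-18, vp=1e-17)
        ref = PKParameters(cl=1.0, vc=10.0, q=0.0, vp=1.0)
        t = np.linspace(0.25, 30.0, 40)
        ev = [DoseEvent(0.0, 500.0, 1.0)]
        np.testing.assert_allclose(
            concentration(t, ev, deg), concentration(t, ev, ref), rtol=1e-6
        )
        del k


class TestSteadyStateMetrics:
    @pytest.mark.parametrize(
        "dose,interval,cl,expected",
        [(500, 24, 1.0, 500.0), (750, 12, 3.0, 500.0)],
    )
    def test_auc_is_daily_dose_over_clearance(self, dose, interval, cl, expected):
        reg = Regimen(dose, interval)
        p = PKParameters(cl=cl, vc=8.02, q=2.66, vp=36.8)
        assert auc24_steady_state(reg, p) == pytest.approx(expected)

    def test_auc_matches_numeric_integration(self):
        reg = Regimen(1000, 12)
        p = STANDARD_P
        t = np.linspace(19 * 24.0, 20 * 24.0, 8001)
        c = concentration(t, reg.events(45), p)
        numeric = np.trapezoid(c, t)
        assert auc24_steady_state(reg, p) == pytest.approx(numeric, rel=5e-3)

    @pytest.mark.parametrize("p", [STANDARD_P, ICU_P], ids=["non_icu", "icu"])
    def test_trough_matches_long_simulation(self, p):
        reg = Regimen(1000, 12)
        n_cycles = 60
        t = n_cycles * reg.interval - 1e-9
        sim = concentration(t, reg.events(n_cycles), p)
        assert trough_steady_state(reg, p) == pytest.approx(sim, rel=1e-3)

    def test_trough_decreases_with_interval(self):
        troughs = [trough_steady_state(Regimen(1000, tau), STANDARD_P)
                   for tau in (8, 12, 24)]
        assert troughs[0] > troughs[1] > troughs[2]

    def test_trough_vanishes_at_huge_clearance(self):
        p = PKParameters(cl=1e6, vc=8.02, q=2.66, vp=36.8)
        assert trough_steady_state(Regimen(1000, 12), p) < 1e-6


class TestRegimen:
    def test_default_infusion_duration_policy(self):
        assert default_infusion_duration(1000) == 1.0
        assert default_infusion_duration(1500) == 2.0
        assert Regimen(500, 12).infusion_duration == 1.0
        assert Regimen(2000, 24).infusion_duration == 2.0

    def test_validation(self):
        with pytest.raises(ValueError):
            Regimen(-100, 12)
        with pytest.raises(ValueError):
            Regimen(500, 12, infusion_duration=12.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 500.0, 0.0)

    def test_model_parameter_validation(self):
        with pytest.raises(ValueError):
            PopulationModel(cl_max=-1.0)
        with pytest.raises(ValueError):
            PopulationModel(sigma2=-0.1)
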