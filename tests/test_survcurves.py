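"""Survival model fitting, selection, extrapolation, and the HR transform."""

import numpy as np
import pytest

from sclccea.km_ipd import PseudoIPD
from sclccea.survcurves import (ALL_FAMILIES, CurveSet, SurvivalFit, apply_hr, fit,
                                select, survival_at)
from sclccea.synthetic_trial import simulate_endpoint


@pytest.fixture(scope="module")
def weibull_ipd():
    return simulate_endpoint("weibull", [1.5, 300.0], 500, seed=3,
                             max_followup_days=900.0)


@pytest.fixture(scope="module")
def exp_ipd():
    return simulate_endpoint("exponential", [0.1], 5000, seed=1)


def test_exponential_mle_closed_form(exp_ipd):
    f = fit(exp_ipd, "exponential")
    closed_form = exp_ipd.n_events / exp_ipd.times_days.sum()
    assert f.params["rate"] == pytest.approx(closed_form, rel=1e-4)
    assert f.params["rate"] == pytest.approx(0.1, rel=0.05)


def test_exponential_aic_definition(exp_ipd):
    f = fit(exp_ipd, "exponential")
    assert f.aic == pytest.approx(2 - 2 * f.loglik)


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_information_criteria_definitions(family, weibull_ipd):
    """AIC = 2k - 2ll and BIC = k ln n - 2ll hold for every family."""
    f = fit(weibull_ipd, family)
    k = len(f.params)
    assert f.aic == pytest.approx(2 * k - 2 * f.loglik, abs=1e-9)
    assert f.bic == pytest.approx(k * np.log(f.n) - 2 * f.loglik, abs=1e-9)
    # and S(t) is a valid non-increasing survival function from 1
    t = np.linspace(0.0, 2000.0, 150)
    S = f.survival(t)
    assert S[0] == 1.0
    assert np.all(np.diff(S) <= 1e-9)
    assert np.all((0.0 <= S) & (S <= 1.0))


def test_rp_hazard_no_knots_is_weibull(weibull_ipd):
    fw = fit(weibull_ipd, "weibull")
    frp = fit(weibull_ipd, "rp_hazard", n_knots=0)
    deciles = np.quantile(weibull_ipd.times_days, np.linspace(0.1, 0.9, 9))
    assert np.max(np.abs(fw.survival(deciles) - frp.survival(deciles))) < 1e-3


def test_rp_odds_no_knots_is_loglogistic(weibull_ipd):
    fl = fit(weibull_ipd, "loglogistic")
    frp = fit(weibull_ipd, "rp_odds", n_knots=0)
    deciles = np.quantile(weibull_ipd.times_days, np.linspace(0.1, 0.9, 9))
    assert np.max(np.abs(fl.survival(deciles) - frp.survival(deciles))) < 1e-3


@pytest.mark.parametrize("family,lifelines_fitter", [
    ("weibull", "WeibullFitter"),
    ("lognormal", "LogNormalFitter"),
    ("loglogistic", "LogLogisticFitter"),
    ("exponential", "ExponentialFitter"),
])
def test_against_lifelines(family, lifelines_fitter, weibull_ipd):
    """Independent cross-check: lifelines' fitters reach the same likelihood
    and survival curve."""
    import lifelines

    f = fit(weibull_ipd, family)
    lf = getattr(lifelines, lifelines_fitter)().fit(
        weibull_ipd.times_days, weibull_ipd.events)
    assert f.loglik == pytest.approx(lf.log_likelihood_, rel=1e-5)
    t = np.quantile(weibull_ipd.times_days, [0.25, 0.5, 0.75])
    assert np.allclose(f.survival(t),
                       lf.survival_function_at_times(t).to_numpy(), atol=1e-4)


def test_mcm_tends_to_cure_fraction():
    rng = np.random.default_rng(5)
    n = 2000
    cured = rng.uniform(size=n) < 0.3
    t_unc = 100.0 * (-np.log(rng.uniform(size=n))) ** (1 / 1.4)
    t = np.where(cured, 1e6, t_unc)
    cens = np.full(n, 2000.0)
    ipd = PseudoIPD(np.minimum(t, cens), (t <= cens).astype(int))
    f = fit(ipd, "mcm")
    assert f.cure_fraction == pytest.approx(0.3, abs=0.05)
    # far beyond the uncured median the curve plateaus at the cure fraction
    median_unc = 100.0 * np.log(2.0) ** (1 / 1.4)
    assert f.survival(10 * median_unc) == pytest.approx(f.cure_fraction, abs=0.01)


def test_fit_preconditions():
    ipd = simulate_endpoint("exponential", [0.01], 50, seed=0)
    with pytest.raises(ValueError, match="unknown family"):
        fit(ipd, "gaussian")
    few = PseudoIPD(ipd.times_days[:5], ipd.events[:5])
    with pytest.raises(ValueError, match="at least 10"):
        fit(few, "weibull")
    no_events = PseudoIPD(ipd.times_days, np.zeros(len(ipd), int))
    with pytest.raises(ValueError, match="event"):
        fit(no_events, "weibull")


class TestSelect:
    @staticmethod
    def stub(family, k, ll, n=100):
        params = {f"p{i}": 0.0 for i in range(k)}
        return SurvivalFit(family, params, ll, 2 * k - 2 * ll,
                           k * np.log(n) - 2 * ll, n)

    def test_aic_penalty_breaks_loglik_tie(self):
        table = select([self.stub("two", 2, -50.0), self.stub("one", 1, -50.0)])
        assert table.iloc[0]["family"] == "one"

    def test_weibull_beats_exponential_on_weibull_data(self):
        ipd = simulate_endpoint("weibull", [1.5, 300.0], 2000, seed=8)
        table = select([fit(ipd, "exponential"), fit(ipd, "weibull")])
        assert table.iloc[0]["family"] == "weibull"

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="two fits"):
            select([self.stub("one", 1, -50.0)])

    def test_different_n_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            select([self.stub("a", 1, -50.0, n=100), self.stub("b", 1, -50.0, n=200)])


class TestSurvivalAt:
    def test_time_zero_is_one(self, weibull_ipd):
        f = fit(weibull_ipd, "weibull")
        assert survival_at(f, 0.0) == 1.0

    def test_exponential_closed_form(self, exp_ipd):
        f = fit(exp_ipd, "exponential")
        lam = f.params["rate"]
        t = np.array([1.0, 5.0, 20.0])
        assert np.allclose(survival_at(f, t), np.exp(-lam * t), rtol=1e-9)

    def test_negative_time_rejected(self, exp_ipd):
        f = fit(exp_ipd, "exponential")
        with pytest.raises(ValueError, match=">= 0"):
            survival_at(f, -1.0)


class TestApplyHR:
    def test_identity(self, exp_ipd):
        f = fit(exp_ipd, "exponential")
        c = apply_hr(f, 1.0)
        t = np.array([0.0, 3.0, 10.0])
        assert np.allclose(c.survival(t), f.survival(t))

    def test_power_rule(self):
        class Half:
            def survival(self, t):
                return np.full_like(np.asarray(t, float), 0.5)

        assert apply_hr(Half(), 2.0).survival(np.array([1.0]))[0] == pytest.approx(0.25)

    def test_exponential_rate_scaling(self, exp_ipd):
        f = fit(exp_ipd, "exponential")
        lam = f.params["rate"]
        c = apply_hr(f, 0.86)
        t = np.array([5.0, 15.0])
        assert np.allclose(c.survival(t), np.exp(-0.86 * lam * t), rtol=1e-9)

    def test_invalid_hr_rejected(self, exp_ipd):
        f = fit(exp_ipd, "exponential")
        with pytest.raises(ValueError, match="> 0"):
            apply_hr(f, 0.0)


def test_curveset_repairs_pfs_os_crossing():
    class Const:
        def __init__(self, v):
            self.v = v

        def survival(self, t):
            return np.full_like(np.asarray(t, float), self.v)

    cs = CurveSet({"arm": {"os": Const(0.4), "pfs": Const(0.6)}}, horizon_days=100.0)
    s_os, s_pfs = cs.evaluate("arm", np.array([10.0]))
    assert s_pfs[0] == pytest.approx(0.4)  # clipped to alive
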