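"""Parametric survival families: functional forms, MLE, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psmcea.reconstruct import IPDSet
from psmcea.survival import (FAMILIES, FitResult, ParametricSurvival, fit_all,
                             fit_mle, loglik, select_model)

# one realistic parameter set per family, months time scale
EXAMPLE_PARAMS = {
    "exponential": {"rate": 0.08},
    "weibull": {"shape": 1.4, "scale": 14.0},
    "gompertz": {"shape": 0.06, "rate": 0.04},
    "loglogistic": {"shape": 2.309, "scale": 13.051},
    "lognormal": {"meanlog": 2.376, "sdlog": 0.805},
}


class TestSurvivalFunction:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_starts_at_one(self, family):
        m = ParametricSurvival(family, EXAMPLE_PARAMS[family])
        assert m.survival(0.0) == pytest.approx(1.0)

    def test_loglogistic_median_at_scale(self):
        # under S(t) = 1/(1 + (t/scale)^shape) the scale is the median
        m = ParametricSurvival("loglogistic", {"shape": 2.309, "scale": 13.051})
        assert m.survival(13.051) == pytest.approx(0.5, abs=1e-12)

    def test_lognormal_median_at_exp_meanlog(self):
        m = ParametricSurvival("lognormal", {"meanlog": 2.376, "sdlog": 0.805})
        assert m.survival(math.exp(2.376)) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_monotone_nonincreasing_to_zero(self, family):
        m = ParametricSurvival(family, EXAMPLE_PARAMS[family])
        t = np.linspace(0.0, 400.0, 2000)
        s = m.survival(t)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))
        assert s[-1] < 1e-3

    def test_gompertz_negative_shape_plateaus(self):
        g, r = -0.05, 0.03
        m = ParametricSurvival("gompertz", {"shape": g, "rate": r})
        plateau = math.exp(r / g)
        assert m.survival(1e6) == pytest.approx(plateau, rel=1e-9)

    def test_negative_time_rejected(self):
        m = ParametricSurvival("exponential", {"rate": 0.1})
        with pytest.raises(ValueError):
            m.survival(-1.0)

    @pytest.mark.parametrize("family,params", [
        ("exponential", {"rate": -1.0}),
        ("weibull", {"shape": 0.0, "scale": 5.0}),
        ("lognormal", {"meanlog": 1.0, "sdlog": -0.5}),
    ])
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValueError):
            ParametricSurvival(family, params)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shape=st.floats(0.3, 5.0), scale=st.floats(0.5, 50.0),
           t1=st.floats(0.0, 100.0), t2=st.floats(0.0, 100.0))
    def test_loglogistic_monotone_property(self, shape, scale, t1, t2):
        m = ParametricSurvival("loglogistic", {"shape": shape, "scale": scale})
        lo, hi = sorted((t1, t2))
        assert m.survival(lo) >= m.survival(hi) - 1e-12

    @pytest.mark.parametrize("family", FAMILIES)
    def test_rvs_match_survival_function(self, family, rng):
        # empirical exceedance fraction at the median-ish point matches S(t)
        m = ParametricSurvival(family, EXAMPLE_PARAMS[family])
        draws = m.rvs(20000, rng)
        t0 = 10.0
        assert np.mean(draws > t0) == pytest.approx(m.survival(t0), abs=0.012)


class TestFitting:
    def test_exponential_closed_form(self, rng):
        # censoring-free exponential MLE is events / total follow-up, exactly
        times = rng.exponential(12.0, size=300)
        ipd = IPDSet(times, np.ones(300, dtype=int))
        fit = fit_mle(ipd, "exponential")
        d, total = 300, float(times.sum())
        assert fit.model.params["rate"] == d / total
        assert fit.loglik == pytest.approx(d * math.log(d / total) - d, rel=1e-12)
        assert fit.converged

    def test_exponential_with_censoring_closed_form(self, rng):
        times = rng.exponential(12.0, size=400)
        events = (times < 15.0).astype(int)
        times = np.minimum(times, 15.0)
        fit = fit_mle(IPDSet(times, events), "exponential")
        assert fit.model.params["rate"] == events.sum() / times.sum()

    def test_aic_bic_identities(self, rng):
        times = rng.weibull(1.5, 200) * 10.0
        ipd = IPDSet(times, np.ones(200, dtype=int))
        for fit in fit_all(ipd):
            k = fit.model.n_params
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, rel=1e-12)
            assert fit.bic == pytest.approx(k * math.log(200) - 2 * fit.loglik,
                                            rel=1e-12)

    def test_loglogistic_recovery_n2000(self, rng):
        truth = ParametricSurvival("loglogistic", {"shape": 2.309, "scale": 13.051})
        times = truth.rvs(2000, rng)
        fit = fit_mle(IPDSet(times, np.ones(2000, dtype=int)), "loglogistic")
        assert fit.model.params["shape"] == pytest.approx(2.309, rel=0.05)
        assert fit.model.params["scale"] == pytest.approx(13.051, rel=0.05)

    def test_fitted_loglik_beats_perturbed(self, rng):
        # the optimum really is a maximum of the censored log-likelihood
        truth = ParametricSurvival("weibull", {"shape": 1.4, "scale": 14.0})
        times = np.minimum(truth.rvs(500, rng), 24.0)
        events = (times < 24.0).astype(int)
        ipd = IPDSet(times, events)
        fit = fit_mle(ipd, "weibull")
        for factor in (0.9, 1.1):
            worse = ParametricSurvival("weibull", {
                "shape": fit.model.params["shape"] * factor,
                "scale": fit.model.params["scale"]})
            assert loglik(worse, times, events) <= fit.loglik + 1e-8

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_mle(IPDSet(np.ones(10), np.zeros(10, dtype=int)), "weibull")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_median_error(self, family):
        # median relative parameter error over 20 simulated datasets (n=1000)
        truth = ParametricSurvival(family, EXAMPLE_PARAMS[family])
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            times = truth.rvs(1000, rng)
            fit = fit_mle(IPDSet(times, np.ones(1000, dtype=int)), family)
            for name, true_val in EXAMPLE_PARAMS[family].items():
                errs.append(abs(fit.model.params[name] - true_val) / abs(true_val))
        assert np.median(errs) < 0.10


class TestSelection:
    def _fit(self, family, loglik, n=100):
        model = ParametricSurvival(family, EXAMPLE_PARAMS[family])
        return FitResult.from_loglik(model, loglik, n)

    def test_single_candidate(self):
        fit = self._fit("weibull", -500.0)
        assert select_model([fit]) is fit

    def test_min_aic_wins(self):
        a, b = self._fit("weibull", -500.0), self._fit("lognormal", -490.0)
        assert select_model([a, b]) is b

    def test_aic_tie_broken_by_bic(self):
        # same loglik: 1-parameter exponential has lower AIC *and* BIC, so
        # construct an exact AIC tie between two 2-parameter families with
        # different n (hence different BIC)
        a = self._fit("weibull", -500.0, n=100)
        b = self._fit("lognormal", -500.0, n=50)
        assert a.aic == b.aic and b.bic < a.bic
        assert select_model([a, b]) is b

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_recovers_generating_family_large_n(self, rng):
        truth = ParametricSurvival("loglogistic", {"shape": 2.309, "scale": 13.051})
        times = truth.rvs(2000, rng)
        ipd = IPDSet(times, np.ones(2000, dtype=int))
        best = select_model(fit_all(ipd))
        assert best.model.family == "loglogistic"


def test_cross_check_against_lifelines(rng):
    """Our MLE agrees with lifelines' fitters on the families both cover."""
    from lifelines import (ExponentialFitter, LogLogisticFitter,
                           LogNormalFitter, WeibullFitter)
    truth = ParametricSurvival("weibull", {"shape": 1.4, "scale": 14.0})
    times = np.minimum(truth.rvs(800, rng), 30.0)
    events = (times < 30.0).astype(int)
    ipd = IPDSet(times, events)
    pairs = [
        ("exponential", ExponentialFitter(), lambda f: {"rate": 1.0 / f.lambda_}),
        ("weibull", WeibullFitter(),
         lambda f: {"shape": f.rho_, "scale": f.lambda_}),
        ("loglogistic", LogLogisticFitter(),
         lambda f: {"shape": f.beta_, "scale": f.alpha_}),
        ("lognormal", LogNormalFitter(),
         lambda f: {"meanlog": f.mu_, "sdlog": f.sigma_}),
    ]
    for family, fitter, extract in pairs:
        ours = fit_mle(ipd, family)
        fitter.fit(times, events)
        for name, theirs in extract(fitter).items():
            assert ours.model.params[name] == pytest.approx(theirs, rel=1e-3)
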