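"""Median residual life regression: oracles, closed forms, invariances."""

import numpy as np
import pytest
from scipy import stats

from merlcross import (
    DegenerateRiskSetError,
    MedianResidualLifeRegressor,
    fit_merl_parametric,
    fit_merl_semiparametric,
    km_censoring_survivor,
    predict_median_residual,
)

LN2 = np.log(2.0)


class TestCensoringSurvivor:
    def test_no_censoring_is_unity(self):
        g = km_censoring_survivor([1.0, 2.0, 3.0], [True, True, True])
        for t in (0.0, 1.5, 10.0):
            assert g(t) == 1.0

    def test_hand_computed_single_censoring(self):
        # censoring "event" at 4 with 2 at risk: G = 1 below 4, 1/2 after
        g = km_censoring_survivor([2.0, 4.0, 6.0], [True, False, True])
        assert g(3.9) == 1.0
        assert g(4.0) == pytest.approx(0.5)
        assert g(100.0) == pytest.approx(0.5)
        assert g.left(4.0) == 1.0  # left limit excludes the jump at 4

    def test_nonincreasing(self, rng):
        t = rng.exponential(2.0, 200)
        e = rng.random(200) < 0.6
        g = km_censoring_survivor(t, e)
        grid = np.linspace(0, t.max(), 300)
        vals = g(grid)
        assert np.all(np.diff(vals) <= 1e-12)
        assert g(0.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_censoring_survivor([], [])


class TestSemiparametric:
    def test_intercept_only_equals_sample_median(self):
        fit = fit_merl_semiparametric(
            [1.0, 2.0, 3.0, 4.0, 5.0], [True] * 5, None, t0=0.0, min_events=3)
        assert np.exp(fit.coef_[0]) == pytest.approx(3.0)

    @pytest.mark.parametrize("t0", [0.0, 0.7, 1.5, 2.9])
    def test_intercept_only_brute_force_any_t0(self, rng, t0):
        times = rng.exponential(3.0, 41) + 0.05
        fit = fit_merl_semiparametric(times, [True] * 41, None, t0=t0)
        resid = np.sort(times[times > t0] - t0)
        assert np.exp(fit.coef_[0]) == pytest.approx(np.median(resid))

    def test_binary_covariate_recovers_log_scale_ratio(self, rng):
        # covariate doubles the exponential scale => beta1 -> log 2
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n) * np.where(x == 1, 2.0, 1.0)
        fit = fit_merl_semiparametric(t, [True] * n, x[:, None], t0=0.0)
        # 3 x asymptotic SE of a log median difference at n/2 per group
        assert fit.coef_[1] == pytest.approx(np.log(2.0), abs=0.2)

    def test_ipcw_weighting_corrects_random_censoring(self, rng):
        # heavy random censoring; weighted median of events should still
        # land near the true median (ln 2 for unit exponential)
        n = 4000
        t = rng.exponential(1.0, n)
        c = rng.exponential(2.0, n)
        obs, d = np.minimum(t, c), t <= c
        fit = fit_merl_semiparametric(obs, d, None, t0=0.0)
        assert np.exp(fit.coef_[0]) == pytest.approx(LN2, rel=0.08)

    def test_degenerate_risk_set_raises(self):
        times = [1.0, 2.0, 3.0, 10.0, 10.0, 10.0]
        events = [True, True, True, False, False, False]
        with pytest.raises(DegenerateRiskSetError, match="parametric"):
            fit_merl_semiparametric(times, events, None, t0=10.0)


class TestParametric:
    def test_exponential_closed_form_mle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        fit = fit_merl_parametric(times, [True] * 5, None, family="exponential")
        assert np.exp(fit.coef_[0]) == pytest.approx(times.mean(), rel=1e-5)

    def test_exponential_censored_closed_form(self):
        # scale MLE with right censoring: sum(t) / sum(delta)
        times = np.array([1.0, 2.0, 3.0, 5.0, 5.0])
        events = np.array([True, True, True, False, False])
        fit = fit_merl_parametric(times, events, None, family="exponential")
        assert np.exp(fit.coef_[0]) == pytest.approx(times.sum() / 3.0, rel=1e-5)

    def test_weibull_parameter_recovery(self, rng):
        shape, decay = 0.95, 0.29           # density s*d*x^(s-1)*exp(-d*x^s)
        scale = decay ** (-1.0 / shape)
        t = stats.weibull_min(c=shape, scale=scale).rvs(2000, random_state=rng)
        fit = fit_merl_parametric(t, [True] * 2000, None, family="weibull")
        # 3 x asymptotic MLE SEs at n=2000
        assert fit.shape_ == pytest.approx(shape, rel=0.06)
        assert np.exp(fit.coef_[0]) == pytest.approx(scale, rel=0.08)

    def test_weibull_nests_exponential(self, rng):
        t = rng.exponential(3.0, 1500)
        x = rng.normal(size=(1500, 1))
        wei = fit_merl_parametric(t, [True] * 1500, x, family="weibull")
        exp = fit_merl_parametric(t, [True] * 1500, x, family="exponential")
        assert wei.shape_ == pytest.approx(1.0, abs=0.06)
        np.testing.assert_allclose(wei.coef_, exp.coef_, atol=0.08)

    def test_matches_lifelines_weibull_aft(self, rng):
        # independent cross-check of the censored Weibull AFT likelihood
        import pandas as pd
        from lifelines import WeibullAFTFitter

        n = 300
        x = rng.normal(size=n)
        t = rng.weibull(1.4, n) * 3.0 * np.exp(0.5 * x)
        c = rng.exponential(6.0, n)
        obs, d = np.minimum(t, c), t <= c
        ours = fit_merl_parametric(obs, d, x[:, None], family="weibull")
        df = pd.DataFrame({"t": obs, "e": d.astype(int), "x": x})
        ll = WeibullAFTFitter().fit(df, duration_col="t", event_col="e")
        theirs_b0 = ll.params_[("lambda_", "Intercept")]
        theirs_b1 = ll.params_[("lambda_", "x")]
        theirs_shape = np.exp(ll.params_[("rho_", "Intercept")])
        assert ours.coef_[0] == pytest.approx(theirs_b0, abs=1e-3)
        assert ours.coef_[1] == pytest.approx(theirs_b1, abs=1e-3)
        assert ours.shape_ == pytest.approx(theirs_shape, rel=1e-3)

    def test_fallback_needs_event(self):
        with pytest.raises(ValueError, match="event"):
            fit_merl_parametric([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                                [False] * 6, None)


class TestPrediction:
    def test_zero_coefficients_give_unity(self):
        reg = MedianResidualLifeRegressor(route="semiparametric", t0=1.0)
        reg.coef_ = np.zeros(1)
        reg.coef_names_ = ["intercept"]
        assert reg.predict(np.empty((3, 0)), t0=1.0) == pytest.approx([1.0] * 3)

    def test_exponential_memorylessness(self, rng):
        t = rng.exponential(4.0, 500)
        fit = fit_merl_parametric(t, [True] * 500, None, family="exponential")
        x = np.empty((1, 0))
        m = [predict_median_residual(fit, t0, x)[0] for t0 in (0.0, 1.0, 5.0, 20.0)]
        assert np.ptp(m) < 1e-9
        assert m[0] == pytest.approx(LN2 * np.exp(fit.coef_[0]))

    def test_weibull_unconditional_median_at_zero(self, rng):
        t = rng.weibull(1.7, 800) * 5.0
        fit = fit_merl_parametric(t, [True] * 800, None, family="weibull")
        scale, s = np.exp(fit.coef_[0]), fit.shape_
        m0 = predict_median_residual(fit, 0.0, np.empty((1, 0)))[0]
        assert m0 == pytest.approx(scale * LN2 ** (1.0 / s), rel=1e-9)
        # and against direct numeric inversion of the fitted survivor
        dist = stats.weibull_min(c=s, scale=scale)
        assert m0 == pytest.approx(dist.ppf(0.5), rel=1e-9)

    def test_lognormal_median_residual_against_numeric_inversion(self, rng):
        t = np.exp(rng.normal(1.0, 0.6, 600))
        fit = fit_merl_parametric(t, [True] * 600, None, family="lognormal")
        mu, sigma = fit.coef_[0], fit.shape_
        t0 = 3.0
        m = predict_median_residual(fit, t0, np.empty((1, 0)))[0]
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        target = 0.5 * dist.sf(t0)
        assert dist.sf(t0 + m) == pytest.approx(target, rel=1e-8)

    def test_covariate_mismatch_raises(self, rng):
        t = rng.exponential(2.0, 50)
        fit = fit_merl_parametric(t, [True] * 50, rng.normal(size=(50, 2)))
        with pytest.raises(ValueError, match="covariates"):
            fit.predict(rng.normal(size=(5, 3)))


class TestInvariances:
    @pytest.mark.parametrize("family", ["weibull", "exponential", "lognormal"])
    def test_positivity(self, rng, family):
        t = rng.gamma(2.0, 2.0, 120)
        d = rng.random(120) < 0.8
        x = rng.normal(size=(120, 1))
        fit = fit_merl_parametric(t, d, x, family=family)
        grid = np.linspace(-2, 2, 9)[:, None]
        for t0 in (0.0, 1.0, float(np.quantile(t, 0.8))):
            assert (fit.predict(grid, t0=t0) > 0).all()

    @pytest.mark.parametrize("route", ["parametric", "semiparametric"])
    def test_scale_equivariance(self, rng, route):
        t = rng.gamma(2.0, 2.0, 150)
        x = rng.normal(size=(150, 1))
        c, t0 = 3.7, 1.2
        kw = dict(route=route, t0=t0) if route == "semiparametric" else dict(route=route)
        base = MedianResidualLifeRegressor(**kw).fit(x, (t, [True] * 150))
        scaled = MedianResidualLifeRegressor(
            **(dict(route=route, t0=c * t0) if route == "semiparametric"
               else dict(route=route))).fit(x, (c * t, [True] * 150))
        grid = np.linspace(-1, 1, 5)[:, None]
        np.testing.assert_allclose(
            scaled.predict(grid, t0=c * t0),
            c * base.predict(grid, t0=t0), rtol=1e-4)

    def test_parametric_matches_empirical_conditional_median(self, rng):
        # large uncensored sample: m(0|x) ~= empirical median given x
        n = 6000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.weibull(1.3, n) * 2.0 * np.exp(0.7 * x)
        fit = fit_merl_parametric(t, [True] * n, x[:, None], family="weibull")
        for v in (0.0, 1.0):
            pred = fit.predict(np.array([[v]]), t0=0.0)[0]
            emp = np.median(t[x == v])
            assert pred == pytest.approx(emp, rel=0.06)
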