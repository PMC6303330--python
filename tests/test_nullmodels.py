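import numpy as np
import pytest

from paleospd.errors import ArgumentError
from paleospd.nullmodels import (
    fit_breakpoint,
    fit_exponential_null,
    fit_logistic_null,
    poisson_loglink_fit,
)


def change_point_series(make_series, oldest=16000, youngest=10000,
                        bp=13000, r_up=0.0008, r_down=-0.002):
    grid = np.arange(oldest, youngest - 1, -1)
    t = (grid[0] - grid).astype(float)
    tb = float(oldest - bp)
    y = np.where(t <= tb, np.exp(r_up * t),
                 np.exp(r_up * tb + r_down * (t - tb)))
    return make_series(y, oldest=oldest)


class TestPoissonIrls:
    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        t = np.arange(300.0)
        y = np.exp(0.004 * t) * rng.uniform(0.8, 1.2, t.size)
        b0, b1, dev = poisson_loglink_fit(t, y)
        X = sm.add_constant(t)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert b0 == pytest.approx(glm.params[0], abs=1e-8)
        assert b1 == pytest.approx(glm.params[1], abs=1e-10)
        assert dev == pytest.approx(glm.deviance, rel=1e-8)

    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(500.0)
        y = 0.01 * np.exp(0.003 * t)
        b0, b1, dev = poisson_loglink_fit(t, y)
        assert b1 == pytest.approx(0.003, rel=1e-10)
        assert b0 == pytest.approx(np.log(0.01), abs=1e-9)
        assert dev == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_raises(self):
        with pytest.raises(ArgumentError):
            poisson_loglink_fit(np.arange(10.0), np.zeros(10))


class TestFitBreakpoint:
    def test_noiseless_change_point_recovered(self, make_series):
        spd = change_point_series(make_series)
        fit = fit_breakpoint(spd, (15000, 11000))
        assert abs(fit.breakpoint_cal_bp - 13000) <= 50
        assert not fit.no_interior_optimum
        assert fit.slope_pre > 0 > fit.slope_post

    def test_single_slope_series_has_no_interior_optimum(self, make_series):
        grid_t = np.arange(6001.0)
        spd = make_series(np.exp(0.0005 * grid_t), oldest=16000)
        fit = fit_breakpoint(spd, (15000, 11000))
        assert fit.no_interior_optimum

    def test_search_margin_precondition(self, make_series):
        spd = change_point_series(make_series)
        with pytest.raises(ArgumentError):
            fit_breakpoint(spd, (15900, 11000))

    def test_all_zero_window_raises(self, make_series):
        spd = make_series(np.zeros(6001), oldest=16000)
        with pytest.raises(ArgumentError):
            fit_breakpoint(spd, (15000, 11000))

    def test_estimate_improves_as_noise_shrinks(self, make_series):
        errs = {}
        for sd in (0.10, 0.01):
            rng = np.random.default_rng(42)
            spd = change_point_series(make_series)
            noisy = make_series(
                spd.values * (1 + sd * rng.standard_normal(spd.values.size)),
                oldest=16000,
            )
            fit = fit_breakpoint(noisy, (15000, 11000))
            errs[sd] = abs(fit.breakpoint_cal_bp - 13000)
        assert errs[0.01] <= errs[0.10]


class TestExponentialNull:
    def test_noiseless_input_reproduced_on_fit_window(self, make_series):
        grid_t = np.arange(10001.0)
        y = 0.005 * np.exp(0.0004 * grid_t)
        spd = make_series(y, oldest=20000)
        null = fit_exponential_null(spd, 20000, 13000)
        sl = slice(0, 20000 - 13000 + 1)
        np.testing.assert_allclose(null.fitted[sl], y[sl], rtol=1e-6)

    def test_extrapolation_is_exactly_loglinear(self, make_series):
        spd = change_point_series(make_series, oldest=20000)
        null = fit_exponential_null(spd, 20000, 13000)
        i_bp = 20000 - 13000
        lhs = np.log(null.fitted[i_bp + 1000])
        rhs = np.log(null.fitted[i_bp]) + 1000 * null.beta1
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_matches_closed_form_wls_on_noiseless_input(self, make_series):
        # for noiseless model-true data the IRLS solution equals the
        # log-scale ordinary least squares solution (independent oracle)
        grid_t = np.arange(5001.0)
        y = 0.02 * np.exp(0.0006 * grid_t)
        spd = make_series(y, oldest=15000)
        null = fit_exponential_null(spd, 15000, 10500)
        t_fit = grid_t[: 15000 - 10500 + 1]
        coeffs = np.polyfit(t_fit, np.log(y[: t_fit.size]), 1)
        assert null.beta1 == pytest.approx(coeffs[0], rel=1e-8)

    def test_fit_window_too_small_raises(self, make_series):
        spd = change_point_series(make_series, oldest=20000)
        with pytest.raises(ArgumentError):
            fit_exponential_null(spd, 13005, 13000)
        with pytest.raises(ArgumentError):
            fit_exponential_null(spd, 13000, 13000)


class TestLogisticNull:
    def richards_series(self, make_series, A=0.002, K=0.05, B=0.0015, M=5000.0, nu=1.2):
        grid_t = np.arange(10001.0)
        y = A + (K - A) / (1 + np.exp(-B * (grid_t - M))) ** (1 / nu)
        return make_series(y, oldest=20000), (A, K, B, M, nu)

    def test_noiseless_upper_asymptote_recovered(self, make_series):
        spd, truth = self.richards_series(make_series)
        fit = fit_logistic_null(spd, 20000, 10500, starts=25,
                                rng=np.random.default_rng(5))
        assert fit.K == pytest.approx(truth[1], rel=0.10)
        assert fit.converged

    def test_exponential_phase_data_pushes_asymptote_high(self, make_series):
        grid_t = np.arange(10001.0)
        y = 0.001 * np.exp(0.0004 * grid_t)
        spd = make_series(y, oldest=20000)
        fit = fit_logistic_null(spd, 20000, 10500, starts=25,
                                rng=np.random.default_rng(6))
        assert fit.K > 2.0 * y.max()

    def test_fixed_zero_lower_asymptote_keeps_fit_nonnegative(self, make_series):
        spd, _ = self.richards_series(make_series, A=0.0)
        fit = fit_logistic_null(spd, 20000, 10500, starts=10,
                                rng=np.random.default_rng(7), fix_A_zero=True)
        assert np.all(fit.fitted >= 0)
        assert fit.A <= 1e-10
        # fitted stays within the asymptotes
        assert fit.fitted.max() <= fit.K * (1 + 1e-9)
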