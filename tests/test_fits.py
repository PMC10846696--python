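import numpy as np
import pytest

from hyphamap.fits import (FitError, adjust_t0, fit_doubling,
                           fit_exponential_counts, fit_linear_area)


def _doubling(t, X0, tau, t0=0.0):
    return X0 * 2.0 ** ((t + t0) / tau)


class TestFitDoubling:
    def test_noiseless_recovery(self):
        t = np.linspace(1.0, 12.0, 15)
        X = _doubling(t, 3.0, 2.09)
        fit = fit_doubling(t, X, np.sqrt(X))
        assert fit.tau == pytest.approx(2.09, abs=1e-6)
        assert fit.X0 == pytest.approx(3.0, rel=1e-6)

    def test_t0_offset_recovery(self):
        t = np.linspace(1.0, 12.0, 15)
        X = _doubling(t, 3.0, 2.0, t0=-0.5)
        fit = fit_doubling(t, X, np.sqrt(X), t0=-0.5)
        assert fit.tau == pytest.approx(2.0, abs=1e-6)
        assert fit.X0 == pytest.approx(3.0, rel=1e-6)

    def test_predict_matches_model(self):
        t = np.linspace(0.5, 8.0, 12)
        X = _doubling(t, 2.0, 1.7)
        fit = fit_doubling(t, X, np.sqrt(X))
        assert fit.predict(4.0) == pytest.approx(_doubling(4.0, 2.0, 1.7),
                                                 rel=1e-6)

    def test_point_order_invariance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(1.0, 10.0, 10)
        X = _doubling(t, 3.0, 2.5) * rng.normal(1.0, 0.02, size=10)
        s = np.sqrt(X)
        perm = rng.permutation(10)
        a = fit_doubling(t, X, s)
        b = fit_doubling(t[perm], X[perm], s[perm])
        assert a.tau == pytest.approx(b.tau, rel=1e-6)

    def test_window_restricts_points(self):
        t = np.linspace(0.0, 12.0, 13)
        X = _doubling(t, 3.0, 2.0)
        X[:3] = 3.0                           # flat lag phase
        fit = fit_doubling(t, X, np.sqrt(X), window=(3.0, 12.0))
        assert fit.n_points == 10
        assert fit.tau == pytest.approx(2.0, abs=1e-6)

    def test_poisson_coverage(self):
        # 200 MC replicates: tau within +-2 reported sd in >= 95%
        rng = np.random.default_rng(42)
        t = np.linspace(1.0, 10.0, 50)
        mu = _doubling(t, 20.0, 2.0)
        hits = 0
        for _ in range(200):
            X = rng.poisson(mu).astype(float)
            good = X > 0
            fit = fit_doubling(t[good], X[good], np.sqrt(X[good]))
            if abs(fit.tau - 2.0) <= 2.0 * fit.tau_sd:
                hits += 1
        assert hits >= 190

    def test_chi2_reduced_near_one(self):
        rng = np.random.default_rng(7)
        t = np.linspace(1.0, 10.0, 200)
        mu = _doubling(t, 20.0, 2.0)
        X = rng.poisson(mu).astype(float)
        fit = fit_doubling(t, X, np.sqrt(X))
        assert 0.5 < fit.chi2_reduced < 2.0

    def test_errors(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(FitError):
            fit_doubling(t[:2], np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        with pytest.raises(FitError):
            fit_doubling(t, np.full(4, 5.0), np.ones(4))     # constant
        with pytest.raises(FitError):
            fit_doubling(t, np.array([8.0, 4.0, 2.0, 1.0]), np.ones(4))
        with pytest.raises(FitError):
            fit_doubling(t, np.array([1.0, 2.0, 4.0, 8.0]),
                         np.array([1.0, 0.0, 1.0, 1.0]))     # bad sigma


class TestAdjustT0:
    def test_recovers_common_offset(self):
        t = np.linspace(1.0, 12.0, 15)
        t0_true = -0.4
        series = {
            "A": (t, _doubling(t, 3.0, 2.0, t0_true),
                  np.sqrt(_doubling(t, 3.0, 2.0, t0_true))),
            "N": (t, _doubling(t, 1.0, 1.8, t0_true),
                  np.sqrt(_doubling(t, 1.0, 1.8, t0_true))),
        }
        expected = {"A": (2.5, 3.5), "N": (0.8, 1.2)}
        grid = np.arange(-1.0, 0.41, 0.05)
        t0_best, fits = adjust_t0(series, expected, grid)
        assert t0_best == pytest.approx(t0_true, abs=0.051)
        assert fits["A"].tau == pytest.approx(2.0, rel=1e-3)


class TestFitLinearArea:
    def test_exact_line(self):
        t = np.linspace(2.0, 10.0, 9)
        S = 3.2 * t - 1.5
        fit = fit_linear_area(t, S, 2.0, 10.0)
        assert fit.slope == pytest.approx(3.2, rel=1e-9)
        assert fit.intercept == pytest.approx(-1.5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_sd_nan(self):
        fit = fit_linear_area(np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                              1.0, 2.0)
        assert np.isnan(fit.slope_sd)
        assert fit.n_points == 2

    def test_window_excludes_points(self):
        t = np.linspace(0.0, 10.0, 11)
        S = np.where(t < 4.0, 0.0, 2.0 * (t - 4.0))
        fit = fit_linear_area(t, S, 4.0, 10.0)
        assert fit.slope == pytest.approx(2.0, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_linear_area(np.array([1.0]), np.array([1.0]), 0.0, 2.0)


class TestFitExponentialCounts:
    def test_noiseless_recovery(self):
        t = np.linspace(0.0, 10.0, 30)
        c = 6.0 * np.exp(0.5 * t)
        fit = fit_exponential_counts(t, c, count_window=(5, 10_000))
        assert fit.alpha == pytest.approx(0.5, abs=1e-9)
        assert fit.beta == pytest.approx(6.0, rel=1e-9)

    def test_count_window_exclusion(self):
        t = np.linspace(0.0, 10.0, 30)
        c = 6.0 * np.exp(0.5 * t)
        c[c > 336] = 400.0                       # corrupt out-of-window tail
        c[c < 5] = 2.0                           # corrupt head
        fit = fit_exponential_counts(t, c, count_window=(5, 336))
        assert fit.alpha == pytest.approx(0.5, abs=1e-9)

    def test_loglinear_vs_nls(self):
        t = np.linspace(0.0, 8.0, 25)
        c = 6.0 * np.exp(0.4 * t)
        a = fit_exponential_counts(t, c, count_window=(1, 1e9),
                                   method="loglinear")
        b = fit_exponential_counts(t, c, count_window=(1, 1e9), method="nls")
        assert a.alpha == pytest.approx(b.alpha, abs=1e-6)

    def test_errors(self):
        t = np.linspace(0.0, 5.0, 6)
        with pytest.raises(FitError):
            fit_exponential_counts(t, np.full(6, 100.0),
                                   count_window=(200, 336))   # nothing inside
        with pytest.raises(ValueError):
            fit_exponential_counts(t, np.exp(t), method="nonsense")
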