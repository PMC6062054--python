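"""Base estimators: OLS, robust IRLS and the profiled nonlinear fit."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import brute, curve_fit, fmin

from chamberflux import (
    ChamberSystem,
    ConcentrationSeries,
    InvalidInputError,
    aic_of_fit,
    conversion_factor,
    fit_hmr,
    fit_linear,
    fit_robust_linear,
    hmr_profile_sse,
)
from chamberflux.regression import KAPPA_HI, KAPPA_LO, hmr_start_kappa

from conftest import make_hmr_series


class TestFitLinear:
    def test_matches_statsmodels_ols_to_12_digits(self, case_system, times4):
        rng = np.random.default_rng(1)
        y = 325.0 + 0.01 * times4 + rng.normal(0, 3, 4)
        s = ConcentrationSeries(times4, y, case_system)
        fit = fit_linear(s)
        ols = sm.OLS(y, sm.add_constant(times4)).fit()
        scale = 0.2 * conversion_factor(case_system)
        assert fit.flux == pytest.approx(ols.params[1] * scale, rel=1e-12)
        assert fit.sse == pytest.approx(float(ols.ssr), rel=1e-10)
        assert fit.se_flux == pytest.approx(float(ols.bse[1]) * scale, rel=1e-10)

    def test_recovers_flux_in_linear_limit(self, case_system):
        s = make_hmr_series(case_system, f0=1.0, kappa=1e-8)
        assert fit_linear(s).flux == pytest.approx(1.0, abs=1e-3)

    def test_constant_series_zero_flux(self, case_system, times4):
        s = ConcentrationSeries(times4, np.full(4, 330.0), case_system)
        assert fit_linear(s).flux == 0.0

    def test_slope_sampling_sd_matches_theory(self, case_system, times4):
        # closed form: sd(slope) = sd_gc / sqrt(sum((t-tbar)^2)) = 3/sqrt(2592000)
        rng = np.random.default_rng(2)
        scale = 0.2 * conversion_factor(case_system)
        expected_sd = 3.0 / math.sqrt(2_592_000.0) * scale
        fluxes = []
        for _ in range(2000):
            y = 325.0 + rng.normal(0, 3, 4)
            fluxes.append(fit_linear(ConcentrationSeries(times4, y, case_system)).flux)
        assert np.std(fluxes) == pytest.approx(expected_sd, rel=0.05)


class TestFitRobustLinear:
    def test_clean_data_equals_ols(self, case_system, times4):
        y = 325.0 + 0.01 * times4
        s = ConcentrationSeries(times4, y, case_system)
        assert fit_robust_linear(s).flux == pytest.approx(fit_linear(s).flux, rel=1e-9)

    def test_downweights_gross_middle_outlier(self, case_system, times4):
        y = 325.0 + 0.01 * times4
        y_out = y.copy()
        y_out[1] += 40.0
        s = ConcentrationSeries(times4, y_out, case_system)
        rob = fit_robust_linear(s).flux
        ols = fit_linear(s).flux
        # consensus: OLS slope of the three clean points
        tt = np.delete(times4, 1)
        yy = np.delete(y_out, 1)
        consensus = (
            np.sum((tt - tt.mean()) * (yy - yy.mean())) / np.sum((tt - tt.mean()) ** 2)
            * 0.2 * conversion_factor(case_system)
        )
        assert abs(rob - consensus) < abs(ols - consensus)

    def test_agrees_with_statsmodels_rlm_large_n(self, case_system):
        # the four-point endpoint rule is inactive at n=30
        rng = np.random.default_rng(3)
        t = np.linspace(0, 3600, 30)
        y = 325.0 + 0.02 * t + rng.normal(0, 3, 30)
        y[rng.integers(0, 30, 3)] += 25.0
        s = ConcentrationSeries(t, y, case_system)
        mine = fit_robust_linear(s)
        smf = sm.RLM(y, sm.add_constant(t), M=sm.robust.norms.HuberT(1.345)).fit()
        assert mine.params.slope == pytest.approx(float(smf.params[1]), rel=1e-2)

    def test_symmetric_noise_consistent_with_ols(self, case_system, times4):
        rng = np.random.default_rng(4)
        rob, ols = [], []
        for _ in range(400):
            y = 325.0 + 0.01 * times4 + rng.normal(0, 3, 4)
            s = ConcentrationSeries(times4, y, case_system)
            rob.append(fit_robust_linear(s).flux)
            ols.append(fit_linear(s).flux)
        se = np.std(ols) / math.sqrt(len(ols))
        assert abs(np.mean(rob) - np.mean(ols)) < 3 * se


class TestHmrProfileSse:
    def test_noiseless_inversion_at_true_kappa(self, case_system):
        s = make_hmr_series(case_system, f0=2.0, kappa=1e-3)
        phi, f0, sse = hmr_profile_sse(s, 1e-3)
        conv = conversion_factor(case_system)
        phi_true = 325.0 + 2.0 / (conv * 1e-3 * 0.2)
        assert phi == pytest.approx(phi_true, rel=1e-10)
        assert f0 == pytest.approx(2.0, rel=1e-10)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_misspecified_kappa_positive_sse(self, case_system):
        s = make_hmr_series(case_system, f0=2.0, kappa=1e-3)
        _, _, sse = hmr_profile_sse(s, 5e-3)
        assert sse > 1e-3

    def test_matches_brute_force_grid_oracle(self, case_system, times4):
        rng = np.random.default_rng(5)
        y = 325.0 + np.array([0.0, 20.0, 28.0, 31.0]) + rng.normal(0, 1, 4)
        s = ConcentrationSeries(times4, y, case_system)
        kappa = 1.3e-3
        phi_hat, _, sse_hat = hmr_profile_sse(s, kappa)

        x = np.exp(-kappa * times4)

        def sse_of(params):
            phi, beta = params
            return float(np.sum((y - phi - beta * x) ** 2))

        coarse = brute(
            sse_of, ((y.min() - 200, y.max() + 200), (-400.0, 400.0)), Ns=60,
            finish=None,
        )
        refined = fmin(sse_of, coarse, xtol=1e-12, ftol=1e-14, disp=False)
        assert sse_hat <= sse_of(refined) * (1 + 1e-6)

    def test_nonpositive_kappa_rejected(self, case_system, times4):
        s = ConcentrationSeries(times4, np.full(4, 325.0), case_system)
        with pytest.raises(InvalidInputError):
            hmr_profile_sse(s, 0.0)


class TestFitHmr:
    @pytest.mark.parametrize("kappa", [1e-6, 1e-4, 1e-3, 5e-3, 1e-2])
    def test_noiseless_parameter_recovery(self, case_system, kappa):
        s = make_hmr_series(case_system, f0=2.0, kappa=kappa)
        fit = fit_hmr(s)
        assert fit.converged
        assert fit.params.kappa == pytest.approx(kappa, rel=1e-4)
        assert fit.flux == pytest.approx(2.0, rel=1e-4)
        conv = conversion_factor(case_system)
        assert fit.params.phi == pytest.approx(
            325.0 + 2.0 / (conv * kappa * 0.2), rel=1e-4
        )

    def test_negative_flux_recovery(self, case_system):
        s = make_hmr_series(case_system, f0=-1.5, kappa=1e-3)
        fit = fit_hmr(s)
        assert fit.converged
        assert fit.flux == pytest.approx(-1.5, rel=1e-4)

    def test_noiseless_linear_series_does_not_converge(self, case_system):
        s = make_hmr_series(case_system, f0=1.0, kappa=0.0)
        fit = fit_hmr(s)
        assert not fit.converged
        assert fit.flux is None and fit.params is None

    def test_constant_series_does_not_converge(self, case_system, times4):
        s = ConcentrationSeries(times4, np.full(4, 325.0), case_system)
        assert not fit_hmr(s).converged

    def test_agrees_with_scipy_curve_fit(self, case_system, times4):
        rng = np.random.default_rng(6)
        n_checked = 0
        for _ in range(50):
            s = make_hmr_series(case_system, f0=2.0, kappa=1e-3, sd=0.5, rng=rng)
            fit = fit_hmr(s)
            if not fit.converged:
                continue

            def model(t, phi, beta, k):
                return phi + beta * np.exp(-k * t)

            y = s.concentrations
            p0 = (y[-1], y[0] - y[-1], hmr_start_kappa(s))
            popt, _ = curve_fit(model, times4, y, p0=p0, maxfev=10000)
            scale = 0.2 * conversion_factor(case_system)
            assert fit.params.kappa == pytest.approx(popt[2], rel=1e-5)
            assert fit.flux == pytest.approx(-popt[1] * popt[2] * scale, rel=1e-5)
            n_checked += 1
        assert n_checked >= 30

    def test_kappa_always_within_bounds(self, case_system, times4):
        rng = np.random.default_rng(7)
        for _ in range(300):
            y = 325.0 + rng.normal(0, 3, 4) + rng.uniform(0, 0.02) * times4
            fit = fit_hmr(ConcentrationSeries(times4, y, case_system))
            if fit.converged:
                assert KAPPA_LO < fit.params.kappa < KAPPA_HI
                assert fit.sse >= 0

    def test_sse_is_local_optimum_of_profile(self, case_system, times4):
        # within its basin the fitted SSE beats nearby profile evaluations
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(50):
            s = make_hmr_series(case_system, f0=1.0, kappa=1e-3, sd=1.0, rng=rng)
            fit = fit_hmr(s)
            if not fit.converged:
                continue
            k_hat = fit.params.kappa
            for delta in (1e-3, 1e-2, 5e-2):
                for k_probe in (k_hat * (1 + delta), k_hat * (1 - delta)):
                    _, _, sse_probe = hmr_profile_sse(s, k_probe)
                    assert fit.sse <= sse_probe * (1 + 1e-9)
            checked += 1
        assert checked >= 30

    def test_sse_below_linear_when_converged(self, case_system, times4):
        rng = np.random.default_rng(9)
        for _ in range(100):
            y = 325.0 + rng.normal(0, 3, 4) + 0.01 * times4
            s = ConcentrationSeries(times4, y, case_system)
            fit = fit_hmr(s)
            if fit.converged:
                assert fit.sse < fit_linear(s).sse


class TestAic:
    def test_penalty_monotone_in_parameter_count(self, case_system):
        s = make_hmr_series(case_system, f0=2.0, kappa=1e-3, sd=1.0,
                            rng=np.random.default_rng(10))
        lin = fit_linear(s)
        hmr = fit_hmr(s)
        if hmr.converged and hmr.sse == pytest.approx(lin.sse):
            assert aic_of_fit(lin, 4) < aic_of_fit(hmr, 4)

    def test_halving_sse_drops_aic_by_n_log2(self, case_system, times4):
        rng = np.random.default_rng(11)
        y = 325.0 + 0.01 * times4 + rng.normal(0, 3, 4)
        s = ConcentrationSeries(times4, y, case_system)
        fit = fit_linear(s)
        n = 4
        half = fit.sse / 2
        manual = n * math.log(half / n) + 2 * 3
        assert manual == pytest.approx(aic_of_fit(fit, n) - n * math.log(2), rel=1e-12)

    def test_strong_curvature_prefers_hmr(self, case_system):
        s = make_hmr_series(case_system, f0=2.0, kappa=2e-3, sd=0.5,
                            rng=np.random.default_rng(12))
        lin = fit_linear(s)
        hmr = fit_hmr(s)
        assert hmr.converged
        assert hmr.aic < lin.aic

    def test_invalid_n_rejected(self, case_system):
        s = make_hmr_series(case_system, f0=1.0, kappa=1e-3)
        with pytest.raises(InvalidInputError):
            aic_of_fit(fit_linear(s), 0)
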