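"""Segmented-regression estimation against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from opioid_its import (
    FitError,
    SyntheticConfig,
    build_design,
    durbin_watson,
    fit_ar1_ml,
    fit_its,
    fit_ols,
    post_slope,
    predict_lines,
    residual_diagnostics,
    simulate_series,
)
from opioid_its.its_model import _profile_loglik


def design_60():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_design(60, 29, 50)


class TestBuildDesign:
    def test_interruption_month_coding(self):
        X = design_60().X
        assert X.loc[28, ["nims", "time_after_nims", "covid"]].tolist() == [0, 0, 0]
        assert X.loc[29, ["nims", "time_after_nims"]].tolist() == [1, 1]
        assert X.loc[49, "time_after_nims"] == 21 and X.loc[49, "covid"] == 0
        assert X.loc[50, ["covid", "time_after_covid"]].tolist() == [1, 1]
        assert X.loc[60, "time_after_nims"] == 32
        assert X.loc[60, "time_after_covid"] == 11

    def test_column_sums_closed_form(self):
        X = design_60().X
        assert X["nims"].sum() == 32
        assert X["covid"].sum() == 11
        assert X["time_after_nims"].sum() == 32 * 33 / 2
        assert X["time_after_covid"].sum() == 11 * 12 / 2

    def test_single_interruption_omits_covid_columns(self):
        d = build_design(60, 29)
        assert d.terms == ("intercept", "time", "nims", "time_after_nims")
        assert d.m2 is None

    @pytest.mark.parametrize("m1,m2", [(1, None), (0, None), (29, 29), (29, 20),
                                       (61, None)])
    def test_invalid_interruptions_rejected(self, m1, m2):
        with pytest.raises(ValueError):
            build_design(60, m1, m2)

    def test_short_segment_warns(self):
        with pytest.warns(UserWarning, match="12"):
            build_design(60, 29, 50)


class TestOLS:
    def test_zero_noise_exact_interpolation(self):
        d = design_60()
        betas = np.array([0.79, 0.004, 0.17, 0.027, 0.05, 0.03])
        y = d.X.to_numpy() @ betas
        fit = fit_ols(d, y)
        np.testing.assert_allclose(fit.params.to_numpy(), betas, atol=1e-12)

    def test_constant_series(self):
        d = design_60()
        fit = fit_ols(d, np.full(60, 7.0))
        assert fit.params["intercept"] == pytest.approx(7.0)
        np.testing.assert_allclose(fit.params.to_numpy()[1:], 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        d = design_60()
        rng = np.random.default_rng(11)
        X = d.X.to_numpy()
        for _ in range(5):
            y = rng.normal(size=60)
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            fit = fit_ols(d, y)
            np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle,
                                       rtol=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        d = design_60()
        y = np.random.default_rng(3).normal(2.0, 0.5, size=60)
        fit = fit_ols(d, y)
        ref = sm.OLS(y, d.X.to_numpy()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues, atol=1e-12)

    def test_rank_deficient_design_names_columns(self):
        d = design_60()
        X = d.X.copy()
        X["dup"] = X["time"]
        from opioid_its import DesignMatrix
        bad = DesignMatrix(X=X, m1=29, m2=50)
        with pytest.raises(FitError, match="collinear"):
            fit_ols(bad, np.zeros(60))

    def test_missing_months_dropped_with_warning(self):
        d = design_60()
        y = d.X.to_numpy() @ np.array([1, 0.01, 0.2, 0.01, 0.1, 0.01])
        y[10] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            fit = fit_ols(d, y)
        assert len(fit.residuals) == 59
        assert 11 not in fit.residuals.index   # calendar t retained


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        stat, _ = durbin_watson(np.full(10, 3.0))
        assert stat == 0.0

    def test_alternating_residuals_closed_form(self):
        n = 12
        e = np.array([1.0, -1.0] * (n // 2))
        stat, _ = durbin_watson(e)
        assert stat == pytest.approx(4 * (n - 1) / n)

    def test_white_noise_mean_near_two(self):
        rng = np.random.default_rng(0)
        stats_ = [durbin_watson(rng.standard_normal(100))[0] for _ in range(1000)]
        assert np.mean(stats_) == pytest.approx(2.0, abs=0.05)

    def test_all_zero_residuals_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            stat, p = durbin_watson(np.zeros(10))
        assert np.isnan(stat) and np.isnan(p)

    def test_bootstrap_agrees_with_normal_approximation(self):
        d = design_60()
        y = simulate_series(SyntheticConfig(noise_sd=0.3, ar1_rho=0.6, seed=4),
                            "high_dose").to_numpy()
        fit = fit_ols(d, y)
        e = fit.residuals.to_numpy()
        _, p_norm = durbin_watson(e, design=d)
        _, p_boot = durbin_watson(e, design=d, method="bootstrap", n_boot=4000,
                                  rng=np.random.default_rng(1))
        assert p_norm < 0.05 and p_boot < 0.05


class TestAR1ML:
    def test_zero_noise_recovers_betas(self):
        d = design_60()
        betas = np.array([1.0, 0.01, 0.3, 0.02, 0.1, -0.01])
        fit = fit_ar1_ml(d, d.X.to_numpy() @ betas)
        np.testing.assert_allclose(fit.params.to_numpy(), betas, atol=1e-6)

    def test_rho_zero_data_close_to_ols(self):
        d = design_60()
        agree = 0
        for s in range(20):
            y = simulate_series(SyntheticConfig(noise_sd=0.3, seed=s),
                                "high_dose").to_numpy()
            f_ols, f_ar = fit_ols(d, y), fit_ar1_ml(d, y)
            agree += np.all(np.abs(f_ar.params - f_ols.params) <= 2 * f_ols.bse)
            assert abs(f_ar.rho_hat) < 0.5
        assert agree >= 18

    def test_loglik_at_optimum_dominates_rho_zero(self):
        d = design_60()
        X = d.X.to_numpy()
        for s in range(10):
            y = simulate_series(SyntheticConfig(noise_sd=0.3, ar1_rho=0.4, seed=s),
                                "overlap").to_numpy()
            fit = fit_ar1_ml(d, y)
            assert fit.loglik >= _profile_loglik(0.0, X, y) - 1e-9

    def test_matches_arima_exact_ml(self):
        from statsmodels.tsa.arima.model import ARIMA

        d = design_60()
        y = simulate_series(SyntheticConfig(noise_sd=0.4, ar1_rho=0.5, seed=5),
                            "overlap").to_numpy()
        fit = fit_ar1_ml(d, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = ARIMA(y, exog=d.X.to_numpy(), order=(1, 0, 0), trend="n").fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params[:6], atol=0.02)
        assert fit.rho_hat == pytest.approx(ref.params[-2], abs=0.02)
        assert fit.loglik >= ref.llf - 1e-3   # at least as good an optimum


class TestFitITS:
    def test_strong_autocorrelation_selects_ar1(self):
        d = design_60()
        chosen = [fit_its(d, simulate_series(
            SyntheticConfig(noise_sd=0.3, ar1_rho=0.7, seed=s), "high_dose"
        ).to_numpy()).estimator for s in range(10)]
        assert chosen.count("AR1-ML") >= 9

    def test_independent_noise_mostly_selects_ols(self):
        d = design_60()
        chosen = [fit_its(d, simulate_series(
            SyntheticConfig(noise_sd=0.3, seed=s), "high_dose"
        ).to_numpy()).estimator for s in range(50)]
        assert chosen.count("OLS") >= 45

    def test_alpha_one_forces_ar1(self):
        d = design_60()
        y = simulate_series(SyntheticConfig(noise_sd=0.3, seed=1),
                            "high_dose").to_numpy()
        fit = fit_its(d, y, alpha=1.0)
        assert fit.estimator == "AR1-ML"
        assert np.isfinite(fit.dw)   # OLS Durbin-Watson carried over

    def test_estimator_override(self):
        d = design_60()
        y = simulate_series(SyntheticConfig(noise_sd=0.3, ar1_rho=0.7, seed=2),
                            "high_dose").to_numpy()
        assert fit_its(d, y, estimator="ols").estimator == "OLS"
        assert fit_its(d, y, estimator="ar1").estimator == "AR1-ML"


class TestDerived:
    @pytest.mark.parametrize("b1,b3,expected", [
        (0.0040, 0.0271, 0.0311), (0.0156, -0.0117, 0.0039), (0.5, 0.0, 0.5)])
    def test_post_interruption_slope(self, b1, b3, expected):
        coefs = {"time": b1, "time_after_nims": b3}
        assert post_slope(coefs) == pytest.approx(expected, abs=1e-12)

    def test_slope_after_second_needs_two_interruptions(self):
        with pytest.raises(ValueError):
            post_slope({"time": 0.1, "time_after_nims": 0.0}, "after_second")

    def test_counterfactual_differs_by_level_change_only(self):
        d = design_60()
        betas = np.array([2.0, 0.0, 0.5, 0.0, 0.0, 0.0])   # pure level change
        fit = fit_ols(d, d.X.to_numpy() @ betas)
        lines = predict_lines(fit)
        diff = lines["fitted"] - lines["counterfactual_pre"]
        np.testing.assert_allclose(diff[d.X.index < 29], 0.0, atol=1e-10)
        np.testing.assert_allclose(diff[d.X.index >= 29], 0.5, atol=1e-10)

    def test_flat_model_counterfactual_identical(self):
        d = design_60()
        fit = fit_ols(d, np.full(60, 3.0))
        lines = predict_lines(fit)
        np.testing.assert_allclose(lines["fitted"], 3.0, atol=1e-10)
        np.testing.assert_allclose(lines["counterfactual_pre"], 3.0, atol=1e-10)

    def test_zero_noise_predicted_equals_observed(self):
        d = design_60()
        y = d.X.to_numpy() @ np.array([1, 0.02, 0.3, 0.01, 0.2, -0.01])
        fit = fit_ols(d, y)
        np.testing.assert_allclose(predict_lines(fit)["fitted"].to_numpy(), y,
                                   atol=1e-10)


class TestResidualDiagnostics:
    def test_lag_zero_autocorrelation_is_one(self):
        d = design_60()
        fit = fit_ols(d, simulate_series(SyntheticConfig(noise_sd=0.3, seed=9),
                                         "naloxone").to_numpy())
        diag = residual_diagnostics(fit, max_lag=12)
        assert diag.loc[0, "acf"] == pytest.approx(1.0)
        assert diag.loc[0, "upper"] == pytest.approx(1.96 / np.sqrt(60))

    def test_ar1_series_shows_lag_one_autocorrelation(self):
        rng = np.random.default_rng(5)
        n = 2000
        e = np.empty(n)
        e[0] = rng.normal()
        for t in range(1, n):
            e[t] = 0.6 * e[t - 1] + rng.normal(0, np.sqrt(1 - 0.36))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = build_design(n, 29, 50)
        fit = fit_ols(d, e + 5.0)
        diag = residual_diagnostics(fit, max_lag=5)
        assert diag.loc[1, "acf"] == pytest.approx(0.6, abs=0.07)

    def test_white_noise_false_positive_rate(self):
        rng = np.random.default_rng(12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = build_design(1000, 400, 700)
        exceed = []
        for _ in range(30):
            fit = fit_ols(d, rng.standard_normal(1000))
            diag = residual_diagnostics(fit, max_lag=20).iloc[1:]
            exceed.append(float((diag["acf"].abs() > diag["upper"]).mean()))
        assert np.mean(exceed) <= 0.1
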