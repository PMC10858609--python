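"""Stage-1 estimators: design construction, OLS/PW/REML, fallback hierarchy."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

import itsmeta.itsfit as itsfit
from itsmeta import (
    build_design,
    fit_ols,
    fit_pw,
    fit_reml_ar1,
    fit_with_fallback,
    generate_series,
    lag1_autocorrelation,
)
from itsmeta.itsfit import reml_neg2_loglik
from itsmeta.types import SeriesParams, TimeSeriesStudy


def _series(T=60, ti=30, rho=0.0, sigma_w=1.0, beta=(10, 0.05, 1.0, 0.02), seed=0):
    return generate_series(
        SeriesParams(n_points=T, interruption_index=ti, beta0=beta[0], beta1=beta[1],
                     beta2=beta[2], beta3=beta[3], rho=rho, sigma_w=sigma_w, seed=seed)
    )


class TestDesign:
    def test_small_design_by_hand(self):
        s = TimeSeriesStudy("s", np.arange(1, 7), np.zeros(6), 4)
        x = build_design(s)
        np.testing.assert_array_equal(x[:, 2], [0, 0, 0, 1, 1, 1])
        np.testing.assert_array_equal(x[:, 3], [0, 0, 0, 0, 1, 2])
        # at t = T_I the level term is on but the interaction is zero
        assert x[3, 2] == 1 and x[3, 3] == 0

    @pytest.mark.parametrize("T,ti", [(6, 4), (20, 5), (50, 40), (195, 97)])
    def test_full_rank(self, T, ti):
        s = TimeSeriesStudy("s", np.arange(1, T + 1), np.zeros(T), ti)
        assert np.linalg.matrix_rank(build_design(s)) == 4


class TestLag1:
    def test_hand_computed_values(self):
        assert lag1_autocorrelation(np.array([1.0, 1, 1, 1])) == pytest.approx(3 / 4)
        assert lag1_autocorrelation(np.array([1.0, -1, 1, -1])) == pytest.approx(-3 / 4)

    def test_white_noise_limit(self):
        e = np.random.default_rng(0).normal(size=100_000)
        assert abs(lag1_autocorrelation(e)) < 0.01

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert lag1_autocorrelation(np.zeros(5)) == 0.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40))
    def test_bounded_by_one(self, e):
        e = np.asarray(e)
        if np.all(e == 0):
            return
        assert abs(lag1_autocorrelation(e)) <= 1.0 + 1e-12


class TestOLS:
    def test_noiseless_recovery_all_estimators(self):
        s = _series(T=30, ti=15, sigma_w=0.0)
        truth = [10, 0.05, 1.0, 0.02]
        for fitter in (fit_ols, fit_pw, fit_reml_ar1):
            fit = fitter(s)
            np.testing.assert_allclose(fit.beta_hat, truth, atol=1e-8)
        assert fit_ols(s).rmse_ols == pytest.approx(0.0, abs=1e-10)

    def test_matches_generic_least_squares(self):
        s = _series(T=40, ti=20, rho=0.3, seed=5)
        x = build_design(s)
        beta, *_ = np.linalg.lstsq(x, s.values, rcond=None)
        np.testing.assert_allclose(fit_ols(s).beta_hat, beta, atol=1e-10)

    def test_doubled_noise_doubles_ses(self):
        mean = _series(T=40, ti=20, sigma_w=0.0).values
        noise = np.random.default_rng(8).normal(size=40)
        t = np.arange(1, 41)
        s1 = TimeSeriesStudy("a", t, mean + noise, 20)
        s2 = TimeSeriesStudy("b", t, mean + 2 * noise, 20)
        np.testing.assert_allclose(2 * fit_ols(s1).se, fit_ols(s2).se, rtol=1e-10)
        assert fit_ols(s2).rmse_ols == pytest.approx(2 * fit_ols(s1).rmse_ols)


class TestPW:
    def test_reduces_to_ols_without_autocorrelation(self):
        s = _series(T=500, ti=250, rho=0.0, seed=2)
        pw, ols = fit_pw(s), fit_ols(s)
        assert abs(pw.rho_hat) < 0.1
        np.testing.assert_allclose(pw.beta_hat, ols.beta_hat, atol=0.05)
        np.testing.assert_allclose(pw.se, ols.se, rtol=0.1)

    def test_transform_whitens_residuals(self):
        """Transformed-model residuals are uncorrelated in expectation."""
        acs = []
        for seed in range(50):
            s = _series(T=200, ti=100, rho=0.6, seed=seed)
            fit = fit_pw(s)
            assert fit.converged
            x = build_design(s)
            xs, ys = itsfit._pw_transform(x, s.values, fit.rho_hat)
            acs.append(lag1_autocorrelation(ys - xs @ fit.beta_hat))
        assert abs(np.mean(acs)) < 0.02

    def test_tolerance_stability(self):
        s = _series(T=80, ti=40, rho=0.5, seed=4)
        r1 = fit_pw(s, tol=1e-6).rho_hat
        r2 = fit_pw(s, tol=1e-8).rho_hat
        assert abs(r1 - r2) < 1e-4


class TestREML:
    def test_close_to_ols_when_rho_zero(self):
        s = _series(T=400, ti=200, rho=0.0, seed=6)
        reml, ols = fit_reml_ar1(s), fit_ols(s)
        np.testing.assert_allclose(reml.beta_hat, ols.beta_hat, atol=0.05)
        assert abs(reml.rho_hat) < 0.1

    def test_grid_optimality(self):
        """The profiled restricted likelihood at rho_hat beats a 50-point grid."""
        s = _series(T=60, ti=30, rho=0.4, seed=7)
        fit = fit_reml_ar1(s)
        x = build_design(s)
        best = reml_neg2_loglik(fit.rho_hat, x, s.values)
        for r in np.linspace(-0.95, 0.95, 50):
            assert best <= reml_neg2_loglik(r, x, s.values) + 1e-6

    def test_rho_consistency(self):
        """Mean rho_hat over replicates is close to the generating value."""
        vals = [
            fit_reml_ar1(_series(T=500, ti=250, rho=0.4, seed=s)).rho_hat
            for s in range(300)
        ]
        assert abs(np.mean(vals) - 0.4) < 0.03

    def test_matches_r_gls_oracle(self, tmp_path):
        """Independent check against nlme::gls REML with AR(1) correlation."""
        s = _series(T=40, ti=20, rho=0.5, seed=9)
        x = build_design(s)
        import pandas as pd

        df = pd.DataFrame({"y": s.values, "t": x[:, 1], "d": x[:, 2], "td": x[:, 3]})
        csv = tmp_path / "series.csv"
        df.to_csv(csv, index=False)
        rscript = (
            "suppressMessages(library(nlme));"
            f"d <- read.csv('{csv}');"
            "m <- gls(y ~ t + d + td, data=d, correlation=corAR1(form=~t), method='REML');"
            "cat(coef(m), sqrt(diag(vcov(m))),"
            "coef(m$modelStruct$corStruct, unconstrained=FALSE), sep='\\n')"
        )
        try:
            out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                                 text=True, timeout=180, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"R oracle unavailable: {exc}")
        nums = [float(v) for v in out.stdout.split()]
        beta_r, se_r, rho_r = nums[:4], nums[4:8], nums[8]
        fit = fit_reml_ar1(s)
        np.testing.assert_allclose(fit.beta_hat, beta_r, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(fit.se, se_r, rtol=1e-3)
        assert fit.rho_hat == pytest.approx(rho_r, abs=1e-3)


class TestFallback:
    def test_well_behaved_series_uses_reml(self):
        fit = fit_with_fallback(_series(T=100, ti=50, rho=0.3, seed=10))
        assert fit.estimator_used == "REML"

    def test_forced_reml_failure_uses_pw(self, monkeypatch):
        def boom(study):
            raise RuntimeError("optimiser exploded")

        monkeypatch.setattr(itsfit, "fit_reml_ar1", boom)
        fit = itsfit.fit_with_fallback(_series(T=50, ti=25, rho=0.3, seed=11))
        assert fit.estimator_used == "PW"

    def test_forced_double_failure_uses_ols(self, monkeypatch):
        def boom(study):
            raise RuntimeError("no")

        monkeypatch.setattr(itsfit, "fit_reml_ar1", boom)
        monkeypatch.setattr(itsfit, "fit_pw", boom)
        fit = itsfit.fit_with_fallback(_series(T=50, ti=25, seed=12))
        assert fit.estimator_used == "OLS"
        assert fit.converged

    def test_fallback_accounting_sums_to_total(self, corpus_pipeline):
        """Every series in the chain arm resolves to exactly one estimator."""
        c = corpus_pipeline.convergence
        assert c["reml"] + c["pw"] + c["ols"] == c["n_series"]
        assert c["reml"] / c["n_series"] > 0.5  # REML is the dominant path

    @given(
        T=st.integers(8, 40),
        frac=st.floats(0.25, 0.75),
        rho=st.floats(-0.85, 0.85),
        seed=st.integers(0, 10_000),
    )
    def test_never_errors_on_valid_study(self, T, frac, rho, seed):
        ti = min(max(4, int(T * frac)), T - 2)
        s = _series(T=T, ti=ti, rho=rho, seed=seed)
        fit = fit_with_fallback(s)
        assert fit.estimator_used in ("REML", "PW", "OLS")
        assert np.all(np.isfinite(fit.beta_hat))


class TestEstimatorBehaviour:
    def test_unbiasedness_of_level_change(self):
        """All three estimators are unbiased for beta2 under the model."""
        reps = 300
        ests = {"OLS": [], "PW": [], "REML": []}
        for seed in range(reps):
            s = _series(T=100, ti=50, rho=0.2, seed=seed)
            ests["OLS"].append(fit_ols(s).level_change)
            ests["PW"].append(fit_pw(s).level_change)
            ests["REML"].append(fit_reml_ar1(s).level_change)
        for name, v in ests.items():
            v = np.asarray(v)
            mc_se = v.std(ddof=1) / np.sqrt(reps)
            assert abs(v.mean() - 1.0) < 3 * mc_se, name

    def test_ols_ses_smaller_under_positive_autocorrelation(self):
        ratios = []
        for seed in range(100):
            s = _series(T=50, ti=25, rho=0.6, seed=seed)
            ratios.append(fit_ols(s).se[2] / fit_reml_ar1(s).se[2])
        assert np.mean(ratios) < 1.0
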