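"""ML estimation: self-consistency, closed forms, cross-implementation checks."""

import numpy as np
import pandas as pd
import pytest

from errtsem.sem import (
    SEM,
    IdentificationError,
    SampleMoments,
    aic,
    fit_indices,
    fit_ml,
    implied_covariance,
)
from _oracle import BruteForceCFA, closed_form_one_factor_3, factanal_reference

ONE_FACTOR_5 = "F =~ x1 + x2 + x3 + x4 + x5"


class TestSelfConsistency:
    def test_fit_to_own_implied_covariance_recovers_parameters(self, one_factor_data):
        df, lam, theta = one_factor_data
        fit = fit_ml(ONE_FACTOR_5, df, robust=False)
        Sigma, names = implied_covariance(ONE_FACTOR_5, fit.theta)
        refit = fit_ml(ONE_FACTOR_5, SampleMoments(S=Sigma, N=500, var_names=names), robust=False)
        assert refit.chi2_ml == pytest.approx(0.0, abs=1e-7)
        for k, v in fit.theta.items():
            assert refit.theta[k] == pytest.approx(v, abs=1e-6)

    def test_just_identified_three_indicator_closed_form(self, one_factor_data):
        df, *_ = one_factor_data
        sub = df[["x1", "x2", "x3"]]
        fit = fit_ml("F =~ x1 + x2 + x3", sub, robust=False)
        lam_cf = closed_form_one_factor_3(np.cov(sub.to_numpy(), rowvar=False, ddof=1))
        assert fit.chi2_ml == pytest.approx(0.0, abs=1e-7)
        for i, name in enumerate(["F=~x1", "F=~x2", "F=~x3"]):
            assert fit.theta[name] == pytest.approx(lam_cf[i], abs=1e-6)

    def test_scale_equivariance(self, one_factor_data):
        df, *_ = one_factor_data
        fit = fit_ml(ONE_FACTOR_5, df, robust=False)
        scaled = df.copy()
        scaled["x1"] = 3.0 * scaled["x1"]
        fit2 = fit_ml(ONE_FACTOR_5, scaled, robust=False)
        assert fit2.chi2_ml == pytest.approx(fit.chi2_ml, rel=1e-5, abs=1e-6)
        assert fit2.df == fit.df
        assert fit2.rmsea == pytest.approx(fit.rmsea, abs=1e-6)
        assert fit2.cfi == pytest.approx(fit.cfi, abs=1e-6)
        assert fit2.theta["F=~x1"] == pytest.approx(3.0 * fit.theta["F=~x1"], rel=1e-4)
        assert fit2.theta["x1~~x1"] == pytest.approx(9.0 * fit.theta["x1~~x1"], rel=1e-4)

    def test_non_positive_definite_input_rejected(self):
        S = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml("F =~ a + b + c", SampleMoments(S=S, N=100, var_names=list("abc")))

    def test_unidentified_model_rejected(self, one_factor_data):
        df, *_ = one_factor_data
        with pytest.raises(IdentificationError):
            fit_ml("F =~ x1 + x2", df[["x1", "x2"]])


class TestReferenceAgreement:
    """Cross-implementation checks against R factanal and a brute-force fit."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_one_factor_agrees_with_factanal(self, seed):
        rng = np.random.default_rng(seed)
        lam = np.array([0.8, 0.7, 0.9, 0.6, 0.5])
        f = rng.normal(size=400)
        X = f[:, None] * lam + rng.normal(size=(400, 5)) * np.sqrt(1 - lam**2)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(1, 6)])
        ref = factanal_reference(df)
        if ref is None:
            pytest.skip("Rscript not available")
        ref_load, ref_uniq, ref_obj = ref
        R = np.corrcoef(X, rowvar=False)
        fit = fit_ml(
            ONE_FACTOR_5,
            SampleMoments(S=R, N=400, var_names=list(df.columns)),
            robust=False,
            gtol=1e-10,
        )
        sign = np.sign(fit.theta["F=~x1"]) * np.sign(ref_load[0])
        for i in range(5):
            assert fit.theta[f"F=~x{i + 1}"] * sign == pytest.approx(ref_load[i], abs=1e-4)
            assert fit.theta[f"x{i + 1}~~x{i + 1}"] == pytest.approx(ref_uniq[i], abs=1e-4)
        assert fit.chi2_ml / (400 - 1) == pytest.approx(ref_obj, rel=1e-3, abs=1e-6)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_two_factor_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        lam1 = np.array([0.8, 0.7, 0.6, 0.0, 0.0, 0.0])
        lam2 = np.array([0.0, 0.0, 0.0, 0.9, 0.7, 0.5])
        f = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=500)
        X = f[:, :1] * lam1 + f[:, 1:] * lam2
        X += rng.normal(size=(500, 6)) * np.sqrt(1 - (lam1**2 + lam2**2))
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(1, 7)])
        fit = fit_ml("F1 =~ x1 + x2 + x3\nF2 =~ x4 + x5 + x6", df, robust=False, gtol=1e-9)

        S = np.cov(X, rowvar=False, ddof=1)
        oracle = BruteForceCFA(
            pattern={(0, 0): True, (1, 0): True, (2, 0): True, (3, 1): True, (4, 1): True, (5, 1): True},
            p=6, m=2,
        )
        res = oracle.fit(S)
        assert fit.chi2_ml / 499 == pytest.approx(res.fun, rel=1e-2, abs=1e-8)
        lam_hat = np.array([fit.theta[f"F1=~x{i}"] for i in (1, 2, 3)]
                           + [fit.theta[f"F2=~x{i}"] for i in (4, 5, 6)])
        assert np.abs(np.abs(lam_hat) - np.abs(res.x[:6])).max() < 1e-4
        assert fit.theta["F1~~F2"] == pytest.approx(res.x[6], abs=1e-4)


class TestFitIndicesAndAic:
    def test_rmsea_clamped_at_zero(self):
        rmsea, _ = fit_indices(5.0, 10, 249, 300.0, 28)
        assert rmsea == 0.0

    def test_saturated_model_warns(self):
        with pytest.warns(UserWarning, match="saturated"):
            rmsea, _ = fit_indices(0.0, 0, 249, 300.0, 28)
        assert rmsea == 0.0

    def test_aic_formula(self, one_factor_data):
        df, *_ = one_factor_data
        fit = fit_ml(ONE_FACTOR_5, df, robust=False)
        assert aic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.n_free)

    def test_aic_raises_on_dnc(self, one_factor_data):
        df, *_ = one_factor_data
        fit = fit_ml(ONE_FACTOR_5, df, robust=False, max_iter=1)
        if fit.converged == "dnc":
            with pytest.raises(RuntimeError):
                aic(fit)
            with pytest.raises(RuntimeError):
                _ = fit.theta

    def test_aic_prefers_true_model_at_large_n(self):
        rng = np.random.default_rng(5)
        lam1 = np.array([0.8, 0.7, 0.6, 0, 0, 0])
        lam2 = np.array([0, 0, 0, 0.9, 0.7, 0.5])
        f = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=3000)
        X = f[:, :1] * lam1 + f[:, 1:] * lam2
        X += rng.normal(size=(3000, 6)) * np.sqrt(1 - (lam1**2 + lam2**2))
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(1, 7)])
        true = fit_ml("F1 =~ x1 + x2 + x3\nF2 =~ x4 + x5 + x6", df, robust=False)
        restricted = fit_ml("F =~ x1 + x2 + x3 + x4 + x5 + x6", df, robust=False)
        assert aic(true) < aic(restricted)


class TestEstimatorInterface:
    def test_sklearn_style_params_and_fitted_attributes(self, one_factor_data):
        df, *_ = one_factor_data
        est = SEM(ONE_FACTOR_5, robust=False)
        assert est.get_params()["identification"] == "unit_variance"
        est.set_params(gtol=1e-7)
        est.fit(df)
        assert hasattr(est, "result_")
        assert est.df_ == 5
        assert est.chi2_ml_ >= 0
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)
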