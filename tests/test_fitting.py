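"""Estimation machinery against brute-force and statsmodels oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from saltreg.dataset import Dataset, DesignMatrix, PhenotypeRecord, Term, build_design
from saltreg.fitting import (
    FitError,
    LeverageError,
    adequacy_anova,
    error_nullity_test,
    fit_design,
    hc3_covariance,
    performance_measures,
    predicted_residuals,
    fit_design as fit,
)

from conftest import random_design


def loo_prediction_errors(design: DesignMatrix) -> np.ndarray:
    """Literal leave-one-out refits: the independent PRESS oracle."""
    X, y = design.values, design.response
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        out[i] = y[i] - X[i] @ beta
    return out


def hc3_brute_force(design: DesignMatrix, resid: np.ndarray, hat: np.ndarray) -> np.ndarray:
    X = design.values
    xtx_inv = np.linalg.inv(X.T @ X)
    omega = np.diag(resid**2 / (1 - hat) ** 2)
    return xtx_inv @ X.T @ omega @ X @ xtx_inv


class TestFitSvd:
    def test_exact_fit_has_zero_residuals(self, rng):
        D = random_design(rng, 12, 3)
        D.response = D.values @ np.array([1.0, -2.0, 0.5])
        res = fit(D)
        assert np.max(np.abs(res.resid)) < 1e-10
        assert res.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_three_collinear_points_give_unit_slope(self):
        D = DesignMatrix(
            np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]),
            [Term("intercept"), Term("linear", (1,))],
            np.array([0.0, 1.0, 2.0]),
        )
        np.testing.assert_allclose(fit(D).slopes, [0.0, 1.0], atol=1e-12)

    def test_duplicated_column_yields_finite_minimum_norm_solution(self, rng):
        D = random_design(rng, 10, 3)
        D.values[:, 2] = D.values[:, 1]
        res = fit(D)
        assert np.all(np.isfinite(res.slopes))
        assert res.rank == 2
        # minimum-norm splits the shared coefficient equally
        assert res.slopes[1] == pytest.approx(res.slopes[2])

    def test_empty_and_all_zero_designs_rejected(self):
        terms = [Term("linear", (1,))]
        with pytest.raises(FitError):
            fit(DesignMatrix(np.empty((0, 1)), terms, np.empty(0)))
        with pytest.raises(FitError):
            fit(DesignMatrix(np.zeros((4, 1)), terms, np.ones(4)))

    def test_agrees_with_normal_equations_when_well_conditioned(self, rng):
        D = random_design(rng, 40, 5)
        res = fit(D)
        X, y = D.values, D.response
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.slopes, beta_ne, rtol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_leverages_bounded_and_sum_to_rank(self, seed):
        rng = np.random.default_rng(seed)
        D = random_design(rng, 15, 4)
        if seed == 2:
            D.values[:, 3] = D.values[:, 0] + D.values[:, 1]  # rank deficient
        res = fit(D)
        assert np.all(res.hat >= 0) and np.all(res.hat <= 1)
        assert np.sum(res.hat) == pytest.approx(res.rank, abs=1e-8)


class TestPredictedResiduals:
    @pytest.mark.parametrize("n,p", [(6, 2), (12, 4), (30, 6)])
    def test_press_identity_matches_literal_refits(self, n, p):
        rng = np.random.default_rng(n * 100 + p)
        D = random_design(rng, n, p)
        res = fit(D)
        np.testing.assert_allclose(predicted_residuals(res), loo_prediction_errors(D), atol=1e-8)

    def test_zero_residual_fit_has_zero_predicted_residuals(self, rng):
        D = random_design(rng, 10, 2)
        D.response = D.values @ np.array([2.0, 3.0])
        assert np.max(np.abs(predicted_residuals(fit(D)))) < 1e-8

    def test_unit_leverage_raises_naming_record(self, rng):
        # n == p makes every leverage 1
        D = random_design(rng, 3, 3)
        with pytest.raises(LeverageError):
            predicted_residuals(fit(D))


class TestHc3:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        D = random_design(rng, 8, 2)
        res = fit(D)
        np.testing.assert_allclose(
            hc3_covariance(res), hc3_brute_force(D, res.resid, res.hat), rtol=1e-8
        )

    def test_matches_statsmodels_cov_hc3(self, rng):
        D = random_design(rng, 25, 4)
        res = fit(D)
        ols = sm.OLS(D.response, D.values).fit()
        np.testing.assert_allclose(hc3_covariance(res), ols.cov_HC3, rtol=1e-8)

    def test_zero_residuals_give_zero_matrix(self, rng):
        D = random_design(rng, 10, 2)
        D.response = D.values @ np.array([1.0, 1.0])
        assert np.max(np.abs(hc3_covariance(fit(D)))) < 1e-16

    def test_symmetric_psd(self, rng):
        D = random_design(rng, 20, 5)
        S = hc3_covariance(fit(D))
        np.testing.assert_allclose(S, S.T, rtol=1e-12)
        assert np.linalg.eigvalsh(S).min() >= -1e-10 * np.trace(S)

    def test_homoskedastic_large_n_approaches_classical_covariance(self):
        rng = np.random.default_rng(11)
        n = 5000
        X = rng.standard_normal((n, 2))
        sigma = 0.7
        y = X @ np.array([1.0, -1.0]) + rng.normal(0, sigma, n)
        D = DesignMatrix(X, [Term("linear", (1,)), Term("linear", (2,))], y)
        S = hc3_covariance(fit(D))
        classical = sigma**2 * np.linalg.inv(X.T @ X)
        np.testing.assert_allclose(np.diag(S), np.diag(classical), rtol=0.10)


class TestMeasures:
    def test_perfect_fit(self, rng):
        D = random_design(rng, 10, 2)
        D.response = D.values @ np.array([1.0, 2.0])
        m = performance_measures(fit(D))
        assert m.rmse_ho == pytest.approx(0.0, abs=1e-8)
        assert m.mae_ho == pytest.approx(0.0, abs=1e-8)
        assert m.r2_ho == pytest.approx(1.0)

    def test_intercept_only_model_has_zero_adjusted_r2(self, rng):
        y = rng.standard_normal(15) + 3.0
        D = DesignMatrix(np.ones((15, 1)), [Term("intercept")], y)
        m = performance_measures(fit(D), tss="centered")
        assert m.r2_adj == pytest.approx(0.0, abs=1e-12)

    def test_holdout_residuals_inflate_ordinary_ones(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            D = random_design(rng, 20, 4)
            res = fit(D)
            m = performance_measures(res)
            rmse_ordinary = np.sqrt(np.mean(res.resid**2))
            assert m.rmse_ho >= rmse_ordinary
            assert m.rmse_ho >= m.mae_ho >= 0.0

    def test_constant_response_with_centered_tss_is_undefined(self):
        D = DesignMatrix(np.ones((8, 1)), [Term("intercept")], np.full(8, 2.0))
        with pytest.raises(FitError):
            performance_measures(fit(D), tss="centered")


class TestAdequacyAndNullity:
    def test_strong_signal_is_decisively_adequate(self, default_synthetic):
        data, _ = default_synthetic
        from conftest import EQ2_TERMS

        res = fit(build_design(data, EQ2_TERMS))
        assert adequacy_anova(res) < 1e-10

    def test_zero_residual_fit_gives_p_zero(self, rng):
        D = random_design(rng, 10, 2)
        D.response = D.values @ np.array([1.0, 1.0])
        assert adequacy_anova(fit(D)) < 1e-50  # numerically zero

    def test_type_one_error_of_overall_f(self):
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            D = random_design(rng, 40, 3)
            if adequacy_anova(fit(D)) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def _fit_with_pred_resid(self, e_tilde):
        rng = np.random.default_rng(0)
        D = random_design(rng, len(e_tilde), 2)
        res = fit(D)
        res._pred_resid = np.asarray(e_tilde, dtype=float)
        return res

    def test_antisymmetric_predicted_residuals_give_p_one(self):
        res = self._fit_with_pred_resid([-0.3, 0.3, -1.1, 1.1, -0.2, 0.2])
        assert error_nullity_test(res) == pytest.approx(1.0)

    def test_constant_offset_gives_p_near_zero(self):
        res = self._fit_with_pred_resid(np.ones(10))
        assert error_nullity_test(res) == pytest.approx(0.0)

    def test_nullity_type_one_error(self):
        rejections = 0
        n_rep = 1000
        master = np.random.default_rng(77)
        for _ in range(n_rep):
            res = self._fit_with_pred_resid(master.standard_normal(30))
            if error_nullity_test(res) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07
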