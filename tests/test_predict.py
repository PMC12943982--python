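"""Prediction engine: means, variances, intervals, grids, optima,
and internal consistency of the bundled reference model."""

import numpy as np
import pytest
from scipy import stats

from saltreg.dataset import Term
from saltreg.predict import (
    FinalModel,
    ScenarioSpec,
    confidence_interval,
    figure_spec,
    parabola_optimum,
    predict_mean,
    predict_variance,
    published_model,
    published_model_dict,
    scenario_grid,
)


@pytest.fixture(scope="module")
def model():
    return published_model()


class TestMean:
    def test_zero_point_predicts_zero(self, model):
        assert predict_mean(model, 0, 0, 0) == 0.0

    def test_reference_point_matches_hand_arithmetic(self, model):
        # direct arithmetic on the model's printed coefficients
        assert predict_mean(model, 30, 50, 200) == pytest.approx(2.09313, abs=1e-9)

    def test_mean_invariant_to_spad_sign(self, model):
        assert predict_mean(model, 25, 40, 150) == pytest.approx(
            predict_mean(model, -25, 40, 150)
        )

    def test_additive_decomposition_without_cross_terms(self, model, rng):
        for _ in range(20):
            s, g, k = rng.uniform(10, 50), rng.uniform(10, 90), rng.uniform(10, 300)
            total = predict_mean(model, s, g, k)
            parts = (
                predict_mean(model, s, 0, 0)
                + predict_mean(model, 0, g, 0)
                + predict_mean(model, 0, 0, k)
            )
            assert total == pytest.approx(parts, rel=1e-12)


class TestVarianceAndIntervals:
    def test_zero_vector_gives_zero_variance_and_degenerate_interval(self, model):
        x = np.zeros(5)
        assert predict_variance(model, x) == 0.0
        assert confidence_interval(model, x, 0.5) == (0.0, 0.0)

    def test_quadratic_form_matches_loop_oracle(self, model, rng):
        for _ in range(10):
            x = rng.uniform(-1, 1, 5) * np.array([90, 300, 2500, 8100, 90000])
            expected = sum(
                x[i] * model.cov[i, j] * x[j] for i in range(5) for j in range(5)
            )
            assert predict_variance(model, x) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            predict_variance(model, np.ones(4))

    def test_halfwidth_uses_t_quantile_with_119_dof(self, model):
        assert model.dof == 119
        x = model.observation_vector(30, 50, 200)
        lo, hi = confidence_interval(model, x, 0.50)
        halfwidth = (hi - lo) / 2
        # frozen from a t-table: t_{0.75, 119}
        assert halfwidth == pytest.approx(0.6766 * np.sqrt(predict_variance(model, x)), rel=1e-4)

    def test_interval_collapses_as_level_shrinks(self, model):
        x = model.observation_vector(30, 50, 200)
        lo, hi = confidence_interval(model, x, 1e-9)
        assert hi - lo < 1e-7

    def test_prediction_interval_is_wider(self, model):
        x = model.observation_vector(30, 50, 200)
        ci = confidence_interval(model, x, 0.5)
        pi = confidence_interval(model, x, 0.5, prediction=True)
        assert pi[0] < ci[0] < ci[1] < pi[1]


class TestGrids:
    @pytest.mark.parametrize("fig,n_sweep", [(1, 41), (2, 59), (3, 41), (4, 41), (5, 59)])
    def test_figure_grids_have_documented_sweep_counts(self, model, fig, n_sweep):
        spec = figure_spec(fig)
        table = scenario_grid(model, spec)
        assert spec.sweep_values().size == n_sweep
        assert len(table) == n_sweep * 15  # 3 x 5 fixed-level combinations
        assert np.all(table["ci_lo"] <= table["mean_sdw_g"] + 1e-12)
        assert np.all(table["mean_sdw_g"] <= table["ci_hi"] + 1e-12)

    def test_mean_is_unimodal_in_k_around_optimum(self, model):
        spec = figure_spec(5)
        table = scenario_grid(model, spec)
        k_opt = parabola_optimum(model, "k")
        one_curve = table[(table["gs"] == 30) & (table["spad"] == 30)]
        below = one_curve[one_curve["sweep_value"] <= k_opt - 5]["mean_sdw_g"].to_numpy()
        above = one_curve[one_curve["sweep_value"] >= k_opt + 5]["mean_sdw_g"].to_numpy()
        assert np.all(np.diff(below) > 0)
        assert np.all(np.diff(above) < 0)

    def test_empty_or_invalid_sweep_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("gs", 50, 10, 2, {"spad": [30], "k": [100]})
        with pytest.raises(ValueError):
            ScenarioSpec("gs", 10, 50, 2, {"spad": [30]})  # missing fixed var


class TestOptima:
    def test_reference_optima(self, model):
        assert parabola_optimum(model, "gs") == pytest.approx(46.155, abs=0.01)
        assert parabola_optimum(model, "k") == pytest.approx(209.538, abs=0.01)

    def test_toy_parabola(self):
        toy = FinalModel(
            terms=[Term.parse("X2"), Term.parse("X2^2")],
            slopes=np.array([1.0, -1.0]),
            cov=np.eye(2) * 1e-6,
            resid_sd=0.1,
            dof=10,
        )
        assert parabola_optimum(toy, "gs") == pytest.approx(0.5)

    def test_no_interior_maximum_rejected(self, model):
        convex = FinalModel(
            terms=[Term.parse("X2"), Term.parse("X2^2")],
            slopes=np.array([1.0, 2.0]),
            cov=np.eye(2) * 1e-6,
            resid_sd=0.1,
            dof=10,
        )
        with pytest.raises(ValueError):
            parabola_optimum(convex, "gs")


class TestReferenceModelConsistency:
    def test_sd_line_is_sqrt_of_covariance_diagonal_at_3_sig_figs(self):
        obj = published_model_dict()
        sds = np.sqrt(np.diag(np.asarray(obj["cov"])))
        for computed, reported in zip(sds, obj["reported_slope_sds"]):
            assert computed == pytest.approx(reported, rel=5e-3)

    def test_correlations_reproduce_reported_lower_triangle(self):
        obj = published_model_dict()
        S = np.asarray(obj["cov"])
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        for key, reported in obj["reported_correlations"].items():
            i, j = (int(v) - 1 for v in key.strip("()").split(","))
            decimals = len(str(reported).split(".")[1])
            assert abs(R[i, j] - reported) <= 1.5 * 10.0 ** (-decimals)

    def test_save_load_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        back = FinalModel.load(path)
        np.testing.assert_array_equal(back.slopes, model.slopes)
        np.testing.assert_array_equal(back.cov, model.cov)
        assert back.terms == model.terms and back.dof == model.dof

    def test_malformed_model_json_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"terms": ["X2"], "slopes": [1.0]}')
        with pytest.raises(ValueError, match="malformed"):
            FinalModel.load(path)
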