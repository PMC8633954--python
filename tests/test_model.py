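import numpy as np
import pandas as pd
import pytest

from pkmetab import model
from pkmetab.model import ModelSpec

from oracles import (
    cd_elastic_net,
    explained_variance_formula,
    histogram_brute,
    mape_formula,
    rmse_formula,
)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(30, 5))
    beta = np.array([4.0, -3.0, 2.0, 0.0, 0.0])
    y = 10.0 + X @ beta + rng.normal(0, 0.1, 30)
    return X, y


class TestFitPenalized:
    def test_full_shrinkage_limit(self, linear_problem):
        X, y = linear_problem
        fit = model.fit_penalized(X, y, ModelSpec(penalty_strength=1e6))
        assert np.all(fit.coefficients == 0)
        assert fit.intercept == pytest.approx(y.mean())
        assert fit.nonzero_feature_ids == []

    def test_zero_penalty_equals_ols(self, linear_problem):
        X, y = linear_problem
        fit = model.fit_penalized(X, y, ModelSpec(penalty_strength=0.0))
        design = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        np.testing.assert_allclose(fit.coefficients, beta[1:], rtol=1e-8)

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2, 1.0])
    def test_lasso_matches_coordinate_descent_oracle(self, alpha):
        """5 samples x 3 features, pure L1: solver vs brute-force CD, 1e-6."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        spec = ModelSpec(penalty_strength=alpha, l1_fraction=1.0,
                         convergence_tolerance=1e-10)
        fit = model.fit_penalized(X, y, spec)
        b0, beta = cd_elastic_net(X, y, alpha, 1.0)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-6)

    def test_mixed_penalty_matches_oracle(self):
        rng = np.random.default_rng(43)
        X = rng.normal(size=(8, 4))
        y = X @ np.array([2.0, 0.0, -1.0, 0.5]) + rng.normal(0, 0.2, 8)
        spec = ModelSpec(penalty_strength=0.1, l1_fraction=0.5,
                         convergence_tolerance=1e-10)
        fit = model.fit_penalized(X, y, spec)
        b0, beta = cd_elastic_net(X, y, 0.1, 0.5)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-6)

    def test_ranking_is_by_abs_coefficient(self, linear_problem):
        X, y = linear_problem
        fit = model.fit_penalized(pd.DataFrame(X), y, ModelSpec(penalty_strength=0.05))
        mags = np.abs(fit.coefficients)
        ranked_mags = [mags[fit.feature_ids.index(f)] for f in fit.nonzero_feature_ids]
        assert ranked_mags == sorted(ranked_mags, reverse=True)
        assert set(fit.nonzero_feature_ids) == {
            fit.feature_ids[i] for i in np.flatnonzero(fit.coefficients)
        }

    def test_nonconvergence_is_an_error(self):
        rng = np.random.default_rng(44)
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        spec = ModelSpec(penalty_strength=1e-8, l1_fraction=0.9,
                         max_iterations=2, convergence_tolerance=1e-14)
        with pytest.raises(model.ConvergenceError):
            model.fit_penalized(X, y, spec)

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]])
        with pytest.raises(ValueError):
            model.fit_penalized(X, [1.0, 2.0, 3.0])


class TestLoocv:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        preds = model.loocv_predict(X, np.full(6, 7.0), ModelSpec(penalty_strength=1.0))
        np.testing.assert_allclose(preds, 7.0)

    def test_held_out_prediction_ignores_own_target(self, linear_problem):
        X, y = linear_problem
        spec = ModelSpec(penalty_strength=0.1)
        base = model.loocv_predict(X, y, spec)
        y_perturbed = y.copy()
        y_perturbed[4] += 1000.0
        perturbed = model.loocv_predict(X, y_perturbed, spec)
        assert perturbed[4] == pytest.approx(base[4], rel=1e-10)
        assert not np.allclose(perturbed[:4], base[:4])  # others do move

    def test_exact_signal_has_near_perfect_cv(self, linear_problem):
        X, y = linear_problem
        preds = model.loocv_predict(X, y, ModelSpec(penalty_strength=1e-4))
        assert model.explained_variance(y, preds) > 0.99

    def test_returns_one_prediction_per_sample(self, linear_problem):
        X, y = linear_problem
        assert model.loocv_predict(X, y).shape == (len(y),)


class TestMetrics:
    def test_two_point_hand_examples(self):
        assert model.mape([10, 20], [11, 18]) == pytest.approx(10.0)
        assert model.rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))
        assert model.rmse([3, 4], [0, 0]) == pytest.approx(3.5355, abs=5e-5)

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert model.explained_variance(y, y) == 1.0
        assert model.mape(y, y) == 0.0
        assert model.rmse(y, y) == 0.0

    def test_variance_form_ignores_constant_offset(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        assert model.explained_variance(y, y + 5.0) == pytest.approx(1.0)

    def test_random_pairs_match_formula_oracles(self):
        rng = np.random.default_rng(23)
        y = rng.uniform(1, 100, 25)
        yhat = y * rng.uniform(0.8, 1.2, 25)
        assert model.explained_variance(y, yhat) == pytest.approx(
            explained_variance_formula(y, yhat), rel=1e-12)
        assert model.mape(y, yhat) == pytest.approx(mape_formula(y, yhat), rel=1e-12)
        assert model.rmse(y, yhat) == pytest.approx(rmse_formula(y, yhat), rel=1e-12)

    def test_permutation_and_scaling_behaviour(self):
        rng = np.random.default_rng(24)
        y = rng.uniform(1, 50, 15)
        yhat = y + rng.normal(0, 2, 15)
        perm = rng.permutation(15)
        assert model.rmse(y[perm], yhat[perm]) == pytest.approx(model.rmse(y, yhat))
        assert model.mape(y[perm], yhat[perm]) == pytest.approx(model.mape(y, yhat))
        # affine rescale applied to both leaves explained variance unchanged
        assert model.explained_variance(3 * y + 7, 3 * yhat + 7) == pytest.approx(
            model.explained_variance(y, yhat))
        assert model.rmse(3 * y, 3 * yhat) == pytest.approx(3 * model.rmse(y, yhat))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            model.explained_variance([2.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            model.mape([0.0, 1.0], [1.0, 1.0])


class TestRefinement:
    def test_single_perfect_feature_among_noise(self):
        rng = np.random.default_rng(55)
        signal = rng.normal(size=40)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=[f"f{j}" for j in range(10)])
        X["f0"] = signal
        y = 5.0 + 2.0 * signal
        trace = model.refine_by_coefficient_rank(X, y, ModelSpec(penalty_strength=0.05))
        assert trace.ranked_feature_ids[0] == "f0"
        assert trace.chosen_k == 1
        assert trace.chosen_feature_ids == ["f0"]

    def test_trace_has_one_record_per_nonzero(self, linear_problem):
        X, y = linear_problem
        spec = ModelSpec(penalty_strength=0.05)
        trace = model.refine_by_coefficient_rank(X, y, spec)
        K = len(model.fit_penalized(X, y, spec).nonzero_feature_ids)
        assert list(trace.records["k"]) == list(range(1, K + 1))

    def test_all_zero_initial_fit_suggests_smaller_penalty(self, linear_problem):
        X, y = linear_problem
        with pytest.raises(ValueError, match="smaller"):
            model.refine_by_coefficient_rank(X, y, ModelSpec(penalty_strength=1e6))

    def test_planted_subset_recovered_from_many_features(self):
        """10 informative features among 500: the chosen subset finds
        at least 7 and the LOOCV explained variance is high."""
        rng = np.random.default_rng(77)
        n, p, k = 40, 500, 10
        z = rng.normal(size=n)
        X = rng.normal(size=(n, p))
        planted = [f"f{j}" for j in range(0, p, p // k)][:k]
        cols = [f"f{j}" for j in range(p)]
        Xdf = pd.DataFrame(X, columns=cols)
        for i, f in enumerate(planted):
            Xdf[f] = (1 if i % 2 == 0 else -1) * z + rng.normal(0, 0.2, n)
        y = 100.0 + 30.0 * z
        spec = model.tune_alpha(Xdf, y)
        trace = model.refine_by_coefficient_rank(Xdf, y, spec)
        assert len(set(trace.chosen_feature_ids) & set(planted)) >= 7
        best = trace.records["loocv_explained_variance"].max()
        assert best > 0.8


class TestGridSearch:
    def test_single_point_grid_returns_it(self, linear_problem):
        X, y = linear_problem
        best, n_eval, _ = model.grid_tune(
            X, y, {"penalty_strength": [0.1], "l1_fraction": [0.7]}
        )
        assert n_eval == 1
        assert best.penalty_strength == 0.1
        assert best.l1_fraction == 0.7

    def test_product_count(self, linear_problem):
        X, y = linear_problem
        grid = {"penalty_strength": [0.01, 0.1, 1.0], "l1_fraction": [0.2, 0.8]}
        _, n_eval, results = model.grid_tune(X, y, grid)
        assert n_eval == 6
        assert len(results) == 6

    def test_best_member_dominates_grid(self, linear_problem):
        X, y = linear_problem
        grid = {"penalty_strength": [0.01, 0.5, 5.0], "l1_fraction": [0.3, 1.0]}
        best, _, results = model.grid_tune(X, y, grid)
        best_score = model.explained_variance(y, model.loocv_predict(X, y, best))
        assert best_score >= results["loocv_explained_variance"].max() - 1e-12

    def test_default_grid_cartesian_size(self):
        assert model.grid_size(model.default_grid()) == 4800

    def test_empty_grid_rejected(self, linear_problem):
        X, y = linear_problem
        with pytest.raises(ValueError):
            model.grid_tune(X, y, {})


class TestDiagnosticsAndBlocks:
    def test_zero_residuals_define_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        diag = model.residual_diagnostics(y, y)
        assert diag["ols_r_squared"] == 0.0
        np.testing.assert_allclose(diag["residuals"], 0.0)

    def test_linear_residuals_have_r2_one(self):
        yhat = np.array([1.0, 2.0, 3.0, 4.0])
        y = yhat + (2.0 * yhat - 1.0)  # residual exactly linear in yhat
        diag = model.residual_diagnostics(y, yhat)
        assert diag["ols_r_squared"] == pytest.approx(1.0)
        assert diag["ols_slope"] == pytest.approx(2.0)

    def test_histogram_matches_brute_binning(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=40)
        yhat = y + rng.normal(0, 0.5, 40)
        diag = model.residual_diagnostics(y, yhat, bins=7)
        brute = histogram_brute(y - yhat, diag["histogram_edges"])
        assert list(diag["histogram_counts"]) == brute

    def test_probability_plot_pairs(self):
        rng = np.random.default_rng(32)
        y = rng.normal(size=9)
        diag = model.residual_diagnostics(y, np.zeros(9))
        pairs = diag["probability_plot"]
        assert pairs.shape == (9, 1 + 1)
        np.testing.assert_allclose(pairs[:, 1], np.sort(y))
        from scipy import stats
        np.testing.assert_allclose(
            pairs[:, 0], stats.norm.ppf((np.arange(1, 10) - 0.5) / 9))

    def test_block_concatenation_widths_and_identity(self):
        idx = ["a", "b", "c"]
        m = pd.DataFrame(np.ones((3, 5)), index=idx,
                         columns=[f"m{j}" for j in range(5)])
        c = pd.DataFrame(np.zeros((3, 3)), index=idx,
                         columns=[f"c{j}" for j in range(3)])
        X, prov = model.combine_blocks(m, c)
        assert X.shape == (3, 8)
        assert (prov == "metabolomic").sum() == 5
        assert (prov == "clinical").sum() == 3
        X2, _ = model.combine_blocks(m, c.iloc[:, :0])
        pd.testing.assert_frame_equal(X2, m)

    def test_block_provenance_round_trip(self):
        rng = np.random.default_rng(33)
        idx = [f"s{i}" for i in range(4)]
        m = pd.DataFrame(rng.normal(size=(4, 6)), index=idx,
                         columns=[f"m{j}" for j in range(6)])
        c = pd.DataFrame(rng.normal(size=(4, 2)), index=idx,
                         columns=["age", "weight"])
        X, prov = model.combine_blocks(m, c)
        pd.testing.assert_frame_equal(X.loc[:, prov == "metabolomic"], m)
        pd.testing.assert_frame_equal(X.loc[:, prov == "clinical"], c)

    def test_sample_mismatch_lists_offenders(self):
        m = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["m0", "m1"])
        c = pd.DataFrame(np.ones((2, 2)), index=["a", "z"], columns=["c0", "c1"])
        with pytest.raises(ValueError, match="z"):
            model.combine_blocks(m, c)


class TestEvaluationModes:
    def test_nested_mode_is_more_conservative_on_noise(self):
        """Pure-noise target: full-data selection then LOOCV looks better
        than honest nested selection."""
        rng = np.random.default_rng(91)
        X = pd.DataFrame(rng.normal(size=(20, 40)),
                         columns=[f"f{j}" for j in range(40)])
        y = rng.normal(size=20)
        spec = ModelSpec(penalty_strength=0.1 * model._alpha_max(X, y, 0.5))
        unnested = model.run_prediction_pipeline(X, y, spec, mode="replicate-paper",
                                              max_k=8)
        nested = model.run_prediction_pipeline(X, y, spec, mode="nested", max_k=8)
        assert (unnested.loocv_metrics.explained_variance
                >= nested.loocv_metrics.explained_variance)
        assert nested.loocv_metrics.explained_variance < 0.5

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            model.run_prediction_pipeline(np.ones((5, 2)), np.arange(5.0),
                                          mode="bogus")
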