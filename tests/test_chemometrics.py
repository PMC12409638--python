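"""Linear and PLS regression, VIP selection, error metrics."""

import numpy as np
import pytest

from ramanpat.chemometrics import (cv_select_components, fit_linear, metrics,
                                   model_from_json, model_to_json,
                                   nipals_pls_fit, predict,
                                   select_vip_intervals, vip_scores, VIPResult)
from ramanpat.preprocess import get_config

from conftest import make_set


class TestFitLinear:
    def test_two_points_give_exact_line(self):
        trainset = make_set([[0.0, 5.0], [1.0, 5.0]], reference=[0.0, 1.1])
        model = fit_linear(trainset, 200.0)  # first axis point
        assert model.slope == pytest.approx(1.1)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_intensities_rejected(self):
        trainset = make_set([[2.0, 1.0], [2.0, 3.0]], reference=[0.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            fit_linear(trainset, 200.0)

    def test_prediction_on_training_set_is_fit(self, rng):
        x = rng.uniform(0, 10, size=8)
        c = 0.3 * x + 0.1 + rng.normal(0, 0.01, size=8)
        trainset = make_set(np.column_stack([x, np.zeros(8)]), reference=np.abs(c))
        model = fit_linear(trainset, 200.0)
        preds = predict(model, trainset)
        assert preds.shape == (8,)


class TestNipalsPLS:
    def test_exact_fit_when_y_in_column_space(self, rng):
        basis = rng.normal(size=(2, 3))
        scores = rng.normal(size=(5, 2))
        X = scores @ basis
        y = X @ np.array([1.0, -2.0, 0.5])
        model = nipals_pls_fit(X, y, 2)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_matches_sklearn_pls1(self, rng):
        # independent oracle: scikit-learn's NIPALS PLS regression
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = nipals_pls_fit(X, y, 3)
        oracle = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(predict(model, X),
                                   oracle.predict(X).ravel(), atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            nipals_pls_fit(rng.normal(size=(5, 3)), np.ones(5), 2)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        model = nipals_pls_fit(X, y, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_residual_orthogonal_to_scores(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        model = nipals_pls_fit(X, y, 3)
        Xc = X - model.x_mean
        resid = Xc - model.scores @ model.P.T
        assert np.max(np.abs(model.scores.T @ resid)) < 1e-8 * np.abs(Xc).max()

    def test_coefficients_reproduce_training_fit(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = nipals_pls_fit(X, y, 3)
        via_b = (X - model.x_mean) @ model.b + model.y_mean
        via_scores = model.scores @ model.q + model.y_mean
        np.testing.assert_allclose(via_b, via_scores, atol=1e-9)

    def test_full_rank_pls_equals_ordinary_least_squares(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = nipals_pls_fit(X, y, 4)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), Xd @ beta, atol=1e-8)

    def test_excess_components_truncated_with_flag(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = nipals_pls_fit(X, y, 10)
        assert model.truncated
        assert model.n_components <= 3

    def test_prediction_invariant_to_sample_ordering(self, rng):
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        model = nipals_pls_fit(X, y, 2)
        perm = rng.permutation(9)
        np.testing.assert_allclose(predict(model, X)[perm],
                                   predict(model, X[perm]), atol=1e-12)


class TestCVSelection:
    def test_exact_low_rank_response_selects_parsimony_floor(self, rng):
        # rank-2 design with y in the column space: two components fit
        # exactly on any training split, so the parsimony rule returns the
        # floor of the 2-10 search range
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 10))
        y = 2.0 * X[:, 3]
        selected, table = cv_select_components(X, y, seed=0)
        assert selected == 2
        assert set(table) == set(range(2, 11))

    def test_selection_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(25, 8))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.1, size=25)
        a1, t1 = cv_select_components(X, y, seed=42)
        a2, t2 = cv_select_components(X, y, seed=42)
        assert a1 == a2 and t1 == t2

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cv_select_components(rng.normal(size=(20, 5)),
                                 rng.normal(size=20), a_range=[])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="too few"):
            cv_select_components(rng.normal(size=(4, 5)), rng.normal(size=4))


class TestVIP:
    def test_squared_scores_sum_to_p(self, rng):
        X = rng.normal(size=(15, 12))
        y = rng.normal(size=15)
        model = nipals_pls_fit(X, y, 3)
        vip = vip_scores(model)
        assert np.sum(vip.scores ** 2) == pytest.approx(12, abs=1e-9)

    def test_single_component_closed_form(self, rng):
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        model = nipals_pls_fit(X, y, 1)
        vip = vip_scores(model)
        w = model.W[:, 0]
        expected = np.sqrt(7) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(vip.scores, expected, atol=1e-10)

    def test_uninformative_variable_scores_zero(self, rng):
        X = rng.normal(size=(12, 5))
        X[:, 2] = 0.0  # centered column is identically zero -> zero weight
        y = X[:, 0] + rng.normal(0, 0.01, size=12)
        model = nipals_pls_fit(X, y, 2)
        vip = vip_scores(model)
        assert vip.scores[2] == pytest.approx(0.0, abs=1e-10)


class TestVIPIntervals:
    def _result(self, scores, wn=None):
        scores = np.asarray(scores, dtype=float)
        if wn is None:
            wn = 400.0 + np.arange(scores.size)
        return VIPResult(scores=scores, wavenumbers=np.asarray(wn, dtype=float))

    def test_all_below_threshold_gives_empty_flagged(self):
        vip = self._result(np.full(30, 0.5))
        assert select_vip_intervals(vip, threshold=1.0) == []
        assert vip.empty_selection

    def test_all_above_threshold_spans_axis(self):
        vip = self._result(np.full(30, 2.0))
        assert select_vip_intervals(vip, threshold=1.0) == [(400.0, 429.0)]

    def test_short_runs_dropped_and_close_runs_merged(self):
        scores = np.zeros(60)
        scores[10:18] = 2.0   # run of 8
        scores[20:26] = 2.0   # gap of 2 -> merged with previous
        scores[40:42] = 2.0   # isolated run of 2 -> dropped
        vip = self._result(scores)
        assert select_vip_intervals(vip, threshold=1.0, min_width=5,
                                    merge_gap=5.0) == [(410.0, 425.0)]


class TestMetrics:
    def test_perfect_prediction(self):
        fit = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fit.rmse == 0.0 and fit.r2 == 1.0

    def test_mean_prediction_scores_zero_r2(self):
        ref = np.array([1.0, 2.0, 3.0, 6.0])
        fit = metrics(np.full(4, ref.mean()), ref)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_point_case(self):
        fit = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert fit.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert fit.r2 == pytest.approx(1.0 - 1.0 / (14.0 / 3.0))

    def test_zero_reference_variance_reports_missing_r2(self):
        fit = metrics([1.0, 2.0], [3.0, 3.0])
        assert fit.r2 is None and fit.rmse > 0


class TestSerialization:
    def test_pls_model_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = nipals_pls_fit(X, y, 2)
        model.pipeline = get_config("PLS_AMS")
        restored = model_from_json(model_to_json(model))
        np.testing.assert_allclose(predict(restored, X), predict(model, X),
                                   atol=1e-12)
        assert restored.pipeline == model.pipeline

    def test_linear_model_round_trip(self):
        trainset = make_set([[0.0, 1.0], [1.0, 1.0]], reference=[0.0, 1.1])
        model = fit_linear(trainset, 200.0)
        restored = model_from_json(model_to_json(model))
        assert (restored.slope, restored.intercept) == (model.slope, model.intercept)
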