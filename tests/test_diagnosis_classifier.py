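import numpy as np
import pytest
from scipy import stats

from facecoord.diagnosis_classifier import (
    CohortFeatures,
    CVConfig,
    average_feature_weights,
    compute_metrics,
    loocv_predict,
    nested_cv_predict,
    participant_accuracy,
)

TW_GRID = (1.0, 2.0)


def make_features(X, labels, tw_grid=TW_GRID, jitter_seed=None):
    """Wrap one matrix as a cohort, optionally jittering per Tw table."""
    tables = {}
    for k, tw in enumerate(tw_grid):
        if jitter_seed is None:
            tables[tw] = X
        else:
            rng = np.random.default_rng(jitter_seed + k)
            tables[tw] = X + 0.01 * rng.normal(size=X.shape)
    ids = tuple(f"p{i:02d}" for i in range(X.shape[0]))
    return CohortFeatures(tables, ids, tuple(labels), ())


def separable_cohort(n_per_class=10, n_features=3, gap=25.0, seed=0):
    # keep n_features << n so the margin cannot exploit noise directions
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[:n_per_class, 0] += gap
    labels = ("ASD",) * n_per_class + ("NT",) * n_per_class
    return make_features(X, labels)


class TestNestedCV:
    def test_separable_cohort_is_perfect(self):
        feats = separable_cohort()
        res = nested_cv_predict(feats, CVConfig(outer_folds=5, repeats=3,
                                                tw_grid=TW_GRID, seed=0))
        assert res.mean_accuracy() == 1.0

    def test_permuted_labels_are_at_chance(self):
        rng = np.random.default_rng(123)
        n = 24
        X = rng.normal(size=(n, 30))
        labels = np.array(("ASD",) * (n // 2) + ("NT",) * (n // 2))
        rng.shuffle(labels)
        feats = make_features(X, tuple(labels))
        res = nested_cv_predict(feats, CVConfig(outer_folds=6, repeats=20,
                                                tw_grid=TW_GRID, seed=1))
        # central 95% binomial band around 0.5 for n independent decisions;
        # repeats are correlated so use the per-repeat count n, widened 2x
        half_width = 2 * 1.96 * np.sqrt(0.25 / n)
        assert abs(res.mean_accuracy() - 0.5) < half_width

    def test_same_seed_is_deterministic(self):
        feats = separable_cohort(seed=5)
        cfg = CVConfig(outer_folds=4, repeats=2, tw_grid=TW_GRID, seed=9)
        a = nested_cv_predict(feats, cfg)
        b = nested_cv_predict(feats, cfg)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert [f.selected_tw for f in a.folds] == [f.selected_tw for f in b.folds]
        np.testing.assert_array_equal(a.fold_weights(), b.fold_weights())

    def test_every_participant_predicted_once_per_repeat(self):
        feats = separable_cohort(n_per_class=7)
        res = nested_cv_predict(feats, CVConfig(outer_folds=3, repeats=4,
                                                tw_grid=TW_GRID, seed=2))
        counts = np.zeros(14, dtype=int)
        for rec in res.folds:
            if rec.repeat == 0:
                counts[rec.test_indices] += 1
        np.testing.assert_array_equal(counts, 1)

    def test_single_class_training_fold_raises(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        feats = make_features(X, ("ASD", "ASD", "NT", "NT"))
        cfg = CVConfig(outer_folds=2, repeats=1, inner_folds=2,
                       tw_grid=TW_GRID, seed=0, shuffle=False)
        with pytest.raises(ValueError, match="single class"):
            nested_cv_predict(feats, cfg)

    def test_fewer_than_two_per_class_raises(self):
        X = np.random.default_rng(0).normal(size=(3, 3))
        feats = make_features(X, ("ASD", "NT", "NT"))
        with pytest.raises(ValueError, match="2 participants per class"):
            nested_cv_predict(feats, CVConfig(outer_folds=2, tw_grid=TW_GRID))

    def test_tw_selection_prefers_informative_table(self):
        # Tw=1 table is pure noise, Tw=2 table is separable -> 2 is selected
        rng = np.random.default_rng(3)
        n = 16
        labels = ("ASD",) * 8 + ("NT",) * 8
        noise = rng.normal(size=(n, 5))
        signal = rng.normal(size=(n, 5))
        signal[:8, 0] += 10.0
        feats = CohortFeatures({1.0: noise, 2.0: signal},
                               tuple(f"p{i}" for i in range(n)), labels)
        res = nested_cv_predict(feats, CVConfig(outer_folds=4, repeats=2,
                                                tw_grid=(1.0, 2.0), seed=4))
        assert res.selected_tw_counts() == {2.0: 8}

    def test_no_leakage_canary(self):
        # a feature equal to the label separates under train-only scaling;
        # the same feature shuffled must not give perfect accuracy
        rng = np.random.default_rng(6)
        n = 20
        labels = np.array(("ASD",) * 10 + ("NT",) * 10)
        rng.shuffle(labels)
        X = rng.normal(size=(n, 10))
        X[:, 0] = (labels == "ASD").astype(float)
        cfg = CVConfig(outer_folds=5, repeats=2, tw_grid=TW_GRID, seed=7)
        assert nested_cv_predict(make_features(X, tuple(labels)), cfg).mean_accuracy() == 1.0
        X_shuf = X.copy()
        X_shuf[:, 0] = rng.permutation(X_shuf[:, 0])
        acc = nested_cv_predict(make_features(X_shuf, tuple(labels)), cfg).mean_accuracy()
        assert acc < 1.0


class TestLoocv:
    def test_separable_all_correct(self):
        feats = separable_cohort(n_per_class=6)
        res = loocv_predict(feats, CVConfig(tw_grid=TW_GRID, seed=0))
        assert res.mean_accuracy() == 1.0
        assert res.predictions.shape == (1, 12)

    def test_matches_nested_with_n_folds_one_repeat(self):
        feats = separable_cohort(n_per_class=5, gap=1.0, seed=8)
        loo = loocv_predict(feats, CVConfig(tw_grid=TW_GRID, seed=3))
        nested = nested_cv_predict(
            feats,
            CVConfig(outer_folds=10, repeats=1, tw_grid=TW_GRID, seed=3,
                     shuffle=False),
        )
        np.testing.assert_array_equal(loo.predictions, nested.predictions)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(11)
        n = 20
        labels = np.array(("ASD",) * 10 + ("NT",) * 10)
        rng.shuffle(labels)
        feats = make_features(rng.normal(size=(n, 15)), tuple(labels))
        acc = loocv_predict(feats, CVConfig(tw_grid=TW_GRID, seed=0)).mean_accuracy()
        # LOOCV on noise is noisy; just require it is far from perfect
        assert acc <= 0.8


class TestParticipantAccuracy:
    def test_separable_all_ones(self):
        feats = separable_cohort(n_per_class=6)
        acc = participant_accuracy(feats, k_folds=3, repeats=5,
                                   cfg=CVConfig(tw_grid=TW_GRID, seed=0))
        np.testing.assert_array_equal(acc, 1.0)

    def test_reproducible_with_fixed_seed(self):
        feats = separable_cohort(n_per_class=5, gap=0.5, seed=2)
        cfg = CVConfig(tw_grid=TW_GRID, seed=13)
        a = participant_accuracy(feats, k_folds=5, repeats=4, cfg=cfg)
        b = participant_accuracy(feats, k_folds=5, repeats=4, cfg=cfg)
        np.testing.assert_array_equal(a, b)

    def test_vector_mean_equals_overall_accuracy(self):
        feats = separable_cohort(n_per_class=5, gap=0.5, seed=2)
        cfg = CVConfig(outer_folds=5, repeats=4, tw_grid=TW_GRID, seed=13)
        res = nested_cv_predict(feats, cfg)
        assert res.per_participant_accuracy().mean() == pytest.approx(
            res.mean_accuracy()
        )


class TestMetrics:
    def test_all_correct_gives_ones(self):
        y = ["ASD", "NT", "ASD", "NT"]
        m = compute_metrics(y, y)
        assert m.as_dict() == {
            "accuracy": 1.0, "ppv": 1.0, "npv": 1.0,
            "sensitivity": 1.0, "specificity": 1.0,
        }
        assert m.undefined == ()

    def test_hand_computed_confusion_matrix(self):
        # TP=3, FN=2, TN=9, FP=1
        truth = ["ASD"] * 5 + ["NT"] * 10
        pred = (["ASD"] * 3 + ["NT"] * 2) + (["NT"] * 9 + ["ASD"] * 1)
        m = compute_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.9)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(9 / 11)
        assert m.accuracy == pytest.approx(12 / 15)

    def test_no_predicted_positives_flags_ppv(self):
        m = compute_metrics(["NT", "NT"], ["ASD", "NT"])
        assert np.isnan(m.ppv)
        assert "ppv" in m.undefined
        assert m.specificity == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(["ASD"], ["ASD", "NT"])


class TestAverageFeatureWeights:
    def _result_with_weights(self, weight_rows):
        feats = separable_cohort(n_per_class=4, n_features=len(weight_rows[0]))
        res = nested_cv_predict(feats, CVConfig(outer_folds=2, repeats=1,
                                                inner_folds=2, tw_grid=TW_GRID,
                                                seed=0))
        for rec, w in zip(res.folds, weight_rows):
            object.__setattr__(rec, "weights", np.asarray(w, dtype=float))
        return res

    def test_single_fold_mean_is_abs_weights(self):
        res = self._result_with_weights([[1.0, -2.0, 0.5]])
        res.folds = res.folds[:1]
        mean, stderr = average_feature_weights(res)
        np.testing.assert_array_equal(mean, [1.0, 2.0, 0.5])
        np.testing.assert_array_equal(stderr, 0.0)

    def test_equal_folds_zero_stderr(self):
        res = self._result_with_weights([[1.0, -2.0, 0.5], [-1.0, 2.0, 0.5]])
        res.folds = res.folds[:2]
        mean, stderr = average_feature_weights(res)
        np.testing.assert_array_equal(mean, [1.0, 2.0, 0.5])
        np.testing.assert_allclose(stderr, 0.0, atol=1e-12)

    def test_matches_direct_recomputation(self):
        feats = separable_cohort(n_per_class=6, gap=1.0, seed=4)
        res = nested_cv_predict(feats, CVConfig(outer_folds=3, repeats=2,
                                                tw_grid=TW_GRID, seed=1))
        mean, stderr = average_feature_weights(res)
        absw = np.abs(np.vstack([f.weights for f in res.folds]))
        np.testing.assert_allclose(mean, absw.mean(axis=0))
        np.testing.assert_allclose(
            stderr, stats.sem(absw, axis=0, ddof=1), atol=1e-12
        )
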