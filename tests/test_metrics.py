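"""Cross-validated SVM fitness and panel evaluation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpanel import (
    ClassifierConfig,
    FitnessEvaluator,
    PCAEncoder,
    SyntheticSpec,
    compute_metrics,
    cv_accuracy,
    generate,
)


def _confusion_to_vectors(tp, tn, fp, fn):
    y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
    y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
    # decision scores consistent with the predictions
    scores = np.where(y_pred == 1, 1.0, -1.0) + np.linspace(0, 1e-6, len(y_pred))
    return y_true, y_pred, scores


def _mcc_formula(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


class TestCvAccuracy:
    def test_separated_classes_classified(self):
        ds = generate(
            SyntheticSpec(s_tumor=50, s_control=50, d=20, n_planted=4,
                          effect_size=6.0, noise_sd=0.5, seed=2)
        )
        X = ds.log2_rpm()
        planted = np.array(ds.truth["planted_indices"]) - 1
        acc = cv_accuracy(X[:, planted], ds.labels, ClassifierConfig(seed=0))
        assert acc > 0.95

    def test_noise_features_near_majority_rate(self):
        ds = generate(
            SyntheticSpec(s_tumor=60, s_control=40, d=20, n_planted=2,
                          effect_size=0.0, seed=9)
        )
        X = ds.log2_rpm()
        acc = cv_accuracy(X[:, :10], ds.labels, ClassifierConfig(seed=0))
        assert abs(acc - 0.6) < 0.1

    def test_deterministic_given_seed(self, small_xy):
        X, y = small_xy
        cfg = ClassifierConfig(seed=42)
        assert cv_accuracy(X, y, cfg) == cv_accuracy(X, y, cfg)

    def test_column_permutation_invariant(self, small_xy):
        X, y = small_xy
        cfg = ClassifierConfig(seed=3)
        perm = np.random.default_rng(1).permutation(X.shape[1])
        assert cv_accuracy(X, y, cfg) == pytest.approx(cv_accuracy(X[:, perm], y, cfg))

    def test_unstratified_single_class_train_fold_errors(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.array([0] * 19 + [1])
        with pytest.raises(ValueError, match="stratification"):
            cv_accuracy(X, y, ClassifierConfig(folds=10, stratified=False, seed=0))


class TestFitness:
    @pytest.fixture()
    def evaluator(self, small_xy, clf_config):
        X, y = small_xy
        enc = PCAEncoder(n_components=4).fit(X)
        return FitnessEvaluator(X, y, enc, clf_config)

    def test_order_invariant_via_set_cache(self, evaluator):
        a = evaluator(np.array([3, 1, 7, 9]))
        b = evaluator(np.array([9, 7, 1, 3]))
        assert a == b
        assert evaluator.n_calls == 2
        assert evaluator.n_evaluations == 1

    def test_bounded(self, evaluator, rng):
        for _ in range(5):
            v = rng.choice(40, size=4, replace=False) + 1
            assert 0.0 <= evaluator(v) <= 1.0

    def test_planted_beats_random_panel(self, small_dataset, clf_config):
        X = small_dataset.log2_rpm()
        y = small_dataset.labels
        enc = PCAEncoder(n_components=4).fit(X)
        evaluator = FitnessEvaluator(X, y, enc, clf_config)
        planted = np.array(small_dataset.truth["planted_indices"])
        non_planted = np.setdiff1d(np.arange(1, 41), planted)
        random_v = np.random.default_rng(5).choice(non_planted, size=4, replace=False)
        assert evaluator(planted) > evaluator(random_v)


class TestComputeMetrics:
    def test_perfect_prediction_maximizes_all(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        bundle = compute_metrics(y, y, np.where(y == 1, 2.0, -2.0))
        assert bundle.accuracy == bundle.f_measure == bundle.auc == 1.0
        assert bundle.mcc == pytest.approx(1.0)
        assert bundle.aggregated_score == pytest.approx(4.0)

    def test_all_tumor_prediction_on_balanced_set(self):
        y_true = np.array([1] * 5 + [0] * 5)
        y_pred = np.ones(10, dtype=int)
        bundle = compute_metrics(y_true, y_pred, np.zeros(10))
        assert bundle.accuracy == pytest.approx(0.5)
        assert bundle.mcc == 0.0  # zero-denominator convention

    @pytest.mark.parametrize(
        "tp, tn, fp, fn",
        [(50, 40, 10, 5), (3, 3, 3, 3), (10, 0, 5, 2), (1, 20, 0, 4), (7, 2, 0, 0)],
    )
    def test_mcc_matches_formula(self, tp, tn, fp, fn):
        y_true, y_pred, scores = _confusion_to_vectors(tp, tn, fp, fn)
        bundle = compute_metrics(y_true, y_pred, scores)
        assert bundle.mcc == pytest.approx(_mcc_formula(tp, tn, fp, fn), abs=1e-9)

    def test_reference_confusion_matrix(self):
        # TP=50 TN=40 FP=10 FN=5 -> MCC = (2000-50)/sqrt(60*55*50*45) = 0.71563
        y_true, y_pred, scores = _confusion_to_vectors(50, 40, 10, 5)
        bundle = compute_metrics(y_true, y_pred, scores)
        assert bundle.mcc == pytest.approx(1950 / math.sqrt(60 * 55 * 50 * 45), abs=1e-9)
        assert bundle.mcc == pytest.approx(0.7156, abs=1e-4)

    def test_mcc_symmetric_under_class_swap(self):
        y_true, y_pred, scores = _confusion_to_vectors(12, 30, 4, 9)
        a = compute_metrics(y_true, y_pred, scores).mcc
        b = compute_metrics(1 - y_true, 1 - y_pred, -scores).mcc
        assert a == pytest.approx(b)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics([1, 1], [1, 0], [0.5, -0.5])

    @settings(deadline=None, max_examples=100)
    @given(
        tp=st.integers(0, 40), tn=st.integers(0, 40),
        fp=st.integers(0, 40), fn=st.integers(0, 40),
    )
    def test_aggregated_score_bounded(self, tp, tn, fp, fn):
        if tp + fn == 0 or tn + fp == 0:
            return  # single-class truth is rejected, covered above
        y_true, y_pred, scores = _confusion_to_vectors(tp, tn, fp, fn)
        bundle = compute_metrics(y_true, y_pred, scores)
        assert 0.0 <= bundle.aggregated_score <= 4.0
        expected = (
            bundle.accuracy + bundle.f_measure + (bundle.mcc + 1) / 2 + bundle.auc
        )
        assert bundle.aggregated_score == pytest.approx(expected)
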