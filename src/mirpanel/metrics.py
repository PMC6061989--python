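"""SVM cross-validation fitness and panel evaluation metrics.

The fitness guiding the evolutionary search is the mean 10-fold
cross-validated accuracy of an RBF-kernel SVM.  Inputs are z-scored on
each training fold (the fixed kernel width gamma=0.5 presumes comparably
scaled features; log2-RPM columns span an order of magnitude in location
and spread, and unscaled they push the kernel matrix to identity).  Folds
are stratified by default: the pooled-control design the method targets is imbalanced (e.g.
hundreds of tumors vs a shared control pool) and plain k-fold splits can
produce single-class training sets.

Panel evaluation reports accuracy, F-measure (positive class = tumor),
Matthews correlation coefficient and AUC, consolidated into a single
Aggregated Score ``AS = accuracy + F + (MCC+1)/2 + AUC``.  The MCC term is
affinely mapped from [-1, 1] to [0, 1] inside the sum so the score is
bounded in [0, 4]; the raw MCC is reported unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .encoders import enhance


@dataclass
class ClassifierConfig:
    """RBF-SVM and cross-validation settings.

    gamma and cost are the kernel width and error/margin trade-off of the
    SVM (defaults 0.5 and 2.0); ``folds`` is the number of CV folds.
    """

    gamma: float = 0.5
    cost: float = 2.0
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class MetricsBundle:
    """Panel classification metrics and their aggregated summary."""

    accuracy: float
    f_measure: float
    mcc: float
    auc: float
    aggregated_score: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "auc": self.auc,
            "aggregated_score": self.aggregated_score,
        }


def _fold_scale(X_train, X_test):
    # features are z-scored on each training fold: the RBF width gamma is a
    # fixed constant, so it must act on comparably scaled inputs regardless
    # of the expression magnitudes of the selected columns
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def _svm(cfg: ClassifierConfig) -> SVC:
    return SVC(kernel="rbf", gamma=cfg.gamma, C=cfg.cost)


def _splitter(cfg: ClassifierConfig):
    if cfg.stratified:
        return StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    return KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def cv_accuracy(X, y, cfg: ClassifierConfig) -> float:
    """Mean per-fold accuracy of an RBF-kernel SVM; deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if X.shape[0] < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} samples for {cfg.folds}-fold CV")
    accs = []
    for train, test in _splitter(cfg).split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                "a training fold contains a single class; enable stratification"
            )
        X_train, X_test = _fold_scale(X[train], X[test])
        clf = _svm(cfg)
        clf.fit(X_train, y[train])
        accs.append(float((clf.predict(X_test) == y[test]).mean()))
    return float(np.mean(accs))


def cv_predictions(X, y, cfg: ClassifierConfig) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predicted labels and decision scores for metric computation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    for train, test in _splitter(cfg).split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                "a training fold contains a single class; enable stratification"
            )
        X_train, X_test = _fold_scale(X[train], X[test])
        clf = _svm(cfg)
        clf.fit(X_train, y[train])
        y_pred[test] = clf.predict(X_test)
        scores[test] = clf.decision_function(X_test)
    return y_pred, scores


def cv_metrics(X, y, cfg: ClassifierConfig) -> MetricsBundle:
    """Cross-validated :class:`MetricsBundle` from pooled out-of-fold predictions."""
    y_pred, scores = cv_predictions(X, y, cfg)
    return compute_metrics(y, y_pred, scores)


def compute_metrics(y_true, y_pred, decision_scores) -> MetricsBundle:
    """Accuracy, F-measure, MCC, AUC and the Aggregated Score.

    F-measure uses tumor (1) as the positive class; MCC follows the
    0-on-zero-denominator convention; AUC is the trapezoidal area under the
    ROC curve of ``decision_scores``.  ``AS = acc + F + (MCC+1)/2 + AUC``
    is bounded in [0, 4].
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    decision_scores = np.asarray(decision_scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(decision_scores)):
        raise ValueError("y_true, y_pred and decision_scores must share a length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC is undefined for single-class y_true")
    acc = float(accuracy_score(y_true, y_pred))
    f = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on the 0/0 convention
        mcc = float(matthews_corrcoef(y_true, y_pred))
    auc = float(roc_auc_score(y_true, decision_scores))
    return MetricsBundle(
        accuracy=acc,
        f_measure=f,
        mcc=mcc,
        auc=auc,
        aggregated_score=acc + f + (mcc + 1.0) / 2.0 + auc,
    )


class FitnessEvaluator:
    """Callable fitness: CV accuracy of the SVM on the enhanced matrix ``Ê(v)``.

    Results are cached keyed by the *set* of indices (DE revisits vectors,
    and the SVM runs are the dominant cost), so two candidates with the
    same features in different order share one evaluation.

    Attributes
    ----------
    n_calls : int
        Fitness invocations, cached or not.
    n_evaluations : int
        Actual SVM cross-validation runs (cache misses).
    """

    def __init__(
        self,
        values,
        y,
        encoder,
        clf_config: ClassifierConfig,
        enhance_mode: str = "additive",
    ):
        self.values = np.asarray(values, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.encoder = encoder
        self.clf_config = clf_config
        self.enhance_mode = enhance_mode
        self.n_calls = 0
        self.n_evaluations = 0
        self._cache: dict[frozenset, float] = {}

    def __call__(self, indices) -> float:
        self.n_calls += 1
        key = frozenset(int(i) for i in indices)
        if key not in self._cache:
            self.n_evaluations += 1
            # canonical (sorted) order: the cache key is the set, so the
            # evaluated enhancement must not depend on element order
            canonical = np.sort(np.asarray(indices, dtype=int))
            enhanced = enhance(self.values, canonical, self.encoder, mode=self.enhance_mode)
            self._cache[key] = cv_accuracy(enhanced, self.y, self.clf_config)
        return self._cache[key]
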