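"""Component-analysis encoders and the enhanced feature matrix.

The selector never feeds raw selected columns ``E(v)`` to the classifier.
Instead the full dataset is projected once onto its top ``n`` components
(PCA or RBF-kernel PCA), giving a score matrix ``Ê`` with one row per
sample, and each candidate's selected-column matrix is *enhanced* by
combining it entrywise with ``Ê`` (see :func:`enhance` for the available
combinations).  Enhancement keeps one row per sample — so cross-validation
fold membership survives it — while every entry carries both the
dataset-wide component structure and the candidate's own expression
values.

``Ê`` is computed once per dataset and reused across all fitness calls;
this is what keeps the evolutionary search affordable, since the SVM is
cheap compared with a fresh decomposition per candidate.

Both encoders fix the sign of each score column so that its
largest-magnitude entry is positive, making runs reproducible across
linear-algebra backends.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, KernelPCA
from sklearn.utils.validation import check_array, check_is_fitted


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Return per-column sign flips making the largest-|entry| positive."""
    idx = np.argmax(np.abs(scores), axis=0)
    signs = np.sign(scores[idx, np.arange(scores.shape[1])])
    signs[signs == 0] = 1.0
    return signs


class PCAEncoder(TransformerMixin, BaseEstimator):
    """Linear principal-component encoder.

    Parameters
    ----------
    n_components : int
        Number of leading components to keep; must not exceed the rank of
        the centered data.

    Attributes
    ----------
    scores_ : ndarray of shape (s, n_components)
        Projections of the training data (the matrix ``Ê``).
    explained_variance_ratio_ : ndarray of shape (n_components,)
    """

    method = "pca"

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        s, d = X.shape
        n = int(self.n_components)
        if not 1 <= n <= min(s, d):
            raise ValueError(f"n_components must be in [1, {min(s, d)}], got {n}")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if n > rank:
            raise ValueError(
                f"n_components={n} exceeds the rank of the centered data "
                f"(achievable rank {rank})"
            )
        pca = PCA(n_components=n, svd_solver="full")
        scores = pca.fit_transform(X)
        self._signs = _fix_signs(scores)
        self._pca = pca
        self.scores_ = scores * self._signs
        self.components_ = pca.components_ * self._signs[:, None]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scores_")
        X = check_array(X, dtype=float)
        return self._pca.transform(X) * self._signs


class KPCAEncoder(TransformerMixin, BaseEstimator):
    """RBF-kernel principal-component encoder.

    Parameters
    ----------
    n_components : int
    kernel_width : float or None
        RBF coefficient gamma in ``exp(-gamma * ||x - x'||^2)``; ``None``
        uses the scale-free default ``1/d``.

    Attributes
    ----------
    scores_ : ndarray of shape (s, n_components)
        Eigen-scores of the double-centered kernel matrix, sign-fixed.
    kernel_width_ : float
        The width actually used.
    """

    method = "kpca"

    def __init__(self, n_components: int = 10, kernel_width: float | None = None):
        self.n_components = n_components
        self.kernel_width = kernel_width

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        s, d = X.shape
        n = int(self.n_components)
        if not 1 <= n <= s:
            raise ValueError(f"n_components must be in [1, {s}], got {n}")
        gamma = 1.0 / d if self.kernel_width is None else float(self.kernel_width)
        if gamma <= 0:
            raise ValueError("kernel_width must be > 0")
        kpca = KernelPCA(n_components=n, kernel="rbf", gamma=gamma)
        try:
            scores = kpca.fit_transform(X)
        except ValueError as err:  # sklearn rejects n_components > #positive eigenvalues
            raise ValueError(
                f"kernel is degenerate for n_components={n} "
                "(all-equal samples or too few informative directions)"
            ) from err
        if scores.shape[1] < n or not np.all(
            kpca.eigenvalues_[:n] > 1e-12 * max(1.0, kpca.eigenvalues_[0])
        ):
            raise ValueError(
                f"kernel is degenerate: fewer than {n} non-null components"
            )
        self._signs = _fix_signs(scores)
        self._kpca = kpca
        self.scores_ = scores * self._signs
        self.kernel_width_ = gamma
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scores_")
        X = check_array(X, dtype=float)
        return self._kpca.transform(X) * self._signs


def choose_encoder(X, y, n_components, clf_config, kernel_width=None, score_fn=None):
    """Fit both encoders and keep the one whose score matrix classifies better.

    Both score matrices are evaluated with the same cross-validation folds
    and seed; an exact tie goes to PCA (the simpler model).

    Returns
    -------
    encoder : PCAEncoder or KPCAEncoder
        The winning fitted encoder, carrying a ``selection_log_`` attribute
        ``{"pca": acc, "kpca": acc, "chosen": method}``.
    """
    if score_fn is None:
        from .metrics import cv_accuracy

        score_fn = lambda scores: cv_accuracy(scores, y, clf_config)  # noqa: E731
    pca = PCAEncoder(n_components=n_components).fit(X)
    kpca = KPCAEncoder(n_components=n_components, kernel_width=kernel_width).fit(X)
    acc_pca = score_fn(pca.scores_)
    acc_kpca = score_fn(kpca.scores_)
    chosen = kpca if acc_kpca > acc_pca else pca
    chosen.selection_log_ = {"pca": acc_pca, "kpca": acc_kpca, "chosen": chosen.method}
    return chosen


def _zscore_columns(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (A - mu) / sd


def enhance(values: np.ndarray, v, encoder, mode: str = "additive") -> np.ndarray:
    """Combine the selected-column matrix ``E(v)`` with the score matrix ``Ê``.

    All modes keep one row per sample, so cross-validation fold membership
    survives enhancement.  ``v`` holds 1-based feature indices and, except
    for ``gram``, ``|v|`` must equal the encoder's component count.

    ``additive`` (default)
        ``Ê(v) = z(E(v)) + z(Ê)`` — both matrices column-standardized and
        summed entrywise.  Every entry carries the dataset-wide component
        structure *and* the candidate's own expression signal with equal
        weight, which makes the fitness genuinely sensitive to which
        columns were selected.
    ``hadamard``
        ``Ê(v)[i, k] = E(v)[i, k] * Ê[i, k]`` — the literal entrywise
        product.  On non-negative expression values the product is a mild
        positive modulation of ``Ê``, so the fitness is dominated by the
        encoder and barely depends on the candidate (see the methods
        note); kept as a documented switch.
    ``gram``
        ``Ê(v) = E(v) · Êᵀ`` — s x s Gram-like features.
    """
    scores = encoder.scores_
    v = np.asarray(v, dtype=int)
    if mode not in ("additive", "hadamard", "gram"):
        raise ValueError("mode must be 'additive', 'hadamard' or 'gram'")
    if v.size != scores.shape[1]:
        raise ValueError(
            f"candidate length {v.size} != encoder components {scores.shape[1]}"
        )
    if values.shape[0] != scores.shape[0]:
        raise ValueError("encoder was fitted on a different number of samples")
    selected = values[:, v - 1]
    if mode == "additive":
        return _zscore_columns(selected) + _zscore_columns(scores)
    if mode == "hadamard":
        return selected * scores
    return selected @ scores.T
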