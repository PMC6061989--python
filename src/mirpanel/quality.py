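"""Cluster-quality diagnostics: cosine homogeneity and separation.

A good two-class panel would make sample profiles similar within a class
(high homogeneity) and dissimilar across classes (low separation — note
these are similarities, not distances).  On real miRNA profiles the two
tend to be close, which is the empirical argument for treating biomarker
discovery as classification rather than clustering.

Homogeneity of a class is the unweighted mean cosine similarity over all
unordered within-class pairs (self-pairs excluded); separation is the mean
over all inter-class pairs.  Profiles are used as-is (log2-RPM,
non-negative), without centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)


@dataclass
class ClusterQualityReport:
    homogeneity_tumor: float
    homogeneity_control: float
    separation: float
    panel: list[str]

    def as_dict(self) -> dict:
        return {
            "homogeneity_tumor": self.homogeneity_tumor,
            "homogeneity_control": self.homogeneity_control,
            "separation": self.separation,
            "panel": self.panel,
        }


def _check_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm sample vector: cosine similarity undefined")
    return X


def homogeneity(X) -> float:
    """Mean pairwise cosine similarity among the rows of one class."""
    X = _check_rows(X)
    m = X.shape[0]
    if m < 2:
        raise ValueError("homogeneity needs at least 2 members")
    sim = cosine_similarity(X)
    upper = sim[np.triu_indices(m, k=1)]
    return float(upper.mean())


def separation(X, labels) -> float:
    """Mean cosine similarity over all inter-class pairs of rows."""
    X = _check_rows(X)
    labels = np.asarray(labels, dtype=int)
    a = X[labels == 1]
    b = X[labels == 0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    return float(cosine_similarity(a, b).mean())


def cluster_quality(
    values, labels, panel_columns, panel_names=None, drop_zero_rows: bool = False
) -> ClusterQualityReport:
    """Report homogeneity per class and separation on panel-restricted profiles.

    ``panel_columns`` are 0-based column indices into ``values``.  With
    ``drop_zero_rows`` samples whose panel-restricted profile is all zero
    (cosine undefined) are excluded with a logged count instead of raising.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    X = values[:, list(panel_columns)]
    if drop_zero_rows:
        keep = np.linalg.norm(X, axis=1) > 0
        if not keep.all():
            logger.info(
                "cluster_quality: dropping %d all-zero panel profile(s)",
                int((~keep).sum()),
            )
        X, labels = X[keep], labels[keep]
    return ClusterQualityReport(
        homogeneity_tumor=homogeneity(X[labels == 1]),
        homogeneity_control=homogeneity(X[labels == 0]),
        separation=separation(X, labels),
        panel=list(panel_names) if panel_names is not None else [str(c) for c in panel_columns],
    )
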