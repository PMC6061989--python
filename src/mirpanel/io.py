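"""Reading, validation and normalization of two-class miRNA expression matrices.

The on-disk dialect is a tab-separated matrix with miRNA rows and sample
columns (header row of sample IDs, first column of miRNA names) plus a
two-column labels file mapping each sample ID to ``tumor`` or ``control``.
In memory the orientation is samples x features and feature names are kept
in lexicographic order so that integer references into the feature table
are stable across runs.

Feature indices are 1-based in all user-facing I/O (candidate vectors
reference features as indices in ``[1, d]``); internal numpy indexing is
0-based and the conversion happens only at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: label encoding used throughout the package
CLASS_CODES = {"control": 0, "tumor": 1}
CODE_NAMES = {0: "control", 1: "tumor"}


@dataclass
class ExpressionMatrix:
    """A two-class expression dataset in log2 reads-per-million units.

    Attributes
    ----------
    values : ndarray of shape (s, d)
        Expression levels, samples x features, finite.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    feature_names : list of str
        Unique miRNA names in lexicographic order (the static feature
        table ``M``); column ``k`` of ``values`` is feature
        ``feature_names[k]``.
    labels : ndarray of shape (s,)
        Binary class per sample, 1 = tumor, 0 = control.
    """

    values: np.ndarray
    sample_ids: list[str] = field(repr=False)
    feature_names: list[str] = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = list(self.sample_ids)
        self.feature_names = list(self.feature_names)
        s, d = self.values.shape
        if len(self.sample_ids) != s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {s} rows")
        if len(self.feature_names) != d:
            raise ValueError(f"{len(self.feature_names)} feature names for {d} columns")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != d:
            raise ValueError("duplicate feature names")
        if self.feature_names != sorted(self.feature_names):
            raise ValueError("feature names must be in lexicographic order")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.labels.shape != (s,):
            raise ValueError("labels length must equal number of samples")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0 = control, 1 = tumor)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def read_expression(matrix_path, labels_path) -> ExpressionMatrix:
    """Read a miRNA-rows-by-sample-columns TSV plus a sample labels TSV.

    Samples present in the matrix but absent from the labels file are
    dropped with a logged warning.  Features are re-sorted
    lexicographically; both classes must be present after the join.
    """
    table = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA names in {matrix_path}: {dupes}")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {matrix_path}: {dupes}")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = table.columns[numeric.isna().any(axis=0)].tolist()
        raise ValueError(f"non-numeric cells in {matrix_path} (samples {bad})")

    labels_map = _read_labels(labels_path)
    kept = [s for s in numeric.columns if s in labels_map]
    missing = [s for s in numeric.columns if s not in labels_map]
    if missing:
        logger.warning(
            "dropping %d sample(s) absent from %s: %s", len(missing), labels_path, missing
        )
    if not kept:
        raise ValueError("no samples shared between matrix and labels file")

    numeric = numeric.sort_index()
    values = numeric[kept].to_numpy(dtype=float).T
    labels = np.array([labels_map[s] for s in kept], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes (tumor and control) must be present")
    return ExpressionMatrix(
        values=values,
        sample_ids=kept,
        feature_names=numeric.index.tolist(),
        labels=labels,
    )


def _read_labels(labels_path) -> dict[str, int]:
    frame = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"labels file {labels_path} needs two tab-separated columns")
    frame = frame.iloc[:, :2]
    # tolerate an optional header row
    if str(frame.iloc[0, 1]).strip().lower() not in CLASS_CODES:
        frame = frame.iloc[1:]
    mapping: dict[str, int] = {}
    for sample_id, cls in frame.itertuples(index=False):
        cls = str(cls).strip().lower()
        if cls not in CLASS_CODES:
            raise ValueError(f"unknown class {cls!r} for sample {sample_id!r}")
        if sample_id in mapping:
            raise ValueError(f"duplicate sample id in labels file: {sample_id!r}")
        mapping[str(sample_id)] = CLASS_CODES[cls]
    return mapping


def write_expression(em: ExpressionMatrix, matrix_path, labels_path) -> None:
    """Write the TSV dialect that :func:`read_expression` reads back.

    Values are written with 6 decimal places, so a round trip reproduces
    them to 6 decimals with identical names and labels.
    """
    frame = pd.DataFrame(em.values.T, index=em.feature_names, columns=em.sample_ids)
    frame.index.name = "miRNA"
    frame.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(labels_path, "w") as fh:
        for sample_id, code in zip(em.sample_ids, em.labels):
            fh.write(f"{sample_id}\t{CODE_NAMES[int(code)]}\n")


def normalize_rpm_log2(counts, library_sizes) -> np.ndarray:
    """Convert raw counts to log2 reads-per-million.

    ``entry = log2(1 + 1e6 * count / library_size)`` with a +1 pseudocount
    so zero counts map to 0 and every output is finite and non-negative.

    Parameters
    ----------
    counts : array of shape (s, d)
        Non-negative counts, samples x features.
    library_sizes : array of shape (s,)
        Strictly positive per-sample sequencing totals.
    """
    counts = np.asarray(counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D samples x features array")
    if library_sizes.shape != (counts.shape[0],):
        raise ValueError("library_sizes must have one entry per sample (row)")
    if not np.all(np.isfinite(counts)) or (counts < 0).any():
        raise ValueError("counts must be finite and non-negative")
    if (library_sizes <= 0).any() or not np.all(np.isfinite(library_sizes)):
        raise ValueError("library sizes must be strictly positive and finite")
    rpm = 1e6 * counts / library_sizes[:, None]
    return np.log2(1.0 + rpm)


def select_columns(em: ExpressionMatrix, v) -> np.ndarray:
    """Return the submatrix ``E(v)`` of the columns named by 1-based indices ``v``.

    Columns appear in the order given; ``em`` is not modified.
    """
    v = np.asarray(v, dtype=int)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("index vector must be a non-empty 1-D sequence")
    d = em.n_features
    if ((v < 1) | (v > d)).any():
        raise ValueError(f"indices must lie in [1, {d}], got {v.tolist()}")
    if len(set(v.tolist())) != v.size:
        raise ValueError(f"indices must be distinct, got {v.tolist()}")
    return em.values[:, v - 1].copy()
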