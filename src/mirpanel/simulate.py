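"""Synthetic two-class miRNA-seq count data with a planted discriminative panel.

The generator emulates log2-RPM-scaled tumor/control expression matrices so
every downstream stage (normalization, encoding, DE search, finishing,
evaluation) is testable without external data.  Counts are drawn as
lognormal-Poisson: a Gaussian log2-mean per feature, per-sample Gaussian
biological noise, a multiplicative lognormal overdispersion term, then
Poisson sampling scaled to a per-sample library size.

Three planted effect models are supported:

``shift``
    planted features gain ``effect_size`` log2 units of mean expression in
    tumor samples — the classic differential-expression signal.
``correlated``
    the mean shift plus a shared per-sample latent factor coupling the
    planted features, so their expression co-varies within samples.
``xor``
    class membership is determined by the *sign product* of consecutive
    pairs of planted features' centered values (each feature deviates
    ±effect_size/2 from its baseline with no marginal mean shift), so every
    single-feature test is blind to the signal while a non-linear
    classifier on the pair is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np

from .io import CODE_NAMES, normalize_rpm_log2

EFFECT_MODELS = ("shift", "correlated", "xor")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a two-class cohort of 150 tumor and 150 control
    samples over 200 miRNAs with a 10-feature planted panel shifted by
    4 log2 units against a biological noise SD of 2 log2 units.
    """

    s_tumor: int = 150
    s_control: int = 150
    d: int = 200
    planted: Sequence[int] | None = None  # 1-based; None -> draw n_planted at random
    n_planted: int = 10
    effect_model: str = "shift"
    effect_size: float = 4.0
    noise_sd: float = 2.0
    dispersion: float = 0.3
    library_size_range: tuple[float, float] = (5e5, 2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_tumor < 1 or self.s_control < 1 or self.s_tumor + self.s_control < 4:
            raise ValueError("need at least 4 samples with both classes present")
        if self.d < 1:
            raise ValueError("d must be positive")
        if self.planted is not None:
            planted = [int(i) for i in self.planted]
            if len(set(planted)) != len(planted):
                raise ValueError("planted indices must be distinct")
            if any(i < 1 or i > self.d for i in planted):
                raise ValueError(f"planted indices must lie in [1, {self.d}]")
            self.planted = planted
            self.n_planted = len(planted)
        if not 0 <= self.n_planted <= self.d:
            raise ValueError("0 <= n_planted <= d required")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if self.effect_model == "xor" and self.n_planted < 2:
            raise ValueError("xor effect model needs at least 2 planted features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0 or self.dispersion <= 0:
            raise ValueError("noise_sd and dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive with lo <= hi")


@dataclass
class SyntheticDataset:
    """Output of :func:`generate`: counts plus ground truth."""

    counts: np.ndarray  # (s, d) integer counts
    library_sizes: np.ndarray  # (s,) true sampling depths
    labels: np.ndarray  # (s,) 1 = tumor, 0 = control
    sample_ids: list[str] = field(repr=False)
    feature_names: list[str] = field(repr=False)
    truth: dict = field(repr=False)

    def log2_rpm(self) -> np.ndarray:
        """Normalized expression on the scale the selector operates on."""
        return normalize_rpm_log2(self.counts, self.library_sizes)


def _feature_names(d: int) -> list[str]:
    # zero padding keeps lexicographic order equal to numeric order
    width = len(str(d))
    return [f"syn-mir-{i:0{width}d}" for i in range(1, d + 1)]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; deterministic given ``spec.seed``.

    Non-planted features have class-independent distributions.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.s_tumor + spec.s_control
    d = spec.d
    labels = np.concatenate(
        [np.ones(spec.s_tumor, dtype=int), np.zeros(spec.s_control, dtype=int)]
    )
    if spec.planted is not None:
        planted = np.asarray(spec.planted, dtype=int)
    else:
        planted = np.sort(rng.choice(d, size=spec.n_planted, replace=False)) + 1
    p0 = planted - 1  # 0-based columns

    base = rng.uniform(1.0, 12.0, size=d)
    log2_expr = base[None, :] + rng.normal(0.0, spec.noise_sd, size=(s, d))

    tumor = labels == 1
    if spec.effect_model == "shift":
        log2_expr[np.ix_(tumor, p0)] += spec.effect_size
    elif spec.effect_model == "correlated":
        log2_expr[np.ix_(tumor, p0)] += spec.effect_size
        latent = rng.normal(0.0, 1.0, size=s)
        log2_expr[:, p0] += spec.noise_sd * latent[:, None]
    elif spec.effect_model == "xor":
        half = spec.effect_size / 2.0
        for k in range(0, spec.n_planted - 1, 2):
            a, b = p0[k], p0[k + 1]
            sign_a = rng.choice([-1.0, 1.0], size=s)
            # tumor -> product +1, control -> product -1; no marginal shift
            sign_b = np.where(tumor, sign_a, -sign_a)
            log2_expr[:, a] += half * sign_a
            log2_expr[:, b] += half * sign_b

    library_sizes = rng.uniform(*spec.library_size_range, size=s)
    rpm = np.maximum(np.exp2(log2_expr) - 1.0, 0.0)
    rate = rpm * library_sizes[:, None] / 1e6
    over = rng.lognormal(
        mean=-0.5 * spec.dispersion**2, sigma=spec.dispersion, size=(s, d)
    )
    counts = rng.poisson(rate * over).astype(np.int64)

    order = rng.permutation(s)  # interleave classes so samples are not block-sorted
    names = _feature_names(d)
    truth = {
        "planted_indices": planted.tolist(),
        "planted_names": [names[i] for i in p0],
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()
        },
    }
    return SyntheticDataset(
        counts=counts[order],
        library_sizes=library_sizes[order],
        labels=labels[order],
        sample_ids=[f"S{i + 1:04d}" for i in range(s)],
        feature_names=names,
        truth=truth,
    )


class RecoveryResult(NamedTuple):
    precision: float
    recall: float
    empty_panel: bool


def planted_recovery(panel, truth: dict) -> RecoveryResult:
    """Set precision/recall of a reported panel against the planted truth.

    ``panel`` may contain miRNA names or 1-based indices.  An empty panel
    has undefined precision; it is reported as 0 with ``empty_panel=True``.
    """
    names = set(truth["planted_names"])
    indices = set(truth["planted_indices"])
    panel = list(panel)
    if not panel:
        return RecoveryResult(0.0, 0.0, True)
    hits = sum(
        1 for item in panel if (item in names or (isinstance(item, (int, np.integer)) and int(item) in indices))
    )
    precision = hits / len(panel)
    recall = hits / len(names) if names else 0.0
    return RecoveryResult(precision, recall, False)


def write_dataset(ds: SyntheticDataset, matrix_path, labels_path, truth_path=None) -> None:
    """Write the counts matrix and labels in the TSV dialect of :mod:`mirpanel.io`.

    The matrix is written as miRNA rows x sample columns (raw counts; use
    ``mirpanel.io.normalize_rpm_log2`` or the CLI ``--input-type counts``
    path to bring it to log2-RPM).  Optionally writes the truth record as
    JSON.
    """
    import pandas as pd

    frame = pd.DataFrame(ds.counts.T, index=ds.feature_names, columns=ds.sample_ids)
    frame.index.name = "miRNA"
    frame.to_csv(matrix_path, sep="\t")
    with open(labels_path, "w") as fh:
        for sample_id, code in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sample_id}\t{CODE_NAMES[int(code)]}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(ds.truth, fh, indent=2)
            fh.write("\n")
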