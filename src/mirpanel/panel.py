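"""Majority-vote aggregation of DE runs, prefix-accuracy panel sizing,
and the random-selection null model.

Independent DE runs land on slightly different index vectors.  The
finishing step counts how often each miRNA was reported across the runs,
ranks miRNAs by count (ties broken by name), and then scans prefixes of
the ranked list: the shortest prefix maximizing cross-validated accuracy
becomes the final panel.

The null model answers "how many distinct miRNAs would the runs report if
selection were random?".  With ``theta`` runs each drawing ``n`` of ``d``
features uniformly, the expected number reported at least once is
``d * (1 - (1 - n/d)^theta)``; a stable selector reports far fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .metrics import ClassifierConfig, cv_accuracy


@dataclass
class PanelEntry:
    rank: int
    name: str
    count: int


@dataclass
class PanelReport:
    """Ranked vote table, prefix accuracies, and the chosen panel."""

    entries: list[PanelEntry]
    prefix_accuracies: list[float]
    selected_size: int
    panel: list[str]
    k: int  # total distinct miRNAs reported by the runs

    def to_rows(self) -> list[dict]:
        return [
            {
                "rank": e.rank,
                "miRNA": e.name,
                "count": e.count,
                "prefix_accuracy": self.prefix_accuracies[i],
            }
            for i, e in enumerate(self.entries)
        ]


@dataclass
class AnalyticExpectation:
    """Closed-form random-selection expectations."""

    d: int
    n: int
    theta: int
    expected_reported: float
    expected_new_next_run: float


def aggregate_runs(best_vectors: Sequence[Sequence[int]], feature_names) -> list[PanelEntry]:
    """Count how often each feature index was reported across runs.

    Returns one entry per distinct reported feature, sorted by count
    descending with ties broken by miRNA name ascending; counts sum to
    ``theta * n``.
    """
    best_vectors = list(best_vectors)
    if not best_vectors:
        raise ValueError("need at least one run to aggregate")
    counts: dict[str, int] = {}
    for vec in best_vectors:
        for idx in vec:
            name = feature_names[int(idx) - 1]
            counts[name] = counts.get(name, 0) + 1
    ordered = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [PanelEntry(rank=r + 1, name=name, count=c) for r, (name, c) in enumerate(ordered)]


def finish_panel(
    values: np.ndarray,
    y,
    entries: list[PanelEntry],
    clf_config: ClassifierConfig | None = None,
    feature_names: Sequence[str] | None = None,
    scorer: Callable[[np.ndarray], float] | None = None,
) -> PanelReport:
    """Prefix-accuracy scan over the ranked vote table.

    ``prefix_accuracies[i-1]`` is the cross-validated accuracy of the raw
    expression columns of the first ``i`` entries; the selected size is the
    *smallest* prefix attaining the maximum (parsimony tie-break).  The
    panel therefore stands alone as a diagnostic, without the
    dataset-specific component encoder.

    A custom ``scorer(X_prefix) -> accuracy`` may be injected (testing,
    alternative finishing criteria).
    """
    if not entries:
        raise ValueError("empty ranked list")
    values = np.asarray(values, dtype=float)
    if feature_names is None:
        raise ValueError("feature_names are required to map entries to columns")
    name_to_col = {name: i for i, name in enumerate(feature_names)}
    try:
        cols = [name_to_col[e.name] for e in entries]
    except KeyError as err:
        raise ValueError(f"panel entry {err} not present in the expression matrix")
    if scorer is None:
        if clf_config is None:
            clf_config = ClassifierConfig()
        scorer = lambda X: cv_accuracy(X, y, clf_config)  # noqa: E731

    prefix_accuracies = [float(scorer(values[:, cols[:i]])) for i in range(1, len(cols) + 1)]
    best = max(prefix_accuracies)
    selected_size = prefix_accuracies.index(best) + 1  # smallest argmax
    return PanelReport(
        entries=entries,
        prefix_accuracies=prefix_accuracies,
        selected_size=selected_size,
        panel=[e.name for e in entries[:selected_size]],
        k=len(entries),
    )


def expected_reported(d: int, n: int, theta: int) -> AnalyticExpectation:
    """Closed-form expectations under uniform random selection.

    Each run draws ``n`` of ``d`` features without replacement; a feature
    is missed by one run with probability ``1 - n/d`` and by all ``theta``
    independent runs with probability ``(1 - n/d)^theta``.  Hence::

        E[reported at least once] = d * (1 - (1 - n/d)^theta)

    and the expected number of previously unseen features contributed by
    run ``theta + 1`` is ``d * (1 - n/d)^theta * (n / d)``.
    """
    if not 1 <= n <= d:
        raise ValueError("need 1 <= n <= d")
    if theta < 1:
        raise ValueError("theta must be >= 1")
    miss = (1.0 - n / d) ** theta
    return AnalyticExpectation(
        d=d,
        n=n,
        theta=theta,
        expected_reported=d * (1.0 - miss),
        expected_new_next_run=d * miss * (n / d),
    )


def monte_carlo_reported(
    d: int, n: int, theta: int, reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Simulation oracle for :func:`expected_reported`.

    Repeats ``reps`` experiments of ``theta`` uniform n-subsets of
    ``[1, d]`` and returns the mean and standard error of the distinct
    count.
    """
    if not 1 <= n <= d:
        raise ValueError("need 1 <= n <= d")
    if theta < 1 or reps < 1:
        raise ValueError("theta and reps must be >= 1")
    counts = np.empty(reps, dtype=float)
    for r in range(reps):
        seen: set[int] = set()
        for _ in range(theta):
            seen.update(rng.choice(d, size=n, replace=False).tolist())
        counts[r] = len(seen)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, se
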