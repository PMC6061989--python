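"""Scikit-learn estimator wrapping the full panel-selection procedure."""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .de import DEConfig, run_de
from .encoders import KPCAEncoder, PCAEncoder, choose_encoder
from .metrics import ClassifierConfig, FitnessEvaluator, cv_metrics
from .panel import aggregate_runs, finish_panel
from .quality import cluster_quality


def _one_run(values, y, encoder, de_config, clf_config, enhance_mode, seed_seq):
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    fitness = FitnessEvaluator(values, y, encoder, clf_config, enhance_mode=enhance_mode)
    return run_de(values.shape[1], de_config, fitness, rng)


class DEPanelSelector(SelectorMixin, BaseEstimator):
    """Select a miRNA biomarker panel by repeated differential evolution.

    The estimator searches subsets of ``n_features`` expression columns by
    integer-coded differential evolution whose fitness is the k-fold
    cross-validated accuracy of an RBF-kernel SVM on the component-
    analysis-enhanced view of the candidate columns.  ``n_runs``
    independent searches are aggregated by majority voting and the final
    panel is the shortest prefix of the vote ranking that maximizes
    cross-validated accuracy on the raw columns.

    Parameters
    ----------
    n_features : int, default=10
        Length of each candidate index vector (and component count of the
        encoder).
    pop_size, n_generations, mutation_factor, crossover_rate :
        Differential-evolution controls (defaults 50, 50, 1.0, 0.8).
    n_runs : int, default=50
        Independent DE runs feeding the majority vote.
    encoder : {"auto", "pca", "kpca"}, default="auto"
        Component analysis used to build the score matrix; "auto" fits
        both and keeps the one whose score matrix classifies better under
        the same folds (exact ties go to PCA).
    kernel_width : float or None
        RBF coefficient of the kernel PCA; None means 1/d.
    svm_gamma, svm_cost : float, defaults 0.5 and 2.0
        RBF-SVM kernel width and error/margin trade-off.
    cv_folds : int, default=10
        Cross-validation folds for fitness and finishing.
    stratified : bool, default=True
    prefix_features : {"raw", "enhanced"}, default="raw"
        Feature view used in the prefix-accuracy scan.  "raw" makes the
        panel stand alone as a diagnostic; "enhanced" scores prefixes
        through the encoder like the fitness does.
    n_jobs : int or None
        Parallelism across the independent runs (joblib); results do not
        depend on scheduling order.
    random_state : int or None
        Master seed; every source of randomness derives from it.

    Attributes
    ----------
    panel_names_ : list of str
        The selected panel, in vote-rank order.
    panel_indices_ : ndarray
        0-based column indices of the panel.
    ranking_ : list of PanelEntry
        Full vote table (name, count, rank).
    report_ : PanelReport
        Ranking plus prefix accuracies and the chosen size.
    encoder_ : PCAEncoder or KPCAEncoder
        The fitted component encoder shared by all runs.
    best_vectors_ : list of ndarray
        Best 1-based index vector of each run.
    fitness_histories_ : list of list of float
        Non-decreasing best-fitness trajectory of each run.
    metrics_ : MetricsBundle
        Cross-validated metrics of the final panel on the training data.
    quality_ : ClusterQualityReport
        Cosine homogeneity/separation of the panel-restricted profiles.
    """

    def __init__(
        self,
        n_features: int = 10,
        pop_size: int = 50,
        n_generations: int = 50,
        mutation_factor: float = 1.0,
        crossover_rate: float = 0.8,
        n_runs: int = 50,
        encoder: str = "auto",
        kernel_width: float | None = None,
        svm_gamma: float = 0.5,
        svm_cost: float = 2.0,
        cv_folds: int = 10,
        stratified: bool = True,
        enhance_mode: str = "additive",
        prefix_features: str = "raw",
        n_jobs: int | None = None,
        random_state: int | None = None,
    ):
        self.n_features = n_features
        self.pop_size = pop_size
        self.n_generations = n_generations
        self.mutation_factor = mutation_factor
        self.crossover_rate = crossover_rate
        self.n_runs = n_runs
        self.encoder = encoder
        self.kernel_width = kernel_width
        self.svm_gamma = svm_gamma
        self.svm_cost = svm_cost
        self.cv_folds = cv_folds
        self.stratified = stratified
        self.enhance_mode = enhance_mode
        self.prefix_features = prefix_features
        self.n_jobs = n_jobs
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, feature_names=None):
        """Run the full selection procedure on a two-class dataset.

        ``X`` is samples x features in log2-RPM units; ``y`` is binary
        with 1 = tumor.  ``feature_names`` defaults to the columns of a
        DataFrame or generated placeholders.
        """
        if feature_names is None and hasattr(X, "columns"):
            feature_names = [str(c) for c in X.columns]
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2 or not np.isin(classes, [0, 1]).all():
            raise ValueError("y must contain both classes coded 0 (control) / 1 (tumor)")
        s, d = X.shape
        if feature_names is None:
            width = len(str(d))
            feature_names = [f"feature_{i + 1:0{width}d}" for i in range(d)]
        if len(feature_names) != d:
            raise ValueError("feature_names length must match number of columns")
        if self.prefix_features not in ("raw", "enhanced"):
            raise ValueError("prefix_features must be 'raw' or 'enhanced'")
        if self.encoder not in ("auto", "pca", "kpca"):
            raise ValueError("encoder must be 'auto', 'pca' or 'kpca'")

        master = np.random.SeedSequence(self.random_state)
        cv_seed = int(master.generate_state(1)[0] % (2**31))
        clf_config = ClassifierConfig(
            gamma=self.svm_gamma,
            cost=self.svm_cost,
            folds=self.cv_folds,
            stratified=self.stratified,
            seed=cv_seed,
        )
        de_config = DEConfig(
            n=self.n_features,
            pop_size=self.pop_size,
            generations=self.n_generations,
            mutation_factor=self.mutation_factor,
            crossover_rate=self.crossover_rate,
            runs=self.n_runs,
            seed=cv_seed,
        )
        if d < self.n_features:
            raise ValueError(f"n_features={self.n_features} exceeds data columns {d}")

        if self.encoder == "pca":
            enc = PCAEncoder(n_components=self.n_features).fit(X)
            enc.selection_log_ = {"chosen": "pca", "forced": True}
        elif self.encoder == "kpca":
            enc = KPCAEncoder(
                n_components=self.n_features, kernel_width=self.kernel_width
            ).fit(X)
            enc.selection_log_ = {"chosen": "kpca", "forced": True}
        else:
            enc = choose_encoder(
                X, y, self.n_features, clf_config, kernel_width=self.kernel_width
            )

        run_seeds = master.spawn(self.n_runs)
        results = Parallel(n_jobs=self.n_jobs)(
            delayed(_one_run)(X, y, enc, de_config, clf_config, self.enhance_mode, seed)
            for seed in run_seeds
        )

        ranking = aggregate_runs([r.best.indices for r in results], feature_names)
        scorer = None
        if self.prefix_features == "enhanced":
            name_to_col = {n: i for i, n in enumerate(feature_names)}
            cols = [name_to_col[e.name] for e in ranking]

            def scorer(X_prefix):  # combine with the leading score columns
                from .encoders import _zscore_columns
                from .metrics import cv_accuracy

                i = X_prefix.shape[1]
                S = enc.scores_[:, :i]
                if self.enhance_mode == "hadamard":
                    view = X_prefix * S
                elif self.enhance_mode == "gram":
                    view = X_prefix @ S.T
                else:
                    view = _zscore_columns(X_prefix) + _zscore_columns(S)
                return cv_accuracy(view, y, clf_config)

        report = finish_panel(
            X, y, ranking, clf_config=clf_config, feature_names=feature_names,
            scorer=scorer,
        )

        name_to_col = {n: i for i, n in enumerate(feature_names)}
        panel_cols = np.array([name_to_col[n] for n in report.panel], dtype=int)

        self.n_features_in_ = d
        self.feature_names_ = list(feature_names)
        self.encoder_ = enc
        self.selection_log_ = getattr(enc, "selection_log_", {})
        self.clf_config_ = clf_config
        self.de_config_ = de_config
        self.run_results_ = results
        self.best_vectors_ = [r.best.indices.copy() for r in results]
        self.fitness_histories_ = [list(r.history) for r in results]
        self.ranking_ = ranking
        self.report_ = report
        self.prefix_accuracies_ = list(report.prefix_accuracies)
        self.panel_names_ = list(report.panel)
        self.panel_indices_ = panel_cols
        self.metrics_ = cv_metrics(X[:, panel_cols], y, clf_config)
        self.quality_ = cluster_quality(
            X, y, panel_cols, panel_names=self.panel_names_, drop_zero_rows=True
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "panel_indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.panel_indices_] = True
        return mask
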