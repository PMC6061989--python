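# Methods

`mirpanel` selects small panels of miRNAs that jointly discriminate tumor
from control samples in miRNA-seq expression profiles.  Panel discovery is
framed as wrapper feature selection for a two-class classification task:
the quantity being maximized is cross-validated classification accuracy,
not per-feature differential expression, so panels can exploit joint and
non-linear structure that single-feature tests miss.

## The model

Let `E` be the `s x d` matrix of log2 reads-per-million (RPM) expression
values of `d` miRNAs over `s` samples, with binary labels (1 = tumor,
0 = control).  A candidate panel is a vector `v` of `n` distinct 1-based
indices into the lexicographically sorted miRNA table `M`.

**Normalization.** Counts are converted as
`log2(1 + 1e6 * count / library_size)`.  The +1 pseudocount keeps zero
counts at exactly 0 and every value finite; without a stated convention
for zeros this is the standard choice.

**Component encoding.** Once per dataset, the full matrix `E` is projected
onto its first `n` components — linear PCA or RBF-kernel PCA — giving the
`s x n` score matrix `Ê`.  Which of the two is used is decided empirically:
both score matrices are scored by cross-validated SVM accuracy under the
same folds, and the better one wins (exact ties go to PCA, the simpler
model).  Kernel width for KPCA defaults to `1/d`, the scale-free
convention.  Component signs are fixed so each score column's
largest-magnitude entry is positive, making results independent of the
linear-algebra backend.  `Ê` is computed once and reused by every fitness
call; the SVM, not the decomposition, is the per-candidate cost.

**Enhancement.** The fitness never sees the raw selected columns `E(v)`
alone; it sees an *enhanced* matrix `Ê(v)` that combines `E(v)` with `Ê`
entrywise, keeping one row per sample so that cross-validation fold
membership is preserved.  Three combinations are implemented
(`enhance_mode`):

- `additive` (default): `Ê(v) = z(E(v)) + z(Ê)`, both matrices
  column-standardized and summed.  Every entry carries the dataset-wide
  component structure and the candidate's own expression signal with equal
  weight.
- `hadamard`: `Ê(v) = E(v) ∘ Ê`, the literal entrywise product.
- `gram`: `Ê(v) = E(v) · Êᵀ`, `s x s` Gram-like features.

The default is a deliberate design choice.  On synthetic data with a
strongly planted panel we measured what each combination rewards.  Because
log2-RPM values are non-negative, the Hadamard product is a mild positive
per-entry modulation of `Ê`: the fitness of a candidate is then dominated
by `Ê` itself (which already separates the classes well on any dataset
with a strong class signal in its top components), random panels score as
high as the planted panel, and the evolutionary search converges to panels
with *zero* overlap with the planted features — the wrapper degenerates.
The Gram variant destroys the signal outright in our measurements.  The
additive combination is the only shape-preserving variant whose fitness is
demonstrably monotone in panel informativeness (planted panel ~0.97 vs
~0.70–0.85 for disjoint random panels under the default study conditions),
which is the property the whole selection procedure rests on.

**Fitness.** `fitness(v)` is the mean 10-fold cross-validated accuracy of
an RBF-kernel SVM (`gamma = 0.5`, `C = 2.0`) on `Ê(v)`.  Folds are
stratified by default because the intended pooled-control designs are
imbalanced (hundreds of tumors against a shared control pool), where plain
k-fold splits can produce single-class training sets.  SVM inputs are
z-scored on each training fold: a *fixed* kernel width is only meaningful
on comparably scaled features, and log2-RPM columns differ by an order of
magnitude in location and spread (unscaled, the kernel matrix degenerates
to the identity and the SVM predicts the majority class).  Fitness values
are cached per index *set*: the search revisits candidates, and two orders
of the same set are the same panel.

**Differential evolution.** Integer-coded DE over index vectors with
population `I = 50`, generations `phi = 50`, mutation factor `F = 1.0`,
crossover rate `Cr = 0.8` (library defaults; the acceptance experiments
scale some of these down, see below).  Per generation and target slot `j`:
three distinct other slots `a, b, c` are drawn and the trial is
`v[c][k] + floor(F * (v[a][k] - v[b][k]))` per element; out-of-range
elements are wrapped back into `[1, d]` by repeatedly adding/subtracting
`d` (implemented as the equivalent modular wrap, which also covers
excursions larger than `d`); binomial crossover restores each target
element with probability `1 - Cr`; duplicated indices are repaired by
replacing each repeat (left to right) with a uniform draw from the
currently unused indices; greedy selection keeps the trial only on a
strict fitness improvement; elitism then replaces the new population's
worst member with the previous generation's best if strictly better (ties
favor the new population).  Selection plus elitism make the best-fitness
trajectory non-decreasing.  Initial-population fitnesses are evaluated
before the first mutation, since selection needs them.

**Finishing.** The search runs `theta = 50` times independently (each run
on its own PCG64 substream spawned from the master seed, so runs are
reproducible and embarrassingly parallel).  All reported indices are
counted; the vote table is sorted by count descending, ties broken by
miRNA name.  Prefixes of the ranked list are scored by 10-fold CV accuracy
on the **raw** expression columns, and the shortest prefix attaining the
maximum becomes the panel.  Raw columns are used so the panel stands alone
as a diagnostic without the dataset-specific encoder; scoring through the
encoder is available behind `prefix_features="enhanced"`.

**Null model.** If each of `theta` runs drew `n` of `d` features uniformly
at random, a feature would be missed by all runs with probability
`(1 - n/d)^theta`, so the expected number reported at least once is
`E[k] = d (1 - (1 - n/d)^theta)` and one further run would contribute
`d (1 - n/d)^theta (n/d)` previously unseen features on expectation.  At
`d = 1046, n = 10, theta = 50` these are 398.95 and 6.19 — against which
an observed `k` of a few dozen demonstrates that the selection is not a
random process.  `monte_carlo_reported` provides a simulation oracle for
the closed form.

**Evaluation.** Panels are scored by accuracy, F-measure (positive class
= tumor), Matthews correlation coefficient (0 on a zero denominator) and
trapezoidal AUC of the SVM decision values, pooled over out-of-fold
predictions.  The Aggregated Score is
`AS = accuracy + F + (MCC + 1)/2 + AUC`.  The MCC term is affinely mapped
to `[0, 1]` inside the sum only — a raw sum would span `[-1, 4]`, whereas
this one attains exactly the intended `[0, 4]` bound; the raw MCC is
reported unchanged.

**Cluster quality.** Homogeneity of a class is the unweighted mean cosine
similarity over all unordered within-class sample pairs of the
panel-restricted profiles; separation is the mean over all inter-class
pairs (similarities, not distances: good clustering structure means high
homogeneity and *low* separation).  Profiles are used as-is (non-negative
log2-RPM, no centering).  On realistic data the two are close, which is
the empirical argument for classification over clustering.

## Synthetic data

The generator (`mirpanel.simulate`) emulates two-class miRNA-seq count
matrices with a planted discriminative panel so the whole pipeline is
testable without external data.  Per feature a baseline log2-RPM mean is
drawn from U[1, 12]; per sample, Gaussian biological noise
(`noise_sd`, default 2.0 log2 units — miRNA expression is highly variable
across samples) is added; values map back to RPM, are scaled by a library
size drawn from U[5e5, 2e6], multiplied by a lognormal overdispersion
factor (`dispersion`, default 0.3) and Poisson-sampled.  Effect models:

- `shift`: planted features gain `effect_size` (default 4) log2 units in
  tumors;
- `correlated`: the shift plus a shared per-sample latent factor over the
  planted features;
- `xor`: consecutive pairs of planted features deviate ±`effect_size`/2
  with the *sign product* determined by the class — no marginal shift, so
  per-feature tests (Wilcoxon, t) are blind while a non-linear classifier
  on the pair is not.

Default cohort: 150 tumor + 150 control samples over 200 features with a
10-feature planted panel.  What the generator does **not** emulate: batch
effects, tissue mixtures, miRNA–target regulatory structure, and the long
right tail of real library-size distributions.  Passing tests on these
data therefore demonstrate the machinery (search, voting, finishing,
metrics), not clinical validity on real cohorts.

## Problem sizes in the test suite

The acceptance experiments scale the search down to desk scale; these are
the package's own study conditions:

- *Planted recovery* (shift): default generator conditions, `theta = 10`
  runs of `I = 20, phi = 20`, three master seeds, median panel recall
  against the planted truth.  At `phi = 20` integer DE is far from
  exhausting `C(200, 10)`; single runs recover only part of the panel and
  it is the majority vote that concentrates the planted features at the
  top of the ranking — which is precisely the behavior the finishing step
  exists to provide.
- *Non-linear advantage* (xor): 100 features, one planted xor pair
  (effect 6, noise 1.5), 2-slot candidates, `theta = 5` runs of
  `I = 20, phi = 25`; panel accuracy compared against the best single
  feature.  The design keeps the component scores informative but
  *unsaturated*: if the score matrix alone classifies perfectly (as
  happens at small `d` with strong pairs), any candidate containing half
  the pair reaches maximal fitness and the search cannot identify the
  partner.
- *Stability*: 50 features, 5 planted shift features (effect 4),
  5-slot candidates, `theta = 10` runs of `I = 50, phi = 60`; the
  distinct-feature count `k` is compared with the random-selection
  expectation.  The budget was chosen with a surrogate-fitness study of
  the optimizer (a monotone overlap-counting fitness, no SVM): at these
  sizes the optimizer converges to identical vectors on every run, so any
  residual run-to-run dispersion measured by the test isolates the
  ruggedness of the cross-validated fitness landscape itself rather than
  optimizer shortfall.

## Numerical choices and edge cases

- Feature indices are 1-based in every user-facing surface (candidate
  vectors, truth records) and 0-based internally; the conversion lives in
  the I/O and enhancement boundaries only.
- Vote ties are broken by miRNA name; equal-accuracy prefixes resolve to
  the smaller panel (parsimony).
- PCA refuses `n` above the rank of the centered data, naming the
  achievable rank; KPCA refuses degenerate kernels (e.g. all-equal
  samples).
- Cosine quality metrics reject zero-norm profiles; the estimator drops
  such samples (with a logged count) when reporting panel quality, since a
  small panel can leave a sample all-zero.
- All randomness flows through `numpy.random.Generator`s seeded from one
  master `SeedSequence`; equal seeds give byte-identical artifacts, and
  parallel execution of the runs cannot change results.

## Known limitations

- The enhancement combines full-dataset statistics (`Ê`, column z-scores)
  computed before cross-validation, as the method's design prescribes
  (one encoder per dataset); fitness values are therefore slightly
  optimistic as estimates of out-of-sample accuracy.  The finishing
  accuracies on raw columns share the usual selection-bias caveat of
  wrapper methods.
- Integer-coded DE treats index arithmetic as meaningful although indices
  are nominal labels; mutation is effectively a randomized jump operator,
  and convergence within a run relies on selection pressure plus
  crossover.  Budgets well below `I * phi = 2500` evaluations leave
  single runs partial; the majority vote is what makes the final panel
  reliable.
- The cross-validated accuracy landscape over candidate sets is rugged:
  sets of equal true informativeness differ by a few misclassified
  samples, and spuriously correlated noise features can tie with or
  slightly exceed a planted optimum.  Independent runs therefore disperse
  over these near-ties, and the run-to-run feature overlap achievable at
  desk scale is well below what would be needed to push the
  distinct-feature count `k` under a quarter of the random-selection
  expectation with only 10 runs; the stability test documents the
  measured gap.  The qualitative contrast — `k` far below the random
  expectation — does reproduce.
- Multi-class designs, survival endpoints and batch correction are out of
  scope.
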