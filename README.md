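# mirpanel

Discovery of small miRNA biomarker panels from two-class (tumor vs
control) miRNA-seq expression matrices, for bioinformaticians who want a
wrapper alternative to differential-expression ranking.  Instead of
testing miRNAs one at a time, `mirpanel` searches for the *set* of miRNAs
that jointly maximizes cross-validated classification accuracy, so panels
can exploit joint and non-linear expression structure that per-feature
statistics miss.

## Method

Given the `s x d` log2-RPM expression matrix `E` with binary labels, a
candidate panel is a vector `v` of `n` distinct indices into the sorted
miRNA table.  The pipeline:

1. **Component encoding** — `E` is projected once onto its first `n`
   components (PCA or RBF-kernel PCA, chosen empirically by classifying
   the score matrix `Ê`), and each candidate's columns `E(v)` are
   *enhanced* by combining them entrywise with `Ê`, preserving one row
   per sample.
2. **Differential evolution** — integer-coded DE (population `I = 50`,
   generations `φ = 50`, mutation `F = 1`, crossover `Cr = 0.8`) evolves
   index vectors; the fitness of `v` is the mean 10-fold cross-validated
   accuracy of an RBF-SVM (`γ = 0.5`, `C = 2`) on the enhanced matrix
   `Ê(v)`.  Greedy selection plus elitism make the best fitness
   non-decreasing.
3. **Majority-vote finishing** — `θ = 50` independent runs are
   aggregated: miRNAs are ranked by how often runs reported them, and the
   shortest prefix of the ranking maximizing CV accuracy on the raw
   columns becomes the final panel.
4. **Null model** — under random selection the expected number of
   distinct miRNAs over `θ` runs is `d(1 − (1 − n/d)^θ)`
   (≈ 399 for `d = 1046, n = 10, θ = 50`, versus the handful a stable
   selector reports), quantifying that the panel is not a product of
   chance.

Panels are scored by accuracy, F-measure, MCC and AUC, summarized as the
Aggregated Score `AS = acc + F + (MCC+1)/2 + AUC ∈ [0, 4]`, plus cosine
homogeneity/separation diagnostics.  A synthetic-data module generates
overdispersed two-class count matrices with planted mean-shift,
correlated, or non-linear (sign-product) panels so the whole pipeline is
testable without external data.  See `docs/methods.md` for assumptions,
parameter rationale and limitations.

## Worked example

Simulate a cohort (60 tumor + 60 control samples, 60 miRNAs, 5 planted
with a 5 log2-unit shift), then select a panel with a scaled-down search:

```
$ mirpanel simulate --out-dir data --s-tumor 60 --s-control 60 -d 60 \
      --n-planted 5 --effect-size 5 --noise-sd 1.5 --seed 21
wrote data/matrix.tsv (120 samples x 60 miRNAs)

$ echo '{"pop_size": 12, "n_generations": 10}' > cfg.json
$ mirpanel run --matrix data/matrix.tsv --labels data/labels.tsv \
      --out-dir results --seed 11 --runs 5 -n 5 --config cfg.json
panel (2 of 16 reported): syn-mir-17, syn-mir-45
accuracy=0.9833 AS=3.9481
```

The 5 runs reported 16 distinct miRNAs; majority voting put `syn-mir-17`
and `syn-mir-45` — both members of the planted panel (`data/truth.json`)
— at the top, and the prefix scan kept the smallest prefix reaching the
accuracy maximum (0.9833, i.e. 2 of 120 cross-validated samples
misclassified; AS 3.95 of 4).  `results/panel.tsv` holds the full vote
table with per-prefix accuracies, `manifest.json` the seeds, per-run best
vectors and metrics needed to reproduce the run bit-for-bit.

The analytic null model for the full-scale configuration:

```
$ mirpanel expect -d 1046 -n 10 --theta 50
expected miRNAs reported at least once after 50 random runs: 398.95
expected new miRNAs from one additional run: 6.19
```

The library surface is sklearn-style (`DEPanelSelector` with
`fit`/`transform`/`get_support`), so the selector composes with sklearn
pipelines:

```python
from mirpanel import DEPanelSelector, SyntheticSpec, generate

ds = generate(SyntheticSpec(seed=1))
sel = DEPanelSelector(n_runs=10, pop_size=20, n_generations=20, random_state=0)
sel.fit(ds.log2_rpm(), ds.labels, feature_names=ds.feature_names)
print(sel.panel_names_, sel.metrics_.aggregated_score)
```

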