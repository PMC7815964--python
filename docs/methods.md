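# Methods

This note documents the statistical procedures the package implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic benchmarks do and do not establish.

## Data model

A dataset is a samples × features numeric grid with an optional missing
marker per cell, a binary outcome defined for every sample, and optional
exploration columns excluded from the predictors.  The positive class must
be named explicitly: sensitivity, precision and the PR curve all change
meaning if it is guessed.  Non-numeric predictor columns are rejected
rather than auto-encoded — silent encoding changes model semantics.
Missing markers default to {"", "NA", "NaN", "null"}, case-insensitive.
Column order is meaningful and preserved by every operation; all
tie-breaking rules below are defined in terms of it.  Files are written
with `%.17g` floats and parsed with exact float conversion, so a
write→read round trip is bit-identical.

## Resample generation (missingness signatures)

Block missingness — an assay run on only part of a cohort — produces a
small number of distinct *missingness signatures*: the observed-feature
sets of the samples.  The family of analyzable complete submatrices is the
intersection closure of those signatures (every distinct non-empty
intersection over subsets).  Each closed set, paired with the maximal set
of samples observing all of it, is a *resample*.

The closure is computed by iterated pairwise intersection to a fixed point
with hash-based deduplication.  This is exact: intersection is associative,
so any k-way intersection is reachable through k−1 pairwise steps, and a
fixed point adds nothing.  The worst case is exponential, so the closure is
capped (default 10,000 sets) with an explicit resource error suggesting
coarser assay blocks.  Default size minima are `min_samples=15`,
`min_features=2`; below ~15 samples, 10-fold stratified CV folds
degenerate.  A second filter drops resamples whose holdout would be too
small: keep when `floor(n_samples × test_fraction) ≥ min_test_samples`
(e.g. with a 25% holdout and a minimum of 10, exactly resamples with
n ≥ 40 survive).  Resample identifiers are content hashes (SHA-1 of the
sorted, newline-joined feature names), so outputs are stable across runs,
platforms and input orderings; canonical output order is descending
n_samples, then descending n_features, then id.

## Preprocessing

All statistics are learned from the training split only and stored in a
plan; applying the plan anywhere (including the holdout) uses only the
stored statistics.  Step order is fixed: median imputation →
near-zero-variance drop → correlated-feature drop → centering → scaling.
Features entirely missing in the training split are dropped with a
warning; zero-variance survivors under `scale` get mean-only centering.
Correlated-feature removal is greedy: while any off-diagonal |r| exceeds
the threshold (default 0.9), drop the member of the worst pair with the
larger mean absolute correlation to everything else; equal means drop the
later column.  Defaults (impute+center+scale) are deliberately
conservative.

## Modeling harness

Partitioning is stratified: per class, `round(count × train_fraction)`
samples go to training (clamped so both classes appear in both splits),
default fraction 0.75.  Tuning is grid search scored by repeated
stratified k-fold CV (10 × 3 by default; the fold count drops to the
minority-class count when needed so every fold keeps both classes).
Preprocessing is refit inside each fold on the fold's training part —
fold-level leakage would otherwise inflate CV estimates.  The winning grid
point maximizes the selection metric (AUROC by default; ties go to the
first grid point in declared order), the final model is refit on the full
training split, and the holdout is scored once.  The "validation" role is
played by the CV folds; no third physical split is made — with the cohort
sizes this package targets, a third split would starve both training and
validation.

For unbalanced data the harness warns when minority prevalence < 0.25 and
suggests ranking by prAUC, which degrades gracefully where AUROC saturates.
`rank_models` sorts descending (ascending for LogLoss, where smaller is
better), breaks ties by the same metric on the other split, then by
algorithm id; undefined metrics sort last.

### Algorithm registry

Eleven representative families, each a native scikit-learn estimator with
a small default grid (≤ 5 candidates per axis):

| id | estimator | tuned axis |
|----|-----------|------------|
| sda | shrinkage LDA (lsqr) | shrinkage {auto, 0.1, 0.5} |
| hdda | regularized QDA | reg_param {0.1, 0.5, 0.9} |
| svmLinear | linear SVM, Platt-calibrated | C {0.25, 1, 4} |
| pcaNNet | PCA → MLP | hidden {3, 5} |
| logitBoost | AdaBoost on depth-1 stumps | n_estimators {25, 50} |
| naiveBayes | Gaussian NB | var_smoothing {1e-9, 1e-6} |
| rf | random forest (100 trees) | max_features {sqrt, 0.5} |
| knn | k-nearest neighbours | k {5, 7, 9} |
| treebag | bagged decision trees | n_estimators {25, 50} |
| gbm | gradient boosting | max_depth {2, 3} |
| nnet | 1-hidden-layer MLP | hidden {4, 8} |

All probabilistic scores are positive-class probabilities; hard labels for
the confusion metrics are taken at 0.5.

### Seeds and determinism

A master seed derives every sub-seed by SHA-256 hashing of
(resample id, algorithm id, purpose), truncated below 2³¹.  Consequences:
adding an algorithm to a run does not perturb any other algorithm's
results; all algorithms on one resample share the same train/holdout
split (so their metrics are comparable); and serial and parallel execution
produce bit-identical outputs because no task reads a shared random
stream.

### Persistence

Models serialize with an embedded format name/version and a prediction
fingerprint (a few raw rows plus their expected scores).  Loading verifies
format, version and fingerprint, so a corrupted or environment-shifted
artifact raises an integrity error instead of silently mis-scoring.

## Metric layer

Written in-package so tie and degenerate handling are pinned down:

* **AUROC** — concordance form via mid-ranks: P(score(+) > score(−)) with
  ties credited ½; equivalent to the trapezoid rule on the tie-grouped ROC
  curve.  Undefined (`None`) when a class is absent.
* **prAUC** — average-precision summation Σ (R_k − R_{k−1}) P_k over
  descending thresholds, tie groups evaluated jointly.  Trapezoidal PR
  interpolation is optimistically biased and deliberately not used; a
  constant classifier yields exactly the prevalence.  Implementations that
  interpolate linearly will disagree slightly by construction.
* **LogLoss** — −mean(y ln p + (1−y) ln(1−p)) with p clamped to
  [1e-15, 1−1e-15].
* Confusion metrics use the standard 2×2 definitions; precision is
  undefined with no positive predictions, specificity with no true
  negatives.  Undefined is always an explicit marker, never a silent 0, so
  rankings can order it last deterministically.

## Variable importance

`auto` prefers the model's native importance — absolute coefficients for
linear/discriminant models (inputs are standardized by the plan, so
coefficients are comparable) and total split gain for tree ensembles —
falling back to permutation importance: the mean drop in training AUROC
over n shuffles (default 25) of one feature's column.  AUROC rather than
accuracy makes the permutation metric robust to class imbalance.  Each
feature's shuffle stream is derived from its name, so results are
independent of column order.  Raw values are shifted to min 0 and scaled
so the maximum is 100 (the common display convention); raw values are
retained because min-max scaling destroys cross-model comparability.  When
every raw importance is numerically zero the table is flagged "no signal"
rather than scaled into noise.  Aggregation reports mean score, model
count, top-k membership and best rank per feature; features dropped by a
model's preprocessing simply contribute no entry for that model.

## Exploration

**Correlation** is pairwise-complete (each pair uses the rows where both
features are observed, with a minimum pair count, default 3); constant
features get undefined correlations and are flagged.  The display
threshold for "highly correlated" pairs defaults to 0.75, independent of
the preprocessing drop threshold.

**Clustering** is agglomerative on euclidean or 1−correlation distances
with average (default), complete or ward-like linkage, over samples or
features; the grid must be complete (impute first).  Ties resolve to the
smaller leaf index and heatmap leaf order is the tree's natural order —
no optimal-leaf reordering, so dendrograms are reproducible.

**SAM** implements the two-class unpaired moderated difference
d_i = (mean₂ − mean₁)/(s_i + s₀), with s_i the pooled two-sample standard
error and the fudge factor s₀ chosen as the percentile of {s_i} (grid
0, 5, …, 100) minimizing the coefficient of variation of the
median-absolute-deviation of d across s-windows, falling back to the
median of s when the search degenerates.  The null comes from label
permutations: full enumeration when at most `n_permutations` distinct
reassignments exist, seeded sampling of distinct reassignments otherwise.
Sorted observed d is compared with the permutation-expected order
statistics d̄; a feature is called at threshold delta when its
quantile-quantile displacement |d_(i) − d̄_(i)| exceeds delta, and the
identical rule applied to each permutation row gives the false-call
counts, with FDR = median false calls ÷ observed calls (capped at 1).
Because observed data and permutations are treated symmetrically, a
pure-noise grid estimates FDR ≈ 1 — the estimator does not flatter noise —
while strongly shifted features separate at low estimated FDR.  Called
sets shrink monotonically as delta grows, and fixed seeds make the whole
table bit-reproducible.

## Synthetic archetypes

The generator draws Gaussian class-conditional features with equal unit
variance; informative features differ between classes by `effect_size`
standard deviations.  This keeps separability analytic — a single feature
at effect e has theoretical AUROC Φ(e/√2), so tests can pin expectations —
at the cost of realism: no heavy tails, no feature correlation unless
injected, no nonlinear structure.  Passing benchmarks therefore
demonstrates the *pipeline machinery* (no leakage, correct enumeration,
calibrated nulls, recoverable signal), not performance on any real cohort.
Block missingness blanks whole feature blocks for seeded random sample
subsets, emulating assays run on part of a cohort; preset block sizes and
fractions are chosen so expected missing-cell rates hit the archetype
targets (e.g. 2 blocks × 8 of 30 features × 15% of samples = 8%).
Ground truth (informative feature names) lives in a separate JSON sidecar
so generated CSVs are schema-identical to real inputs, and recovery tests
read truth only from the sidecar.

Preset shapes: `clinical` 534×14 complete; `cytometry` 195×30, ~8%
missing in two assay blocks; `serology` 72×20, ~21% missing, 26:46
outcome; `microbiome` 184×500 (p ≫ n); `expression` 424 samples at
374:50 — the imbalance regime where prAUC-based ranking matters.

## Benchmark problem sizes

The packaged end-to-end checks run at: 200 random missingness patterns
(≤ 12 signatures) for the closure oracle; 500 random vectors (n ≤ 100)
for the metric oracles; 20 seeded runs each for null calibration (200×50,
permuted labels), signal recovery (200×100, 5 informative at effect 1.5)
and SAM truth recovery (20×500 grids, 100 permutations); all with 10×3
CV.  These sizes give stable pass/fail behaviour at a few minutes of
single-CPU runtime; larger replicas only narrow Monte-Carlo noise.

## Known limitations

* Binary outcomes only; no regression, multiclass, ensembling or stacking.
* The closure cap makes pathological missingness patterns (many unrelated
  signatures) fail fast rather than enumerate exponentially.
* Native importances for calibrated SVM models are not exposed (the
  calibration wrapper hides the coefficients); the permutation route is
  used there.
* SAM is the unpaired two-class variant; no paired or multiclass forms.
* The FDR estimate is the permutation-median convention; implementations
  using tail-threshold cutoffs or π₀ correction will differ at small call
  counts.
* Archetype generators match shapes, prevalences and missingness rates of
  real cohorts, not their marginal distributions or correlation spectra.
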