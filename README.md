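# bioautoml

Automated machine-learning discovery for binary-outcome biomedical feature
tables — clinical panels, flow-cytometry immunophenotypes, serology,
microbiome abundances, expression matrices.  These tables share three
awkward traits: whole assay blocks are missing for subsets of donors,
classes are often strongly unbalanced (e.g. 374 tumor vs 50 normal
samples), and the feature count can exceed the sample count.  `bioautoml`
runs the full path from a delimited table to ranked, honestly evaluated
models, for researchers who want a standardized, leakage-safe pipeline
rather than a pile of ad-hoc scripts.

## What it does

1. **Resample generation for missing data.**  Each sample's *missingness
   signature* is the set of features observed for it.  The intersection
   closure of those signatures — every distinct non-empty intersection —
   defines the family of *resamples*: a feature set together with the
   maximal set of samples observing all of it.  Each resample extracts to a
   complete submatrix, so every learner sees fully observed data and no
   imputation is forced on block-missing assays.
2. **Leakage-safe modeling.**  A stratified train/holdout partition
   (default 75/25) is made once per resample.  Hyperparameters are tuned by
   repeated stratified cross-validation (10 folds x 3 repeats) inside the
   training split, with preprocessing (median imputation, centering,
   scaling, near-zero-variance and correlated-feature removal) refit inside
   every fold.  The holdout is scored exactly once, after tuning.
   A registry of 11 classification algorithms (shrinkage and
   high-dimensional discriminant analysis, linear SVM, PCA+neural net,
   boosted logistic stumps, naive Bayes, random forest, k-NN, bagged trees,
   gradient boosting, single-hidden-layer net) runs on the same splits so
   models are directly comparable.
3. **A self-contained metric layer.**  Accuracy, sensitivity, specificity,
   precision, recall, F1, AUROC, prAUC and LogLoss with explicit tie and
   degenerate-case handling.  AUROC is the concordance probability
   P(score(+) > score(−)) with ties credited 1/2; prAUC is the
   average-precision summation Σ (R_k − R_{k−1}) · P_k.  Under class
   imbalance prAUC is the recommended ranking metric, and the harness warns
   when minority prevalence drops below 0.25.
4. **Feature selection.**  Per-model variable importance (native
   coefficients/split gains where the family defines them, AUROC-drop
   permutation importance otherwise), min-max scaled to 0–100 and
   aggregated across models.
5. **Exploration.**  Pairwise-complete correlation matrices, hierarchical
   clustering with SVG dendrograms (useful for spotting batch effects), and
   two-class SAM: the moderated difference d_i = (mean₂ − mean₁)/(s_i + s₀)
   with a permutation-calibrated false-discovery-rate table.
6. **Synthetic archetypes.**  Seeded generators that emulate the shapes
   above (`clinical` 534×14, `cytometry` 195×30 with ~8% block-missing
   cells, `serology` 72×20 with ~21%, `microbiome` 184×500, `expression`
   424 samples at 374:50), so the whole pipeline is testable without any
   downloads.

## Worked example

```python
from bioautoml import (ExperimentConfig, MulsetConfig, CVPlan, run_experiment,
                       rank_models, aggregate_importance,
                       archetype_spec, make_classification_data)

ds, truth = make_classification_data(archetype_spec("cytometry", seed=5))
cfg = ExperimentConfig(
    algorithms=["sda", "naiveBayes", "svmLinear"],
    cv=CVPlan(n_folds=10, n_repeats=3),
    mulset=MulsetConfig(enabled=True, min_samples=30, min_test_samples=10),
    seed=1, compute_importance=True,
)
results = run_experiment(ds, cfg)
for r in rank_models(results, metric="auroc", split="cv")[:3]:
    print(r.algorithm_id, r.resample_id[:8], r.cv_metrics.auroc,
          r.holdout_metrics.auroc)
print(aggregate_importance(results).head(6))
```

prints (abridged):

```
informative: ['F01', 'F14', 'F16', 'F17', 'F21', 'F23']
12 models trained
naiveBayes resample=ddf40bee n=106+36 cv AUROC=0.998 holdout AUROC=0.987 holdout prAUC=0.992
sda        resample=ddf40bee n=106+36 cv AUROC=0.997 holdout AUROC=0.990 holdout prAUC=0.994
sda        resample=f96ef686 n=125+41 cv AUROC=0.990 holdout AUROC=0.943 holdout prAUC=0.962
feature  mean_score  n_models  top_k_count  best_rank
    F21   81.038387         6            6          1
    F17   78.464108         6            6          1
    F16   74.394701         6            6          1
    F01   71.168648        12          12          1
```

Reading: the block-missing 195×30 table yielded 4 resamples; 3 algorithms
× 4 resamples = 12 models, all sharing each resample's train/holdout split.
The best models separate the classes almost perfectly (cross-validated
AUROC ≈ 1 confirmed on the untouched holdout), and the aggregate importance
table ranks the planted informative features at the top — the truth sidecar
is only read afterwards to check that.

The same run works from the shell:

```bash
bioautoml simulate --preset cytometry --out demo/cyto.csv --seed 5
bioautoml resamples demo/cyto.csv --outcome outcome --positive-class case \
    --id-col sample_id --out-dir demo/resamples
bioautoml train --config demo/train.yaml --out-dir demo/run
bioautoml explore demo/cyto.csv --outcome outcome --positive-class case \
    --id-col sample_id --out-dir demo/explore
```

`train` writes tidy TSVs (`metrics.tsv`: one row per model × metric ×
split; `fold_metrics.tsv` for box plots), `explore` writes correlation and
SAM tables plus SVG figures.

## Layout

```
src/bioautoml/
  dataset_io.py   # schema-aware CSV/TSV reading/writing, complete-case filter
  mulset.py       # signatures, intersection closure, resample filtering
  preprocess.py   # train-split-only preprocessing plans
  modeling.py     # partition, CV tuning, registry, ranking, persistence
  metrics.py      # AUROC / prAUC / LogLoss / confusion metrics
  features.py     # variable importance + cross-model aggregation
  explore.py      # correlation, clustering, SAM
  synth.py        # seeded archetype generators
  cli.py, viz.py  # command-line front end, SVG rendering
docs/methods.md   # models, parameters, numerical choices, limitations
```
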