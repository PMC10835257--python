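# cascadenode

Radiomic multiclass prediction of the head-and-neck primary tumor site from
lymph-node feature tables, with a direct four-class pipeline and a two-step
cascade built around a transitory merged class.

## Scientific problem

In carcinoma of unknown primary (CUP), a metastasis is found in a cervical
lymph node without an identified primary tumor. Radiomic features extracted
from the metastatic node on MRI carry a signature of the primary site, so the
task becomes a four-class prediction problem over the sites hypopharynx/larynx
(HL), oral cavity (OC), oropharynx (OPC) and nasopharynx (NPC). Two practical
difficulties shape the protocol: the feature space is large and redundant
(hundreds of shape, first-order, and GLCM/GLRLM texture features on original
and wavelet-filtered images), and the class distribution is heavily imbalanced
(the typical cohort splits roughly 38/63/162/137).

`cascadenode` implements the full evaluation protocol around this problem:

- **Synthetic cohorts** — a generator that emulates the study conditions:
  catalog-named radiomic features (536 per image type), planted class-mean
  shifts, correlated feature blocks, perturbed-reading replicates with a
  target intraclass correlation, class-dependent clinical covariates (sex,
  age, HPV status), and an optional hierarchical "Fusion-separable" structure
  where the HL-vs-OC distinction is finer than the coarse grouping.
- **Preprocessing** — feature-stability filtering by ICC(2,1) (two-way
  random-effects, absolute agreement, single rater; threshold 0.75 on the
  estimate or its lower confidence bound), greedy redundancy pruning by
  absolute Spearman correlation (thresholds 0.75/0.80/0.85), and z-scoring
  fitted on training rows only.
- **Partitioning and balancing** — 30 seeded stratified held-out-fold splits
  (one fold of 10 per repetition); every training fold is rebalanced to the
  reference-class count by random undersampling and SMOTE oversampling. Test
  folds are never resampled.
- **Feature selection** — five selectors (SFS, SBS, SFFS, diagonal-weight
  NCA, and MRMR with the mutual-information-difference scheme), run once per
  training fold; selection frequencies across the 30 repetitions form the
  nested final sets F1 ⊇ F15 ⊇ F20 ⊇ F25 ⊇ F30.
- **Pipelines** — P1 classifies the four sites directly; P2 first merges
  HL and OC into a transitory *Fusion* class, solves the better-balanced
  three-class problem, elects one frequency threshold (median balanced
  accuracy, with a one-percentage-point general-accuracy tie-break and a
  fewest-predictors final tie-break), then reclassifies the Fusion-routed
  test samples with a four-class model. Five model families are supported:
  neural network, decision tree, naive Bayes, bagged trees, and SVM with a
  linear or quadratic kernel.
- **Metrics** — per-repetition balanced accuracy (mean of per-class
  recalls), general accuracy, and training accuracy, summarized as the
  median and [Q1; Q3] across repetitions; per-class accuracies come from the
  element-wise sum of the repetition confusion matrices.
- **Explainability** — per-patient Shapley values (exact enumeration up to
  12 features, seeded permutation sampling beyond) pooled per class into the
  weighted Shapley value
  `wSV_i = (n_i⁺/n)·ΣSV_i⁺ + (n_i⁻/n)·ΣSV_i⁻`, where the tallies and sums
  run over correctly predicted patients with positive/negative contributions
  of feature *i*.

Every pipeline run carries an instrumented leakage audit verifying that no
fitted statistic (z-score parameters, selector, resampler, model) ever saw a
test row.

## Worked example

```python
import cascadenode as cn

# a desk-scale cohort with the study's class imbalance (38/63/162/137)
spec = cn.CohortSpec(seed=7, n_features=60, n_informative=15,
                     n_redundant_blocks=4, block_size=5)
table = cn.generate_cohort(spec)

# redundancy pruning at |rho| > 0.85
prune = cn.correlation_prune(table, 0.85)
table = table.select_features(prune.kept_features)

# two-step cascade with MRMR selection and a linear SVM
config = cn.PipelineConfig(pipeline="P2", selector="mrmr", mrmr_m=15,
                           frequency_threshold="F20",
                           model=cn.ModelSpec(kind="SVM", svm_kernel="linear"),
                           n_repetitions=10)
res = cn.run_p2(config, table)
print(res.elected, len(res.feature_set))
print(res.overall.median("balanced_acc"))
print(res.overall.per_class_acc.round(3))
```

Output of this exact script:

```
features after redundancy pruning: 44
elected frequency threshold: F1 with 15 features
S1  median balanced accuracy: 0.930
S2  median balanced accuracy: 0.906
overall median balanced accuracy: 0.929
overall per-class accuracy:
HL     0.812
OC     0.949
OPC    0.962
NPC    0.915
```

The same protocol is available on the command line:

```bash
cascadenode simulate --seed 7 -o cohort.csv --replicate-out replicate.csv
cascadenode preprocess --in cohort.csv --replicate replicate.csv \
    --icc 0.75 --rho 0.85 -o pre.csv
cascadenode run --pipeline P2 --in pre.csv -o results/
cascadenode explain --in pre.csv -o explained/
```

Each `run` directory contains `results.json` (lossless), per-stage prediction
tables, a rendered report (`report.csv`/`report.txt`, percentages to one
decimal), summed confusion matrices, and a `manifest.json` with the config
snapshot, seeds, and input hashes from which the run can be re-executed.

## Reproduction

The structural targets of the protocol are recomputed from scratch by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes one JSON entry per target (value and sample size). The script
takes a few seconds and uses no stored data.

## Layout

```
src/cascadenode/   library (catalog, cohort, preprocessing, partitioning,
                   selection, models, pipelines, explain, config, report, cli)
tests/             unit, property, and acceptance tests
scripts/           acceptance recomputation
docs/methods.md    methods note: design decisions and known limitations
```
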