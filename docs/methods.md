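# Methods note

This note records the modeled procedure, the parameter choices with their
rationale, what the synthetic-cohort generator does and does not emulate, and
the numerical conventions that matter for reproducing results.

## Problem and protocol

The package models multiclass prediction of the head-and-neck primary tumor
site (HL, OC, OPC, NPC) from per-patient radiomic feature tables extracted
from lymph-node MRI. Two pipelines are compared under one shared evaluation
protocol:

- **P1** — direct four-class classification.
- **P2** — a cascade: step 1 merges HL and OC into a transitory *Fusion*
  class and solves the three-class problem; step 2 reclassifies exactly the
  test samples step 1 routed to Fusion with a four-class model; the overall
  prediction keeps step 1's OPC/NPC answers and substitutes step 2's answer
  on Fusion routes. The cascade's premise is that the coarse three-class
  structure is easier and better balanced (Fusion has 101 of 400 patients in
  the reference cohort), so the minority classes get a second, focused look.

Per repetition (30 seeded stratified splits, one held-out fold of ten),
the training fold is z-scored, one feature subset is selected, the fold is
rebalanced, a model is trained, and the untouched test fold is scored.
Feature subsets are frequency-aggregated across repetitions into the nested
final sets F1/F15/F20/F25/F30 (minimum selection counts out of 30).

## Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| ICC threshold | 0.75 | standard "good reliability" cut for ICC(2,1); the filter can alternatively threshold the lower 95% confidence bound |
| Spearman prune thresholds | 0.75 / 0.80 / 0.85 | the three redundancy levels of the configuration grid; 0.85 is the single-run default |
| Repetitions / folds | 30 / 10 | the protocol's stated partitioning scheme; repetition seeds default to 1..30 |
| Balancing reference | OC (P1, P2 step 2); Fusion (P2 step 1) | OC's training count (~57) is the protocol's common target; step 1 has no OC class, and Fusion — its smallest class — is the analogous reference |
| SMOTE neighbors | k = 5 | conventional SMOTE setting; k is clipped (with a warning) when a minority class is smaller than k+1 |
| Wrapper criterion | linear-SVM 5-fold CV error, improvement tolerance 1e-6 | deterministic, seeded; the tolerance avoids step decisions on floating-point noise |
| NCA | λ = 1/n, weight cut 0.02 × max weight | the customary regularization for the stochastic-NN leave-one-out objective; the relative cut keeps features whose weight is not numerically negligible |
| MRMR | MID scheme, 8 equal-frequency bins, m = 10 | mutual-information difference on discretized features; m bounds the ranking length |
| Election tolerance | 0.01 on the [0, 1] accuracy scale | "within one percentage point" — candidates this close compete on general accuracy, then on fewest predictors |
| Model families | NN (25 hidden units), DT (Gini), NB (Gaussian), BT (100 trees), SVM (linear or degree-2 polynomial, C = 1, one-vs-rest) | the five families of the comparison grid |
| Shapley | exact ≤ 12 features, else seeded permutation sampling | exact enumeration is 2^d; the sampler satisfies efficiency in expectation and warns when the Monte-Carlo standard error is large |

In the test suite the MRMR budget is raised to `mrmr_m = 15` on cohorts with
15 planted informative features, so that selection capacity is not the
binding constraint when the tests probe signal recovery; this is a test-size
choice, not a change to the library default.

## The synthetic-cohort generator

Real cohorts of this kind are private; the generator reproduces the *study
conditions* rather than any particular dataset:

- class sizes 38/63/162/137 (400 patients) by default;
- catalog-consistent feature names (536 per image type: 14 shape + 18
  first-order + 24 GLCM + 16 GLRLM on the original image, and the 40 + 18
  non-shape features on each of eight 3-D wavelet subbands);
- informative features as Gaussian class-mean shifts; redundant blocks via a
  shared latent factor (correlation ρ within a block);
- perturbed-reading replicates with noise variance 2σ²(1−ICC)/ICC, so the
  expected two-reading ICC(2,1) equals the requested target;
- clinical covariates with class-dependent distributions (HPV prevalence
  0.30/0.35/0.70/0.85 across HL/OC/OPC/NPC);
- an optional hierarchical mode (`fusion_separable=True`) in which the
  coarse (HL+OC)/OPC/NPC contrast and the fine HL-vs-OC contrast live on
  disjoint feature groups, with `fine_effect_ratio` scaling the fine
  contrast relative to the coarse effect size. The directional property
  that the cascade recovers the minority classes better than the direct
  pipeline is a property of this hierarchical structure: when the fine
  contrast is too weak to be selected under three-class relevance ranking,
  neither pipeline can separate HL from OC and the property degenerates.

It does **not** emulate: actual image texture or spatial statistics, scanner
or protocol batch effects, censoring or missingness, inter-feature
distributional families beyond Gaussians, or any real patient data.

## Numerical conventions

- Quartiles and medians use the linear-interpolation quantile convention.
- Balanced accuracy skips classes absent from a test fold (logged); general
  accuracy is trace over total of the confusion matrix with rows as truth.
- Per-class accuracies are recalls of the element-wise *sum* of the 30
  repetition confusion matrices, not means of per-repetition recalls.
- Frequency thresholds scale proportionally (rounded up) when the number of
  repetitions differs from 30, preserving F30 ⊆ F25 ⊆ F20 ⊆ F15 ⊆ F1 and the
  meaning of F30 as "selected in every repetition".
- For SMOTE-synthesized rows, age is interpolated with the same mixing
  weight as the features; sex and HPV take the majority value among the base
  point and its k nearest minority neighbors (ties keep the base value) —
  interpolating a dichotomous variable is undefined.
- Clinical covariates bypass radiomic feature selection: sex and HPV enter
  the design matrix raw, age z-scored with training-fold parameters.
- The ICC(2,1) confidence interval uses the F-based approximation with a
  Satterthwaite degrees-of-freedom estimate; a zero-variance reading matrix
  is defined as ICC = 1 with a degenerate interval.
- Repetition model seeds equal the partition seeds, so a run is fully
  determined by the configuration.

## Known limitations

- **Frequency-aggregation optimism.** The final feature set aggregates
  selections from all 30 repetitions; each repetition's test rows were
  training rows of the other repetitions' selection step. Under permuted
  labels the protocol therefore scores slightly above the 4-class chance
  level on average (median balanced accuracy ≈ 0.25–0.28 at this desk
  scale). This is a property of the protocol itself — the evaluation of any
  single final set re-uses partitions that informed its construction — and
  is why the permutation-null test asserts a band around chance rather than
  exact chance. Within a repetition, the leakage audit confirms no fitted
  statistic saw a test row.
- Step 2 of the cascade is only evaluated on repetitions where step 1 routed
  at least one test sample to Fusion; repetitions with none are skipped in
  the step-2 aggregate (logged) but still contribute to the overall result.
- The sampled Shapley estimator pairs each permutation with a single
  background draw; its Monte-Carlo error decreases as 1/√n_samples and a
  warning is emitted when the standard error is large relative to the
  largest value.
- The quadratic-kernel SVM is a degree-2 polynomial kernel with the library
  default coef0; no kernel-scale tuning is performed (C = 1 throughout).
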