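"""Pipeline orchestration: direct 4-class (P1) and two-step cascade (P2).

P1 classifies the four primary sites (HL, OC, OPC, NPC) directly: per
seeded repetition the training fold is z-scored, one feature set per
repetition is selected, selections are frequency-aggregated into a final
set, the training fold is rebalanced to the oral-cavity count, a model is
trained and evaluated on the untouched test fold.

P2 first merges the two minority classes into a transitory "Fusion" class
and solves the more balanced 3-class problem (step 1); per feature-selection
configuration one frequency threshold is elected by the median balanced
accuracy with a 1-percentage-point general-accuracy tie-break (and a
fewest-predictors final tie-break).  In step 2 the training folds are
relabeled to the original four classes, rebalanced, and a 4-class model
reclassifies exactly the test samples step 1 routed to Fusion.  The overall
prediction keeps step 1's OPC/NPC answers and takes step 2's answer for
Fusion-routed samples.

Clinical covariates, when requested, bypass radiomic feature selection and
enter the design matrix as independent columns: sex and HPV status raw,
age z-scored with training-fold parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CLASSES, MERGED_CLASSES, FeatureTable
from .models import (
    EvalResult,
    ModelSpec,
    RepetitionResult,
    aggregate,
    balanced_accuracy,
    confusion,
    general_accuracy,
    train_model,
)
from .partitioning import BalanceSpec, PartitionPlan, balance_training_set, make_partitions
from .preprocessing import zscore_apply, zscore_fit
from .selection import (
    FREQUENCY_THRESHOLDS,
    SELECTOR_NAMES,
    SelectionFrequency,
    aggregate_frequency,
    make_svm_cv_criterion,
    run_selector,
)

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLDS = (0.75, 0.80, 0.85)
FEATURES_MODES = ("radiomic", "clinical", "radiomic+clinical")


def merge_minority(labels: pd.Series) -> pd.Series:
    """Map the two minority classes (HL, OC) to the merged 'Fusion' class."""
    unknown = set(labels.unique()) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    return labels.replace({"HL": "Fusion", "OC": "Fusion"})


@dataclass
class PipelineConfig:
    """One point of the evaluation grid plus protocol constants."""

    pipeline: str = "P1"
    correlation_threshold: float = 0.85
    selector: str = "mrmr"
    frequency_threshold: str = "F20"
    model: ModelSpec = field(default_factory=ModelSpec)
    features_mode: str = "radiomic"
    seeds: list[int] | None = None
    n_repetitions: int = 30
    k: int = 10
    reference_class: str = "OC"
    s1_reference_class: str = "Fusion"
    smote_k: int = 5
    mrmr_m: int = 10
    max_features: int | None = None

    def __post_init__(self) -> None:
        if self.pipeline not in ("P1", "P2"):
            raise ValueError("pipeline must be 'P1' or 'P2'")
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.correlation_threshold not in CORRELATION_THRESHOLDS:
            logger.warning(
                "correlation threshold %.3f outside the standard grid %s",
                self.correlation_threshold, CORRELATION_THRESHOLDS,
            )
        if self.selector not in SELECTOR_NAMES:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.frequency_threshold not in FREQUENCY_THRESHOLDS:
            raise ValueError(f"unknown frequency threshold {self.frequency_threshold!r}")
        if self.features_mode not in FEATURES_MODES:
            raise ValueError(f"unknown features_mode {self.features_mode!r}")

    def repetition_seeds(self) -> list[int]:
        return self.seeds if self.seeds is not None else list(
            range(1, self.n_repetitions + 1)
        )


def config_grid(stage: str, base: PipelineConfig | None = None) -> list[PipelineConfig]:
    """Enumerate the candidate configurations of one pipeline stage.

    'P1' and 'P2-S1' span 3 correlation thresholds x 5 selectors x 5
    frequency thresholds = 75 configurations; 'P2-S2' inherits one elected
    frequency threshold per (threshold, selector) and therefore spans 15.
    """
    if stage not in ("P1", "P2-S1", "P2-S2"):
        raise ValueError("stage must be 'P1', 'P2-S1' or 'P2-S2'")
    base = base or PipelineConfig(pipeline="P1" if stage == "P1" else "P2")
    freqs = list(FREQUENCY_THRESHOLDS) if stage != "P2-S2" else ["F1"]
    grid = []
    for rho in CORRELATION_THRESHOLDS:
        for sel in SELECTOR_NAMES:
            for f in freqs:
                grid.append(
                    replace(base, correlation_threshold=rho, selector=sel,
                            frequency_threshold=f)
                )
    return grid


@dataclass
class CandidateScore:
    """Summary of one frequency-threshold candidate in the election."""

    frequency_threshold: str
    median_balanced_acc: float
    median_general_acc: float
    n_predictors: int


def elect_feature_set(candidates: list[CandidateScore], tol: float = 0.01) -> CandidateScore:
    """Pick the frequency threshold to carry into the next stage.

    Ordered criteria: highest median balanced accuracy; candidates within
    ``tol`` (one percentage point, accuracies on the [0, 1] scale) of the
    best compete on median general accuracy; if still within ``tol`` on
    both, the candidate with the fewest predictors wins.
    """
    if not candidates:
        raise ValueError("no candidates to elect from")
    eps = 1e-12
    best_bal = max(c.median_balanced_acc for c in candidates)
    pool = [c for c in candidates if best_bal - c.median_balanced_acc <= tol + eps]
    best_gen = max(c.median_general_acc for c in pool)
    pool = [c for c in pool if best_gen - c.median_general_acc <= tol + eps]
    if len(pool) > 1:
        pool.sort(key=lambda c: c.n_predictors)
    return pool[0]


class LeakageAudit:
    """Instrumented record of which rows every fitted statistic saw.

    Each pipeline stage records the patient rows used for fitting
    (z-score parameters, feature selection, resampling, model training)
    together with the untouched test rows; :meth:`verify` re-asserts that
    no fitted statistic ever saw a test row.
    """

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def record(self, stage: str, seed: int, fit_ids, test_ids) -> None:
        fit, test = set(fit_ids), set(test_ids)
        if fit & test:
            raise AssertionError(f"leakage in {stage} (seed {seed})")
        self.entries.append(
            {"stage": stage, "seed": seed, "fit_ids": fit, "test_ids": test}
        )

    def verify(self) -> bool:
        for e in self.entries:
            assert not e["fit_ids"] & e["test_ids"], f"leakage in {e['stage']}"
        return True


# ---------------------------------------------------------------------------
# per-repetition plumbing
# ---------------------------------------------------------------------------


def _design(
    table: FeatureTable,
    labels: pd.Series,
    feature_set: set[str],
    config: PipelineConfig,
    train_idx,
    test_idx,
    rep_seed: int,
    reference_class: str,
    classes: list[str],
    audit: LeakageAudit,
    stage: str,
):
    """Build balanced training and untouched test design matrices for one rep."""
    train = table.subset_rows(train_idx).with_labels(labels.iloc[list(train_idx)])
    test = table.subset_rows(test_idx).with_labels(labels.iloc[list(test_idx)])
    audit.record(stage, rep_seed, train.patient_ids, test.patient_ids)

    use_clinical = config.features_mode in ("clinical", "radiomic+clinical")
    feats = sorted(feature_set)
    tr_f = train.select_features(feats)
    te_f = test.select_features(feats)
    if feats:
        params = zscore_fit(tr_f)
        tr_z, te_z = zscore_apply(tr_f, params), zscore_apply(te_f, params)
    else:
        tr_z, te_z = tr_f, te_f

    if use_clinical:
        if train.clinical is None:
            raise ValueError("features_mode requests clinical columns but none present")
        age_mu = float(train.clinical["age"].mean())
        age_sd = float(train.clinical["age"].std(ddof=0)) or 1.0
        tr_z.features["age_z"] = (train.clinical["age"] - age_mu) / age_sd
        te_z.features["age_z"] = (test.clinical["age"] - age_mu) / age_sd

    bal = balance_training_set(
        tr_z, BalanceSpec(reference_class=reference_class,
                          smote_k=config.smote_k, seed=rep_seed)
    )

    def assemble(tbl: FeatureTable) -> np.ndarray:
        X = tbl.features.to_numpy(dtype=float)
        if use_clinical:
            X = np.column_stack(
                [X, tbl.clinical[["sex", "hpv"]].to_numpy(dtype=float)]
            )
        return X

    names = list(tr_z.feature_names) + (["sex", "hpv"] if use_clinical else [])
    return (
        assemble(bal), bal.labels.to_numpy(),
        assemble(te_z), test.labels.to_numpy(),
        test.patient_ids, names,
    )


def _select_per_repetition(
    table: FeatureTable,
    labels: pd.Series,
    plan: PartitionPlan,
    config: PipelineConfig,
    audit: LeakageAudit,
    stage: str,
) -> SelectionFrequency:
    """Run the configured selector on every z-scored training fold."""
    sets = []
    for rep in plan.repetitions:
        train = table.subset_rows(rep.train_indices)
        audit.record(f"{stage}:selection", rep.seed, train.patient_ids,
                     [table.patient_ids[i] for i in rep.test_indices])
        params = zscore_fit(train)
        Z = zscore_apply(train, params).features.to_numpy(dtype=float)
        y = labels.iloc[list(rep.train_indices)].to_numpy()
        crit = make_svm_cv_criterion(seed=rep.seed)
        sets.append(
            run_selector(
                config.selector, Z, y, table.feature_names,
                criterion=crit, mrmr_m=config.mrmr_m,
                max_features=config.max_features, seed=rep.seed,
            )
        )
    return aggregate_frequency(sets)


def _evaluate_feature_set(
    table: FeatureTable,
    labels: pd.Series,
    plan: PartitionPlan,
    feature_set: set[str],
    config: PipelineConfig,
    reference_class: str,
    classes: list[str],
    audit: LeakageAudit,
    stage: str,
) -> EvalResult:
    """Train/evaluate the configured model on every repetition."""
    reps = []
    for rep in plan.repetitions:
        Xtr, ytr, Xte, yte, test_ids, _ = _design(
            table, labels, feature_set, config, rep.train_indices,
            rep.test_indices, rep.seed, reference_class, classes, audit, stage,
        )
        model = train_model(replace(config.model, seed=rep.seed), Xtr, ytr)
        pred_tr = model.predict(Xtr)
        pred_te = model.predict(Xte)
        conf = confusion(yte, pred_te, classes)
        reps.append(
            RepetitionResult(
                seed=rep.seed,
                predictions=pd.Series(pred_te, index=test_ids),
                conf=conf,
                balanced_acc=balanced_accuracy(conf),
                general_acc=general_accuracy(conf),
                train_acc=float((pred_tr == ytr).mean()),
            )
        )
    return aggregate(reps, classes)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


@dataclass
class P1Result:
    eval: EvalResult
    selection: SelectionFrequency | None
    feature_set: set[str]
    audit: LeakageAudit


def run_p1(config: PipelineConfig, table: FeatureTable) -> P1Result:
    """Direct four-class pipeline on a preprocessed feature table."""
    if table.labels is None:
        raise ValueError("table must carry labels")
    labels = table.labels
    classes = [c for c in CLASSES if c in set(labels)]
    audit = LeakageAudit()
    plan = make_partitions(labels, k=config.k,
                           n_repetitions=config.n_repetitions,
                           seeds=config.repetition_seeds())

    if config.features_mode == "clinical":
        selection, feature_set = None, set()
    else:
        selection = _select_per_repetition(table, labels, plan, config, audit, "P1")
        feature_set = selection.final_sets[config.frequency_threshold]
        if not feature_set:
            raise ValueError(
                f"empty final feature set at {config.frequency_threshold}"
            )
    result = _evaluate_feature_set(
        table, labels, plan, feature_set, config,
        config.reference_class, classes, audit, "P1",
    )
    audit.verify()
    return P1Result(result, selection, feature_set, audit)


@dataclass
class P2Result:
    s1: EvalResult
    s2: EvalResult
    overall: EvalResult
    selection: SelectionFrequency | None
    candidates: list[CandidateScore]
    elected: str
    feature_set: set[str]
    audit: LeakageAudit


def run_p2(config: PipelineConfig, table: FeatureTable) -> P2Result:
    """Two-step cascade: merged 3-class step, then minority reclassification.

    Step 1 partitions and models the 3-class (Fusion/OPC/NPC) problem; per
    frequency threshold a candidate is scored and one is elected.  Step 2
    reuses the same partitions and the elected feature set, relabels the
    training folds to the original four classes, rebalances (all four
    classes to the reference count) and reclassifies the test samples that
    step 1 predicted Fusion.  Repetitions in which step 1 routes no test
    sample to Fusion are skipped in step 2's aggregate (logged).
    """
    if table.labels is None:
        raise ValueError("table must carry labels")
    labels4 = table.labels
    labels3 = merge_minority(labels4)
    classes4 = [c for c in CLASSES if c in set(labels4)]
    classes3 = [c for c in MERGED_CLASSES if c in set(labels3)]
    audit = LeakageAudit()
    plan = make_partitions(labels3, k=config.k,
                           n_repetitions=config.n_repetitions,
                           seeds=config.repetition_seeds())

    # --- step 1: selection, candidate evaluation, election ---------------
    if config.features_mode == "clinical":
        selection = None
        candidates = []
        evals = {config.frequency_threshold: _evaluate_feature_set(
            table, labels3, plan, set(), config,
            config.s1_reference_class, classes3, audit, "P2-S1",
        )}
        elected = config.frequency_threshold
        feature_set: set[str] = set()
        candidates.append(CandidateScore(
            elected,
            evals[elected].median("balanced_acc"),
            evals[elected].median("general_acc"),
            3,
        ))
    else:
        selection = _select_per_repetition(table, labels3, plan, config, audit, "P2-S1")
        evals = {}
        candidates = []
        for fname in FREQUENCY_THRESHOLDS:
            fset = selection.final_sets[fname]
            if not fset:
                logger.info("frequency set %s empty; skipped in election", fname)
                continue
            ev = _evaluate_feature_set(
                table, labels3, plan, fset, config,
                config.s1_reference_class, classes3, audit, "P2-S1",
            )
            evals[fname] = ev
            candidates.append(CandidateScore(
                fname, ev.median("balanced_acc"), ev.median("general_acc"), len(fset)
            ))
        if not candidates:
            raise ValueError("all frequency sets empty; nothing to elect")
        elected = elect_feature_set(candidates).frequency_threshold
        feature_set = selection.final_sets[elected]
    s1 = evals[elected]

    # --- step 2: relabel, rebalance, reclassify Fusion-routed samples ----
    s2_reps: list[RepetitionResult] = []
    overall_reps: list[RepetitionResult] = []
    for rep, s1_rep in zip(plan.repetitions, s1.repetitions):
        Xtr, ytr, Xte, yte4, test_ids, _ = _design(
            table, labels4, feature_set, config, rep.train_indices,
            rep.test_indices, rep.seed, config.reference_class,
            classes4, audit, "P2-S2",
        )
        model2 = train_model(replace(config.model, seed=rep.seed), Xtr, ytr)
        pred_tr = model2.predict(Xtr)

        s1_pred = s1_rep.predictions.loc[test_ids].to_numpy()
        routed = s1_pred == "Fusion"
        composed = s1_pred.astype(object).copy()
        if routed.any():
            pred2 = model2.predict(Xte[routed])
            composed[routed] = pred2
            conf2 = confusion(yte4[routed], pred2, classes4)
            s2_reps.append(RepetitionResult(
                seed=rep.seed,
                predictions=pd.Series(pred2, index=np.array(test_ids)[routed]),
                conf=conf2,
                balanced_acc=balanced_accuracy(conf2),
                general_acc=general_accuracy(conf2),
                train_acc=float((pred_tr == ytr).mean()),
            ))
        else:
            logger.info("seed %d: no test sample routed to Fusion; S2 skipped", rep.seed)

        conf_all = confusion(yte4, composed, classes4)
        assert conf_all.sum(axis=1).tolist() == confusion(
            yte4, yte4, classes4).sum(axis=1).tolist()
        overall_reps.append(RepetitionResult(
            seed=rep.seed,
            predictions=pd.Series(composed, index=test_ids),
            conf=conf_all,
            balanced_acc=balanced_accuracy(conf_all),
            general_acc=general_accuracy(conf_all),
            train_acc=float("nan"),
        ))

    if not s2_reps:
        raise ValueError("no repetition routed any test sample to Fusion")
    s2 = aggregate(s2_reps, classes4)
    overall = aggregate(overall_reps, classes4)
    audit.verify()
    return P2Result(s1, s2, overall, selection, candidates, elected, feature_set, audit)
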