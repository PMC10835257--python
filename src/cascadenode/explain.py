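"""Model explainability: per-patient Shapley values and class-wise pooling.

For the best-performing partition, each correctly predicted patient gets a
vector of Shapley values: the average marginal contribution of each feature
to the model's score for the patient's predicted class, with absent
features marginalized over a background sample of training rows.  Within a
class the per-patient values of a feature are pooled into a weighted
Shapley value

    wSV_i = (count_i+ / n) * sum(SV_i+) + (count_i- / n) * sum(SV_i-)

where ``count_i+``/``count_i-`` tally patients with positive/negative
values of feature ``i``, the sums run over those same patients, and ``n``
is the number of correctly predicted patients in the class.  Patients with
an exactly zero value for a feature enter neither tally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import EvalResult

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12  # features up to which Shapley values are enumerated exactly


def _class_score_fn(model, x: np.ndarray, mode: str = "decision"):
    """Scalar score of the model for ``x``'s predicted class.

    ``mode='decision'`` uses the decision function (one-vs-rest column of
    the predicted class) when available, falling back to the predicted-class
    probability; ``mode='probability'`` forces predict_proba.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    pred = model.predict(x)[0]
    cls_idx = int(np.flatnonzero(model.classes_ == pred)[0])
    use_decision = mode == "decision" and hasattr(model, "decision_function")
    if mode not in ("decision", "probability"):
        raise ValueError("mode must be 'decision' or 'probability'")

    def f(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if use_decision:
            scores = model.decision_function(X)
            if scores.ndim == 1:  # binary: score of the positive class
                return scores if cls_idx == 1 else -scores
            return scores[:, cls_idx]
        return model.predict_proba(X)[:, cls_idx]

    return f, pred


def shapley_values(
    model,
    x: np.ndarray,
    background_rows: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
    mode: str = "decision",
) -> np.ndarray:
    """Shapley values of every feature for one patient.

    Exact subset enumeration when the feature count is at most 12,
    seeded permutation sampling (``n_samples`` permutations, each paired
    with one background draw) otherwise.  Satisfies the efficiency axiom:
    the values sum to ``f(x) - mean_z f(z)`` over the background.
    """
    x = np.asarray(x, dtype=float).ravel()
    Z = np.asarray(background_rows, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != x.size:
        raise ValueError("background_rows must be 2-D with the same feature count")
    f, _ = _class_score_fn(model, x, mode=mode)
    d = x.size
    if d <= EXACT_LIMIT:
        return _shapley_exact(f, x, Z)
    return _shapley_sampled(f, x, Z, n_samples, seed)


def _shapley_exact(f, x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    d = x.size
    # v(S) = mean_z f(z with coordinates in S replaced by x)
    masks = np.array(
        [[(m >> j) & 1 for j in range(d)] for m in range(2**d)], dtype=bool
    )
    values = np.empty(2**d)
    for m, mask in enumerate(masks):
        X = Z.copy()
        X[:, mask] = x[mask]
        values[m] = f(X).mean()
    fact = [math.factorial(s) for s in range(d + 1)]
    sv = np.zeros(d)
    for m, mask in enumerate(masks):
        s = int(mask.sum())
        w = fact[s] * fact[d - s - 1] / fact[d]
        for j in range(d):
            if not mask[j]:
                sv[j] += w * (values[m | (1 << j)] - values[m])
    return sv


def _shapley_sampled(
    f, x: np.ndarray, Z: np.ndarray, n_samples: int, seed: int
) -> np.ndarray:
    d = x.size
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_samples, d))
    for t in range(n_samples):
        perm = rng.permutation(d)
        z = Z[rng.integers(len(Z))].copy()
        prev = f(z.reshape(1, -1))[0]
        cur = z
        for j in perm:
            cur = cur.copy()
            cur[j] = x[j]
            val = f(cur.reshape(1, -1))[0]
            contrib[t, j] = val - prev
            prev = val
    sv = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_samples)
    scale = np.abs(sv).max() or 1.0
    if (se > 0.25 * scale).any():
        logger.warning(
            "Shapley Monte-Carlo SE up to %.3g vs max |SV| %.3g; "
            "consider more samples", se.max(), scale,
        )
    return sv


@dataclass
class ShapleyReport:
    """Class-wise pooled Shapley statistics."""

    class_name: str
    n: int                      # correctly predicted patients of the class
    sv_matrix: pd.DataFrame     # patients x features
    wsv: pd.Series              # weighted Shapley value per feature
    count_plus: pd.Series
    count_minus: pd.Series
    sum_plus: pd.Series
    sum_minus: pd.Series

    def top_positive(self, k: int = 3) -> pd.Series:
        pos = self.wsv[self.wsv > 0]
        return pos.sort_values(ascending=False).head(k)

    def top_negative(self, k: int = 3) -> pd.Series:
        neg = self.wsv[self.wsv < 0]
        return neg.sort_values().head(k)


def weighted_shapley(sv_matrix: pd.DataFrame, class_name: str = "") -> ShapleyReport:
    """Pool per-patient Shapley values of one class into wSV per feature.

    ``sv_matrix`` rows are the correctly predicted patients of the class;
    exactly zero values count in neither the positive nor the negative
    tally.
    """
    if len(sv_matrix) == 0:
        raise ValueError("sv_matrix must have at least one patient")
    V = sv_matrix.to_numpy(dtype=float)
    n = len(sv_matrix)
    pos, neg = V > 0, V < 0
    count_plus = pos.sum(axis=0)
    count_minus = neg.sum(axis=0)
    sum_plus = np.where(pos, V, 0.0).sum(axis=0)
    sum_minus = np.where(neg, V, 0.0).sum(axis=0)
    wsv = (count_plus / n) * sum_plus + (count_minus / n) * sum_minus
    cols = sv_matrix.columns
    return ShapleyReport(
        class_name=class_name,
        n=n,
        sv_matrix=sv_matrix,
        wsv=pd.Series(wsv, index=cols),
        count_plus=pd.Series(count_plus, index=cols),
        count_minus=pd.Series(count_minus, index=cols),
        sum_plus=pd.Series(sum_plus, index=cols),
        sum_minus=pd.Series(sum_minus, index=cols),
    )


def explain_best_partition(
    config,
    table,
    n_samples: int = 100,
    seed: int = 0,
    background_size: int = 20,
    mode: str = "decision",
) -> dict[str, ShapleyReport]:
    """End-to-end explainability for one pipeline configuration.

    Runs the configured pipeline, takes the repetition with the highest
    balanced accuracy (for P2, of the overall composed result), refits the
    final four-class model on that repetition's balanced training set, and
    computes Shapley values for every correctly predicted test patient of
    each class against a background sample of training rows.  Returns one
    weighted-Shapley report per class (for P2 the transitory Fusion class
    never appears: the explained model is the four-class second-step model).
    """
    from . import pipelines as pl
    from .partitioning import make_partitions

    if table.labels is None:
        raise ValueError("table must carry labels")
    labels4 = table.labels
    if config.pipeline == "P1":
        res = pl.run_p1(config, table)
        evaluation, feature_set = res.eval, res.feature_set
        plan_labels = labels4
    else:
        res = pl.run_p2(config, table)
        evaluation, feature_set = res.overall, res.feature_set
        plan_labels = pl.merge_minority(labels4)
    best = select_best_partition(evaluation)

    plan = make_partitions(plan_labels, k=config.k,
                           n_repetitions=config.n_repetitions,
                           seeds=config.repetition_seeds())
    rep = plan.repetitions[best]
    classes = [c for c in evaluation.classes]
    audit = pl.LeakageAudit()
    Xtr, ytr, Xte, yte, test_ids, names = pl._design(
        table, labels4, feature_set, config, rep.train_indices,
        rep.test_indices, rep.seed, config.reference_class, classes,
        audit, "explain",
    )
    from dataclasses import replace as _replace

    from .models import train_model as _train

    model = _train(_replace(config.model, seed=rep.seed), Xtr, ytr)
    pred = model.predict(Xte)

    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(Xtr), size=min(background_size, len(Xtr)), replace=False)
    background = Xtr[bg_idx]

    reports: dict[str, ShapleyReport] = {}
    for cls in classes:
        correct = (pred == yte) & (yte == cls)
        if not correct.any():
            logger.warning("class %s: no correctly predicted patient; skipped", cls)
            continue
        rows = []
        ids = []
        for i in np.flatnonzero(correct):
            sv = shapley_values(model, Xte[i], background, n_samples=n_samples,
                                seed=seed + int(i), mode=mode)
            rows.append(sv)
            ids.append(test_ids[i])
        sv_matrix = pd.DataFrame(rows, index=ids, columns=names)
        reports[cls] = weighted_shapley(sv_matrix, class_name=cls)
    return reports


def select_best_partition(result: EvalResult) -> int:
    """Index of the repetition with the highest balanced accuracy.

    Ties resolve to the lowest repetition seed.
    """
    if not result.repetitions:
        raise ValueError("empty result")
    best = max(
        range(len(result.repetitions)),
        key=lambda i: (result.repetitions[i].balanced_acc,
                       -result.repetitions[i].seed),
    )
    return best
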