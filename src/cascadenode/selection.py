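"""Feature selection: five selectors and frequency aggregation.

Per training partition one feature set is produced by one of five methods —
sequential forward selection (SFS), sequential backward selection (SBS),
sequential floating forward selection (SFFS), neighborhood component
analysis with per-feature weights (NCA), and minimum-redundancy
maximum-relevance ranking (MRMR).  Over the 30 repetitions the selection
frequency of each feature is tallied and the final sets F1/F15/F20/F25/F30
keep the features selected in at least 1, 15, 20, 25 or all 30 repetitions.

The sequential wrappers score a candidate subset by the misclassification
error of a linear SVM under an internal stratified 5-fold cross-validation
of the training rows; NCA and MRMR are filter methods independent of the
downstream classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SELECTOR_NAMES = ("sfs", "sbs", "sffs", "nca", "mrmr")

#: Frequency-threshold names and their nominal minimum counts out of 30.
FREQUENCY_THRESHOLDS = {"F1": 1, "F15": 15, "F20": 20, "F25": 25, "F30": 30}

_IMPROVE_TOL = 1e-6

Criterion = Callable[[np.ndarray, np.ndarray, Sequence[int]], float]


def make_svm_cv_criterion(
    n_folds: int = 5, seed: int = 0, C: float = 1.0
) -> Criterion:
    """Subset-scoring criterion: CV misclassification error of a linear SVM.

    Lower is better.  The internal folds are stratified and seeded, so the
    criterion (and hence the wrapper selectors) is deterministic.
    """

    def criterion(X: np.ndarray, y: np.ndarray, idx: Sequence[int]) -> float:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        acc = cross_val_score(
            SVC(kernel="linear", C=C), X[:, list(idx)], y, cv=cv, scoring="accuracy"
        ).mean()
        return 1.0 - acc

    return criterion


def sfs(
    X: np.ndarray,
    y: np.ndarray,
    criterion: Criterion,
    max_features: int | None = None,
) -> list[int]:
    """Sequential forward selection with an improvement-based stop.

    Always selects at least the single best feature; thereafter adds the
    best-scoring feature while the criterion improves by more than 1e-6.
    """
    n_feat = X.shape[1]
    if n_feat < 1:
        raise ValueError("need at least one feature")
    limit = n_feat if max_features is None else min(max_features, n_feat)
    selected: list[int] = []
    current = math.inf
    while len(selected) < limit:
        remaining = [j for j in range(n_feat) if j not in selected]
        scores = [criterion(X, y, selected + [j]) for j in remaining]
        best = int(np.argmin(scores))
        if selected and scores[best] >= current - _IMPROVE_TOL:
            break
        selected.append(remaining[best])
        current = scores[best]
    return selected


def sbs(X: np.ndarray, y: np.ndarray, criterion: Criterion) -> list[int]:
    """Sequential backward selection; removes while removal improves."""
    n_feat = X.shape[1]
    selected = list(range(n_feat))
    current = criterion(X, y, selected)
    while len(selected) > 1:
        scores = [
            criterion(X, y, [j for j in selected if j != r]) for r in selected
        ]
        best = int(np.argmin(scores))
        if scores[best] >= current - _IMPROVE_TOL:
            break
        del selected[best]
        current = scores[best]
    return selected


def sffs(
    X: np.ndarray,
    y: np.ndarray,
    criterion: Criterion,
    max_features: int | None = None,
) -> list[int]:
    """Sequential floating forward selection.

    Forward steps as in SFS; after each addition, features are conditionally
    excluded while the exclusion beats the best score recorded for the
    resulting subset size.
    """
    n_feat = X.shape[1]
    limit = n_feat if max_features is None else min(max_features, n_feat)
    selected: list[int] = []
    best_for_size: dict[int, float] = {0: math.inf}
    current = math.inf
    while len(selected) < limit:
        remaining = [j for j in range(n_feat) if j not in selected]
        if not remaining:
            break
        scores = [criterion(X, y, selected + [j]) for j in remaining]
        best = int(np.argmin(scores))
        if selected and scores[best] >= current - _IMPROVE_TOL:
            break
        selected.append(remaining[best])
        current = scores[best]
        best_for_size[len(selected)] = min(
            best_for_size.get(len(selected), math.inf), current
        )
        # floating: conditional exclusion while it improves the best score
        # known for the smaller subset size
        while len(selected) > 2:
            drop_scores = [
                criterion(X, y, [j for j in selected if j != r]) for r in selected
            ]
            d = int(np.argmin(drop_scores))
            size_after = len(selected) - 1
            if drop_scores[d] < best_for_size.get(size_after, math.inf) - _IMPROVE_TOL:
                del selected[d]
                current = drop_scores[d]
                best_for_size[size_after] = current
            else:
                break
    return selected


def nca_feature_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-feature weights from diagonal neighborhood component analysis.

    Maximizes the regularized expected leave-one-out accuracy of a
    stochastic nearest-neighbor classifier whose metric is
    ``d(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|``:

        F(w) = (1/n) sum_i p_i - lam * sum_r w_r^2,
        p_i = sum_{j != i, y_j = y_i} p_ij,
        p_ij ~ exp(-d(x_i, x_j)).

    ``lam`` defaults to 1/n.  Expects z-scored features.  Returns |w|.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if lam is None:
        lam = 1.0 / n
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    # pairwise absolute differences per feature: (n, n, p)
    D = np.abs(X[:, None, :] - X[None, :, :])

    def neg_obj_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        w2 = w**2
        dist = D @ w2
        np.fill_diagonal(dist, np.inf)
        logits = -dist
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        p_i = (P * same).sum(axis=1)
        obj = p_i.mean() - lam * w2.sum()
        # d(obj)/d(w_r) = (2 w_r / n) * sum_i [ p_i * sum_j P_ij D_ijr
        #                 - sum_{j in class i} P_ij D_ijr ] - 2 lam w_r
        coef = P * (p_i[:, None] - same)  # (n, n)
        grad = (2.0 * w / n) * np.einsum("ij,ijr->r", coef, D) - 2.0 * lam * w
        return -obj, -grad

    res = minimize(
        neg_obj_grad,
        x0=np.ones(p),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    if not res.success:
        logger.warning("NCA optimizer did not converge: %s", res.message)
    return np.abs(res.x)


def nca_select(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    weight_threshold: float = 0.02,
    max_iter: int = 100,
) -> list[int]:
    """Features whose NCA weight exceeds ``weight_threshold`` x max weight.

    ``weight_threshold = 0`` returns all features.
    """
    w = nca_feature_weights(X, y, lam=lam, max_iter=max_iter)
    if weight_threshold <= 0:
        return list(range(X.shape[1]))
    cut = weight_threshold * w.max()
    return [j for j in range(X.shape[1]) if w[j] > cut]


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning (ranks -> quantile bins); ties share a bin."""
    codes = pd.qcut(pd.Series(x).rank(method="average"), q=n_bins,
                    duplicates="drop", labels=False)
    return np.asarray(codes, dtype=int)


def mrmr_select(
    X: np.ndarray, y: np.ndarray, m: int, n_bins: int = 8
) -> list[int]:
    """Greedy MRMR ranking (mutual-information difference scheme).

    At each step picks the feature maximizing
    ``I(x; y) - mean_{s in selected} I(x; x_s)`` with mutual information
    computed on equal-frequency discretized features (8 bins by default).
    Returns the first ``m`` features in selection order.
    """
    n, p = X.shape
    if m > p:
        raise ValueError("m exceeds the number of features")
    if m == 0:
        return []
    disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(p)])
    y_arr = np.asarray(y)
    relevance = np.array([mutual_info_score(y_arr, disc[:, j]) for j in range(p)])

    selected: list[int] = [int(np.argmax(relevance))]
    redundancy = np.zeros(p)
    mi_cache: dict[tuple[int, int], float] = {}

    def mi_ff(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[:, a], disc[:, b])
        return mi_cache[key]

    while len(selected) < m:
        last = selected[-1]
        for j in range(p):
            if j not in selected:
                redundancy[j] += mi_ff(j, last)
        scores = np.full(p, -np.inf)
        for j in range(p):
            if j not in selected:
                scores[j] = relevance[j] - redundancy[j] / len(selected)
        selected.append(int(np.argmax(scores)))
    return selected


@dataclass
class SelectionFrequency:
    """Selection tallies over repetitions and the thresholded final sets."""

    counts: dict[str, int]
    n_repetitions: int
    final_sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        if any(not 0 <= c <= self.n_repetitions for c in self.counts.values()):
            raise ValueError("counts must lie in [0, n_repetitions]")
        order = list(FREQUENCY_THRESHOLDS)
        for hi, lo in zip(order[::-1], order[::-1][1:]):
            if not self.final_sets[hi] <= self.final_sets[lo]:
                raise AssertionError(f"frequency sets not nested: {hi} !<= {lo}")


def threshold_count(name: str, n_repetitions: int) -> int:
    """Minimum selection count for a frequency threshold.

    The nominal counts (1/15/20/25/30) refer to 30 repetitions; for other
    repetition numbers they scale proportionally (rounded up), so F30 always
    means 'selected in every repetition' and the nesting
    F30 <= F25 <= F20 <= F15 <= F1 is preserved.
    """
    nominal = FREQUENCY_THRESHOLDS[name]
    return max(1, math.ceil(n_repetitions * nominal / 30))


def aggregate_frequency(per_repetition_sets: list[set[str]]) -> SelectionFrequency:
    """Tally how often each feature was selected and build F1..F30 sets."""
    if not per_repetition_sets:
        raise ValueError("need at least one per-repetition selection")
    n_rep = len(per_repetition_sets)
    counts: dict[str, int] = {}
    for s in per_repetition_sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    final = {
        name: {f for f, c in counts.items() if c >= threshold_count(name, n_rep)}
        for name in FREQUENCY_THRESHOLDS
    }
    return SelectionFrequency(counts, n_rep, final)


def run_selector(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    criterion: Criterion | None = None,
    mrmr_m: int = 10,
    max_features: int | None = None,
    seed: int = 0,
) -> set[str]:
    """Dispatch one selector by name and return the selected feature names."""
    if name not in SELECTOR_NAMES:
        raise ValueError(f"unknown selector {name!r}")
    if name in ("sfs", "sbs", "sffs"):
        crit = criterion or make_svm_cv_criterion(seed=seed)
        if name == "sfs":
            idx = sfs(X, y, crit, max_features=max_features)
        elif name == "sbs":
            idx = sbs(X, y, crit)
        else:
            idx = sffs(X, y, crit, max_features=max_features)
    elif name == "nca":
        idx = nca_select(X, y)
    else:
        idx = mrmr_select(X, y, m=min(mrmr_m, X.shape[1]))
    return {feature_names[j] for j in idx}
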