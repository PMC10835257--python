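"""Feature preprocessing: ICC stability filter, redundancy pruning, z-score.

Radiomic features are only useful if they survive small perturbations of the
region of interest; reliability is quantified by the two-way random-effects,
absolute-agreement, single-rater intraclass correlation coefficient,
ICC(2,1).  Features with ICC above a threshold (default 0.75) are kept.
Highly redundant features are then removed by pairwise absolute Spearman
correlation, and the survivors are z-scored with parameters fitted on
training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler

from .cohort import FeatureTable

logger = logging.getLogger(__name__)


def icc(readings: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1) with its two-sided ``1 - alpha`` confidence interval.

    Parameters
    ----------
    readings : (n, k) array
        One row per subject, one column per reading/rater; n >= 3, k >= 2.

    Returns
    -------
    (estimate, ci_low, ci_high)

    Notes
    -----
    Computed from the two-way ANOVA mean squares (rows = subjects,
    columns = raters)::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval uses the standard F-based approximation with a
    Satterthwaite degrees-of-freedom estimate for the denominator.  A matrix
    with zero total variance has perfect (if vacuous) agreement and is
    defined as ICC = 1 with a degenerate interval [1, 1].
    """
    y = np.asarray(readings, dtype=float)
    if y.ndim != 2:
        raise ValueError("readings must be a 2-D subjects x raters matrix")
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 readings per subject")
    if not np.isfinite(y).all():
        raise ValueError("readings must be finite")

    grand = y.mean()
    if np.allclose(y, grand):
        logger.warning("zero total variance: ICC defined as 1 with degenerate CI")
        return 1.0, 1.0, 1.0

    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else 1.0

    # F-based CI (Satterthwaite df for the MSC/MSE mixture)
    r = est
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * r / (n * (1.0 - r)) if r < 1.0 else np.inf
        b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if not np.isfinite(a) or mse == 0:
        return float(est), float(est), float(est)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    high = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    low = float(min(low, est))
    high = float(max(high, est))
    return float(est), low, high


def stability_filter(
    table: FeatureTable,
    replicate: FeatureTable,
    icc_threshold: float = 0.75,
    on: str = "estimate",
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features whose two-reading ICC(2,1) exceeds ``icc_threshold``.

    ``on`` selects the thresholded statistic: the point ``"estimate"``
    (default) or the lower 95% confidence bound ``"ci_low"``.

    Returns the filtered table and a stability report (one row per input
    feature: icc, ci_low, ci_high, stable).
    """
    if table.patient_ids != replicate.patient_ids:
        raise ValueError("table and replicate must share patients (same order)")
    if table.feature_names != replicate.feature_names:
        raise ValueError("table and replicate must share features (same order)")
    if on not in ("estimate", "ci_low"):
        raise ValueError("on must be 'estimate' or 'ci_low'")

    rows = []
    X = table.features.to_numpy(dtype=float)
    R = replicate.features.to_numpy(dtype=float)
    for j, name in enumerate(table.feature_names):
        est, lo, hi = icc(np.column_stack([X[:, j], R[:, j]]))
        stat = est if on == "estimate" else lo
        rows.append((name, est, lo, hi, bool(stat > icc_threshold)))
    report = pd.DataFrame(
        rows, columns=["feature", "icc", "ci_low", "ci_high", "stable"]
    ).set_index("feature")
    kept = [n for n in table.feature_names if report.loc[n, "stable"]]
    logger.info("stability filter: %d of %d features stable", len(kept), table.n_features)
    return table.select_features(kept), report


@dataclass
class PruneResult:
    """Outcome of correlation-based redundancy removal."""

    kept_features: list[str]
    removed_features: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if set(self.kept_features) & set(self.removed_features):
            raise ValueError("kept and removed sets overlap")


def _spearman_abs(X: np.ndarray, names: list[str]) -> np.ndarray:
    """Absolute Spearman correlation matrix; constant columns -> 0, flagged."""
    const = X.std(axis=0) == 0
    if const.any():
        logger.warning(
            "constant features treated as correlation 0: %s",
            [n for n, c in zip(names, const) if c],
        )
    rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # two features: spearmanr returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(rho, 0.0)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    return rho


def correlation_prune(table: FeatureTable, threshold: float) -> PruneResult:
    """Greedy removal of redundant features by absolute Spearman correlation.

    While any kept pair has |rho| above ``threshold``, the most correlated
    violating pair is processed, and the member with the higher mean
    absolute correlation to all other currently-kept features is dropped
    (ties keep the lexicographically first name).  Terminates with no
    surviving pair above the threshold, which is re-asserted before
    returning.
    """
    if table.n_features < 2:
        raise ValueError("need at least 2 features to prune")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")

    names = table.feature_names
    rho = _spearman_abs(table.features.to_numpy(dtype=float), names)
    kept = list(range(len(names)))
    removed: list[str] = []

    while True:
        sub = rho[np.ix_(kept, kept)]
        viol = np.argwhere(np.triu(sub, k=1) > threshold)
        if viol.size == 0:
            break
        vals = sub[viol[:, 0], viol[:, 1]]
        a_loc, b_loc = viol[np.argmax(vals)]
        a, b = kept[a_loc], kept[b_loc]
        others = [i for i in kept if i not in (a, b)]
        mean_a = rho[a, others].mean() if others else 0.0
        mean_b = rho[b, others].mean() if others else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            # tie: keep the lexicographically first name
            drop = b if names[a] < names[b] else a
            logger.info("mean-correlation tie between %s and %s", names[a], names[b])
        kept.remove(drop)
        removed.append(names[drop])

    kept_names = [names[i] for i in kept]
    # machine-check the postcondition on every run
    final = rho[np.ix_(kept, kept)]
    assert not (np.triu(final, k=1) > threshold).any(), "pruning postcondition violated"
    return PruneResult(kept_names, removed, threshold)


@dataclass
class ZScoreParams:
    """Per-feature location/scale fitted on training rows."""

    mean: pd.Series
    scale: pd.Series
    constant_features: list[str]


def zscore_fit(table: FeatureTable) -> ZScoreParams:
    """Fit per-feature standardization parameters (training rows only)."""
    scaler = StandardScaler().fit(table.features.to_numpy(dtype=float))
    const = [n for n, v in zip(table.feature_names, scaler.var_) if v == 0.0]
    if const:
        logger.warning("zero-variance features map to all-zeros: %s", const)
    return ZScoreParams(
        mean=pd.Series(scaler.mean_, index=table.feature_names),
        scale=pd.Series(scaler.scale_, index=table.feature_names),
        constant_features=const,
    )


def zscore_apply(table: FeatureTable, params: ZScoreParams) -> FeatureTable:
    """Standardize features with previously fitted parameters."""
    if list(params.mean.index) != table.feature_names:
        raise ValueError("parameters were fitted on a different feature set")
    Z = (table.features - params.mean) / params.scale
    return FeatureTable(Z, table._lab(), table._clin())
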