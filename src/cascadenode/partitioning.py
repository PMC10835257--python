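"""Repeated seeded train/test partitioning and class rebalancing.

The evaluation protocol draws 30 stratified train/test splits (one held-out
fold of a 10-fold partition per repetition, each with its own seed) and, on
every training set, equalizes the four class counts to the count of a
reference class (oral cavity by default): classes above it are randomly
undersampled and classes below it are oversampled with SMOTE, which
interpolates new minority samples between a minority point and one of its k
nearest minority neighbors.  Test sets are never resampled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .cohort import CLINICAL_COLUMNS, FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Repetition:
    """One seeded train/test split."""

    seed: int
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


@dataclass
class PartitionPlan:
    """Collection of seeded repetitions over the same patients."""

    repetitions: list[Repetition]
    n_patients: int
    k: int = 10

    def __post_init__(self) -> None:
        seeds = [r.seed for r in self.repetitions]
        if len(set(seeds)) != len(seeds):
            raise ValueError("repetition seeds must be distinct")
        allidx = set(range(self.n_patients))
        for r in self.repetitions:
            tr, te = set(r.train_indices), set(r.test_indices)
            if tr & te:
                raise ValueError("train and test overlap")
            if tr | te != allidx:
                raise ValueError("train + test must cover all patients")

    def to_json(self, path) -> None:
        payload = {
            "n_patients": self.n_patients,
            "k": self.k,
            "repetitions": [
                {
                    "seed": r.seed,
                    "train_indices": list(r.train_indices),
                    "test_indices": list(r.test_indices),
                }
                for r in self.repetitions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PartitionPlan":
        with open(path) as fh:
            payload = json.load(fh)
        reps = [
            Repetition(r["seed"], tuple(r["train_indices"]), tuple(r["test_indices"]))
            for r in payload["repetitions"]
        ]
        return cls(reps, payload["n_patients"], payload["k"])


def make_partitions(
    labels: pd.Series | np.ndarray,
    k: int = 10,
    n_repetitions: int = 30,
    seeds: list[int] | None = None,
) -> PartitionPlan:
    """Build ``n_repetitions`` stratified held-out-fold splits.

    Each repetition shuffles the patients with its own seed, partitions them
    into ``k`` stratified folds, and holds out the first fold (size ~= n/k,
    per-class test fraction within one patient of 1/k) as the test set.
    Seeds default to 1..n_repetitions.
    """
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes smaller than k={k}: {small}")
    if seeds is None:
        seeds = list(range(1, n_repetitions + 1))
    if len(seeds) != n_repetitions:
        raise ValueError("need one seed per repetition")

    reps = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        train_idx, test_idx = next(iter(skf.split(np.zeros(len(y)), y)))
        reps.append(Repetition(seed, tuple(train_idx.tolist()), tuple(test_idx.tolist())))
    return PartitionPlan(reps, len(y), k)


@dataclass
class BalanceSpec:
    """How to equalize training-class counts."""

    reference_class: str = "OC"
    smote_k: int = 5
    seed: int = 0
    binary_columns: tuple[str, ...] = ("sex", "hpv")

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def smote_oversample(
    minority: np.ndarray, target_n: int, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE: interpolate synthetic rows between nearest minority neighbors.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the ``k`` nearest minority neighbors of a randomly
    chosen minority row ``x``.

    Returns
    -------
    (rows, base_idx, neighbor_idx, u)
        ``rows`` is the ``(target_n, d)`` output including all originals
        first; the other three describe each synthetic row's provenance
        (used by callers to derive non-interpolable covariates).
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("minority must be a 2-D array with at least 2 rows")
    if target_n < len(X):
        raise ValueError("target_n must be >= the minority size")
    n_new = target_n - len(X)
    if n_new == 0:
        return X.copy(), np.empty(0, int), np.empty(0, int), np.empty(0)

    if k >= len(X):
        logger.warning("smote_k clipped from %d to %d", k, len(X) - 1)
        k = len(X) - 1
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self

    base = rng.integers(0, len(X), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    nbr = neigh[base, pick]
    u = rng.random(n_new)
    synth = X[base] + u[:, None] * (X[nbr] - X[base])
    return np.vstack([X, synth]), base, nbr, u


def balance_training_set(train: FeatureTable, spec: BalanceSpec) -> FeatureTable:
    """Equalize every class count to the reference class's training count.

    Classes above the reference count are randomly undersampled (seeded);
    classes below are SMOTE-oversampled on the feature matrix.  For
    synthetic rows, continuous clinical covariates (age) are interpolated
    with the same mixing weight as the features, while dichotomous ones
    (sex, HPV) take the majority value among the base point and its SMOTE
    neighbors (interpolating a binary variable is undefined).
    """
    if train.labels is None:
        raise ValueError("training table must carry labels")
    y = train.labels
    classes = list(pd.unique(y))
    if spec.reference_class not in classes:
        raise ValueError(f"reference class {spec.reference_class!r} absent from training set")
    target = int((y == spec.reference_class).sum())
    rng = np.random.default_rng(spec.seed)

    has_clin = train.clinical is not None
    pieces_f, pieces_l, pieces_c = [], [], []
    for cls in classes:
        mask = (y == cls).to_numpy()
        Xc = train.features.loc[mask]
        Cc = train.clinical.loc[mask] if has_clin else None
        n_c = len(Xc)
        if n_c > target:
            keep = np.sort(rng.choice(n_c, size=target, replace=False))
            Xc = Xc.iloc[keep]
            Cc = Cc.iloc[keep] if has_clin else None
        elif n_c < target:
            rows, base, nbr, u = smote_oversample(
                Xc.to_numpy(dtype=float), target, spec.smote_k,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ids = list(Xc.index) + [f"{cls}_syn{m:03d}" for m in range(target - n_c)]
            newX = pd.DataFrame(rows, index=ids, columns=train.feature_names)
            if has_clin:
                newC = pd.DataFrame(index=ids, columns=list(CLINICAL_COLUMNS), dtype=float)
                newC.iloc[: n_c] = Cc.to_numpy(dtype=float)
                age = Cc["age"].to_numpy(dtype=float)
                newC.iloc[n_c:, newC.columns.get_loc("age")] = (
                    age[base] + u * (age[nbr] - age[base])
                )
                k_eff = min(spec.smote_k, n_c - 1)
                neigh = (
                    NearestNeighbors(n_neighbors=k_eff + 1)
                    .fit(Xc.to_numpy(dtype=float))
                    .kneighbors(Xc.to_numpy(dtype=float), return_distance=False)
                )  # column 0 is the point itself, so the vote includes it
                for col in spec.binary_columns:
                    vals = Cc[col].to_numpy(dtype=float)
                    frac = vals[neigh[base]].mean(axis=1)
                    # majority among base + k nearest; ties toward the base
                    vote = np.where(frac > 0.5, 1.0,
                                    np.where(frac < 0.5, 0.0, vals[base]))
                    newC.iloc[n_c:, newC.columns.get_loc(col)] = vote
                Cc = newC
            Xc = newX
        pieces_f.append(Xc)
        pieces_l.append(pd.Series([cls] * target, index=Xc.index))
        if has_clin:
            pieces_c.append(Cc)

    features = pd.concat(pieces_f)
    labels = pd.concat(pieces_l)
    clinical = pd.concat(pieces_c) if has_clin else None
    return FeatureTable(features, labels, clinical)
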