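"""Classifier families and evaluation statistics.

Five model families are supported — neural network (NN), decision tree
(DT), Gaussian naive Bayes (NB), bagged trees (BT) and support vector
machine (SVM, linear or quadratic kernel).  Performance is summarized per
repetition by the balanced accuracy (mean of per-class recalls), the general
accuracy (overall fraction correct) and the training accuracy, and across
repetitions by the median and quartiles; per-class accuracies are the
recalls of the element-wise sum of the repetition confusion matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MODEL_KINDS = ("NN", "DT", "NB", "BT", "SVM")


@dataclass
class ModelSpec:
    """Which classifier to train and with what hyperparameters.

    Defaults: SVM C=1 (kernel per ``svm_kernel``, 'quadratic' meaning a
    degree-2 polynomial kernel), NN one hidden layer of 25 units, DT with
    Gini impurity and unlimited depth, NB Gaussian, BT 100 trees.  All are
    overridable through ``hyperparameters``.
    """

    kind: str = "SVM"
    svm_kernel: str = "linear"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.svm_kernel not in ("linear", "quadratic"):
            raise ValueError("svm_kernel must be 'linear' or 'quadratic'")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "SVM":
            if self.svm_kernel == "linear":
                return SVC(kernel="linear", C=hp.pop("C", 1.0),
                           decision_function_shape="ovr", **hp)
            return SVC(kernel="poly", degree=2, C=hp.pop("C", 1.0),
                       decision_function_shape="ovr", **hp)
        if self.kind == "NN":
            return MLPClassifier(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (25,)),
                max_iter=hp.pop("max_iter", 1000),
                random_state=self.seed, **hp,
            )
        if self.kind == "DT":
            return DecisionTreeClassifier(
                criterion=hp.pop("criterion", "gini"), random_state=self.seed, **hp
            )
        if self.kind == "NB":
            return GaussianNB(**hp)
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=self.seed),
            n_estimators=hp.pop("n_estimators", 100),
            random_state=self.seed, **hp,
        )


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit the classifier described by ``spec``; rejects single-class y."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = spec.build()
    model.fit(np.asarray(X, dtype=float), y)
    return model


def confusion(y_true, y_pred, classes: list[str]) -> pd.DataFrame:
    """Confusion matrix with rows = truth, columns = prediction."""
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def balanced_accuracy(conf: pd.DataFrame | np.ndarray) -> float:
    """Mean per-class recall over classes present in the test set.

    Classes with no test samples (empty rows) are skipped, with a log note.
    """
    m = np.asarray(conf, dtype=float)
    if m.shape[0] != m.shape[1] or (m < 0).any():
        raise ValueError("confusion matrix must be square and nonnegative")
    row_sums = m.sum(axis=1)
    if row_sums.sum() == 0:
        raise ValueError("empty confusion matrix")
    present = row_sums > 0
    if not present.all():
        logger.info("balanced accuracy skips %d empty class(es)", (~present).sum())
    recalls = np.diag(m)[present] / row_sums[present]
    return float(recalls.mean())


def general_accuracy(conf: pd.DataFrame | np.ndarray) -> float:
    """Overall fraction of correct predictions (trace over total)."""
    m = np.asarray(conf, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m) / total)


@dataclass
class RepetitionResult:
    """Evaluation of one train/test repetition."""

    seed: int
    predictions: pd.Series  # index = test patient ids, values = predicted class
    conf: pd.DataFrame
    balanced_acc: float
    general_acc: float
    train_acc: float


@dataclass
class EvalResult:
    """Aggregate over repetitions: medians, quartiles, summed confusion."""

    classes: list[str]
    repetitions: list[RepetitionResult]
    metrics: pd.DataFrame          # rows: balanced_acc/general_acc/train_acc;
                                   # columns: median, q1, q3
    summed_confusion: pd.DataFrame
    per_class_acc: pd.Series       # recall of the summed confusion

    def median(self, metric: str) -> float:
        return float(self.metrics.loc[metric, "median"])


def aggregate(repetitions: list[RepetitionResult], classes: list[str]) -> EvalResult:
    """Median/[Q1; Q3] of each metric plus the summed-confusion recalls.

    Quartiles use the linear-interpolation quantile convention.
    """
    if not repetitions:
        raise ValueError("no repetitions to aggregate")
    rows = {}
    for name in ("balanced_acc", "general_acc", "train_acc"):
        vals = np.array([getattr(r, name) for r in repetitions], dtype=float)
        rows[name] = [
            np.percentile(vals, 50),
            np.percentile(vals, 25),
            np.percentile(vals, 75),
        ]
    metrics = pd.DataFrame.from_dict(
        rows, orient="index", columns=["median", "q1", "q3"]
    )
    summed = sum(
        (r.conf.reindex(index=classes, columns=classes, fill_value=0)
         for r in repetitions),
        start=pd.DataFrame(0, index=classes, columns=classes),
    )
    with np.errstate(invalid="ignore"):
        per_class = np.diag(summed.to_numpy()) / summed.sum(axis=1).to_numpy()
    per_class_acc = pd.Series(per_class, index=classes)
    return EvalResult(classes, repetitions, metrics, summed, per_class_acc)
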