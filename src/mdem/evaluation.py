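"""k-fold and stratified k-fold cross-validation with binary metrics.

Works with any estimator exposing ``fit(X, y)`` and ``predict(X)`` — the
moment-displacement models here or wrapped scikit-learn baselines.  A
fresh model is built per fold; class states never leak across folds.

Accuracy is reported as the mean of per-fold accuracies (one number per
configuration).  Precision, recall, F1 and Matthews correlation are
computed on the confusion matrix pooled over folds, which is stabler for
small folds than averaging per-fold ratios; per-fold matrices are also
kept.  The positive class defaults to the minority label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "CVResult",
    "kfold_split",
    "stratified_kfold_split",
    "confusion_matrix",
    "metrics",
    "cross_validate",
    "SklearnAdapter",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class Metrics:
    """Binary scores; undefined ratios are reported as 0 and flagged."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


@dataclass
class CVResult:
    """Fold assignments, per-fold and pooled confusion matrices, scores."""

    folds: np.ndarray
    fold_matrices: list
    fold_accuracies: list
    pooled: ConfusionMatrix
    aggregate: Metrics
    mean_accuracy: float
    seed: int
    positive_label: object = None
    per_fold_metrics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "positive_label": self.positive_label,
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "fold_matrices": [m.to_dict() for m in self.fold_matrices],
            "pooled_matrix": self.pooled.to_dict(),
            "aggregate": self.aggregate.to_dict(),
        }


def kfold_split(n_rows: int, k: int, seed: int) -> np.ndarray:
    """Assign each row to one of k folds after a seeded shuffle.

    Fold sizes are floor(n/k) or ceil(n/k); the remainder rows spread
    over the first folds.
    """
    if not 2 <= k <= n_rows:
        raise ValueError(f"k must be in [2, n_rows]; got k={k}, n_rows={n_rows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    folds = np.empty(n_rows, dtype=int)
    sizes = np.full(k, n_rows // k)
    sizes[: n_rows % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        folds[perm[start : start + size]] = f
        start += size
    return folds


def stratified_kfold_split(labels, k: int, seed: int) -> np.ndarray:
    """Fold assignment preserving class proportions within +/- 1 row.

    Each class's rows are shuffled (seeded) then dealt round-robin over
    the folds, so every fold holds floor or ceil of its share of each
    class.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n_rows]; got k={k}, n_rows={n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for c in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} rows, fewer than k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def confusion_matrix(y_true, y_pred, positive_label) -> ConfusionMatrix:
    """2x2 confusion matrix one-vs-rest for the declared positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
    )


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, recall, F1 and Matthews correlation from a 2x2.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    denominator yields 0 with the metric name flagged as undefined.
    """
    if min(cm.tp, cm.fp, cm.fn, cm.tn) < 0:
        raise ValueError("confusion-matrix entries must be non-negative")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom > 0:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / sqrt(denom)
    else:
        mcc, undefined = 0.0, undefined + ["mcc"]
    return Metrics(accuracy, precision, recall, f1, mcc, tuple(undefined))


class SklearnAdapter:
    """Wrap a scikit-learn estimator factory behind the fit/predict contract.

    Lets the comparison harness run existing baseline implementations
    (logistic regression, random forests, SVMs, nearest neighbours,
    multilayer perceptrons) through the same cross-validation driver as
    the moment-displacement models.
    """

    def __init__(self, factory, seed: int | None = None):
        self.factory = factory
        self.seed = seed
        self.est_ = None

    def fit(self, X, y):
        try:
            self.est_ = self.factory(random_state=self.seed)
        except TypeError:  # estimator without randomness (e.g. KNN)
            self.est_ = self.factory()
        self.est_.fit(X, y)
        return self

    def predict(self, X):
        return self.est_.predict(X)


def cross_validate(
    model_factory,
    X,
    y,
    k: int = 5,
    stratified: bool = False,
    seed: int = 0,
    positive_label=None,
) -> CVResult:
    """k-fold CV of a fit/predict estimator, fresh model per fold.

    ``model_factory()`` must return an unfitted estimator.  Each fold is
    held out once; the model trains on the other k-1 folds and predicts
    the held-out rows in their original order.  An evolving model commits
    its held-out predictions within the fold, but the next fold starts
    from a fresh model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = (
        stratified_kfold_split(y, k, seed) if stratified else kfold_split(len(y), k, seed)
    )
    if positive_label is None:
        labels, counts = np.unique(y, return_counts=True)
        positive_label = labels[np.argmin(counts)]
    fold_matrices, fold_accuracies, per_fold_metrics = [], [], []
    for f in range(k):
        test_mask = folds == f
        train_y = y[~test_mask]
        for c in set(y.tolist()):
            if c not in train_y:
                raise ValueError(f"training split of fold {f} is missing class {c!r}")
        model = model_factory()
        model.fit(X[~test_mask], train_y)
        pred = np.asarray(model.predict(X[test_mask]))
        cm = confusion_matrix(y[test_mask], pred, positive_label)
        fold_matrices.append(cm)
        fold_accuracies.append(float((pred == y[test_mask]).mean()))
        per_fold_metrics.append(metrics(cm))
    pooled = sum(fold_matrices[1:], start=fold_matrices[0])
    return CVResult(
        folds=folds,
        fold_matrices=fold_matrices,
        fold_accuracies=fold_accuracies,
        pooled=pooled,
        aggregate=metrics(pooled),
        mean_accuracy=float(np.mean(fold_accuracies)),
        seed=seed,
        positive_label=positive_label,
        per_fold_metrics=per_fold_metrics,
    )
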