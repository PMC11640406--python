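"""1-NN classification with stratified cross-validation.

The classifier is deliberately minimal: k-nearest neighbours under the L1
(cityblock) distance, default k = 1.  Distance ties go to the lowest training
row index so predictions are deterministic; with k = 1 vote ties cannot occur.
Evaluation pools out-of-fold predictions from a seeded stratified K-fold split
and reports accuracy, per-class recalls, their geometric mean (G-mean), and
the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("at least 2 folds are required")


@dataclass
class EvalReport:
    """Pooled cross-validation outcome."""

    predictions: np.ndarray  # out-of-fold predicted label per beat
    confusion: np.ndarray  # K×K, rows = true class, columns = predicted
    accuracy: float  # percent
    geometric_mean: float  # percent
    per_class_recall: np.ndarray  # fractions, length K
    folds_used: int
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "geometric_mean_percent": self.geometric_mean,
            "per_class_recall": self.per_class_recall.tolist(),
            "confusion": self.confusion.tolist(),
            "folds_used": self.folds_used,
            "classes": self.classes.tolist(),
        }


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int = 1,
    metric: str = "l1",
) -> np.ndarray:
    """Predict test labels from their k nearest training rows under L1 distance.

    For k = 1 each test row takes the label of its closest training row
    (lowest index on ties); for k > 1, majority vote with ties going to the
    smallest label.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    if metric not in ("l1", "cityblock", "manhattan"):
        raise ValueError(f"unsupported metric: {metric!r}")
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if k < 1 or k > train_X.shape[0]:
        raise ValueError(f"k must be in 1..{train_X.shape[0]}, got {k}")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature counts differ")
    D = cdist(test_X, train_X, metric="cityblock")
    if k == 1:
        return train_y[np.argmin(D, axis=1)]
    # stable sort keeps lowest-index neighbours first among equal distances
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    preds = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i, row in enumerate(nn):
        labels, counts = np.unique(train_y[row], return_counts=True)
        preds[i] = labels[np.argmax(counts)]  # first max -> smallest label
    return preds


def _resolve_folds(y: np.ndarray, cv: CVConfig) -> int:
    """Reduce fold count when the smallest class cannot populate every fold."""
    if not cv.stratified:
        return min(cv.folds, len(y))
    counts = np.unique(y, return_counts=True)[1]
    min_count = int(counts.min())
    if min_count < cv.folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing folds "
            f"from {cv.folds} to {min_count}"
        )
        return max(2, min_count)
    return cv.folds


def fold_indices(y: np.ndarray, cv: CVConfig) -> list[np.ndarray]:
    """Seeded (stratified) fold test-index arrays covering every row once."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs at least two classes")
    folds = _resolve_folds(y, cv)
    splitter_cls = StratifiedKFold if cv.stratified else KFold
    splitter = splitter_cls(n_splits=folds, shuffle=True, random_state=cv.seed)
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def oof_predictions_from_distances(
    D: np.ndarray, y: np.ndarray, folds: list[np.ndarray]
) -> np.ndarray:
    """Pooled 1-NN out-of-fold predictions from a precomputed distance matrix.

    Sharing one pairwise matrix across many feature subsets (the iterative
    selector's prefix loop) avoids recomputing distances per subset.
    """
    y = np.asarray(y)
    pred = np.empty_like(y)
    all_idx = np.arange(len(y))
    for test in folds:
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        sub = D[np.ix_(test, train)]
        pred[test] = y[train[np.argmin(sub, axis=1)]]
    return pred


def geometric_mean(confusion: np.ndarray) -> float:
    """G-mean in percent: K-th root of the product of per-class recalls."""
    confusion = np.asarray(confusion, dtype=float)
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("confusion matrix has an empty class row; recall undefined")
    recalls = np.diag(confusion) / row_sums
    if np.any(recalls == 0):
        return 0.0
    return float(100.0 * np.exp(np.mean(np.log(recalls))))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (np.asarray(y_true) - 1, np.asarray(y_pred) - 1), 1)
    return mat


def report_from_predictions(y: np.ndarray, pred: np.ndarray, folds_used: int) -> EvalReport:
    y = np.asarray(y)
    classes = np.unique(y)
    conf = confusion_matrix(y, pred, int(classes.max()))
    recalls = np.diag(conf) / conf.sum(axis=1)
    acc = float(100.0 * np.trace(conf) / conf.sum())
    return EvalReport(
        predictions=pred,
        confusion=conf,
        accuracy=acc,
        geometric_mean=geometric_mean(conf),
        per_class_recall=recalls,
        folds_used=folds_used,
        classes=classes,
    )


def cross_validate(X: np.ndarray, y: np.ndarray, cv: CVConfig | None = None) -> EvalReport:
    """Stratified K-fold 1-NN evaluation with pooled out-of-fold predictions."""
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = fold_indices(y, cv)
    D = cdist(X, X, metric="cityblock")
    pred = oof_predictions_from_distances(D, y, folds)
    return report_from_predictions(y, pred, len(folds))
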