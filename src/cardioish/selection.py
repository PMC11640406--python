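"""Iterative NCA feature selection.

Feature weighting follows the neighbourhood component analysis (NCA) soft
nearest-neighbour objective with per-feature weights and an L1 base distance:

    F(w) = (1/NE) * sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_f w_f^2
    p_ij = exp(-d_ij) / sum_{k != i} exp(-d_ik)
    d_ij = sum_f w_f^2 * |x_if - x_jf|

maximized deterministically with L-BFGS-B from w = 1 (optional seeded jitter
is off by default).  Features are ranked by w_f^2 descending, ties to the
lower feature index.

The iterative stage then evaluates growing prefixes of the ranking with a
1-NN misclassification rate under one fixed stratified fold partition —
the same folds for every prefix size, so the loss curve is comparable across
sizes — and keeps the shortest prefix attaining the minimum loss.

Note the methodological caveat inherited from this selection style: the
ranking and the prefix losses use the labels of all beats, so a subsequent
cross-validation on the same data is optimistically biased.  A nested mode
(selection redone inside each training fold) is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .classify import (
    CVConfig,
    EvalReport,
    fold_indices,
    knn_predict,
    oof_predictions_from_distances,
    report_from_predictions,
)
from .features import DEFAULT_EPSILON


@dataclass(frozen=True)
class NCAConfig:
    """Hyperparameters of the NCA weight fit.

    ``regularization`` defaults to 1/NE when None; ``init_jitter`` adds a
    seeded uniform perturbation to the all-ones start (off by default, the
    fit is then fully deterministic).
    """

    regularization: float | None = None
    max_iterations: int = 100
    tolerance: float = 1e-6
    seed: int = 0
    init_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.regularization is not None and self.regularization < 0:
            raise ValueError("regularization must be nonnegative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SelectionResult:
    """Full record of one INCA run."""

    weights: np.ndarray  # learned NCA weights, length n_features
    ranking: np.ndarray  # 1-based feature indexes by decreasing weight^2
    loss: np.ndarray  # misclassification rate per prefix size start..stop
    start: int
    stop: int
    chosen_size: int  # smallest prefix size attaining min loss
    sel_indexes: np.ndarray  # 1-based chosen feature indexes (ranking prefix)
    folds_used: int = 0

    @property
    def min_loss(self) -> float:
        return float(self.loss.min())

    def selected_columns(self, X: np.ndarray) -> np.ndarray:
        """Sub-matrix of X restricted to the chosen features, ranking order."""
        return np.asarray(X)[:, self.sel_indexes - 1]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "ranking_1based": self.ranking.tolist(),
            "loss_curve": self.loss.tolist(),
            "start": self.start,
            "stop": self.stop,
            "chosen_size": self.chosen_size,
            "chosen_indexes_1based": self.sel_indexes.tolist(),
            "folds_used": self.folds_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            ranking=np.asarray(d["ranking_1based"], dtype=int),
            loss=np.asarray(d["loss_curve"], dtype=float),
            start=int(d["start"]),
            stop=int(d["stop"]),
            chosen_size=int(d["chosen_size"]),
            sel_indexes=np.asarray(d["chosen_indexes_1based"], dtype=int),
            folds_used=int(d.get("folds_used", 0)),
        )


def minmax_normalize(X: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Column-wise (x - min) / (max - min + epsilon); constant columns -> zeros."""
    X = np.asarray(X, dtype=float)
    mins = X.min(axis=0, keepdims=True)
    maxs = X.max(axis=0, keepdims=True)
    return (X - mins) / (maxs - mins + epsilon)


def _nca_negloss_and_grad(w, A, same, lam, n):
    """Negated NCA objective and gradient; A is |x_if - x_jf|, (n, n, F)."""
    w2 = w * w
    d = np.tensordot(A, w2, axes=([2], [0]))  # (n, n)
    logits = -d
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    p_same = (P * same).sum(axis=1)  # p_i
    value = p_same.mean() - lam * w2.sum()
    # dF/dw_f = (2 w_f / n) sum_i [ p_i sum_k p_ik A_ikf - sum_{j same} p_ij A_ijf ]
    #           - 2 lam w_f
    weighted = P * p_same[:, None] - P * same
    grad = (2.0 * w / n) * np.tensordot(weighted, A, axes=([0, 1], [0, 1])) - 2.0 * lam * w
    return -value, -grad


def nca_weights(
    Xn: np.ndarray, y: np.ndarray, cfg: NCAConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fit NCA feature weights; returns (weights, 1-based ranking).

    Memory is O(n^2 * n_features) for the cached per-feature distance tensor,
    so this is meant for beat counts in the hundreds to low thousands.
    """
    cfg = cfg or NCAConfig()
    Xn = np.asarray(Xn, dtype=float)
    y = np.asarray(y)
    n, F = Xn.shape
    if n < 4:
        raise ValueError("NCA needs at least 4 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("NCA needs at least two classes")
    lam = cfg.regularization if cfg.regularization is not None else 1.0 / n
    A = np.abs(Xn[:, None, :] - Xn[None, :, :])  # (n, n, F)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    w0 = np.ones(F)
    if cfg.init_jitter > 0:
        rng = np.random.default_rng(cfg.seed)
        w0 = w0 + rng.uniform(-cfg.init_jitter, cfg.init_jitter, size=F)
    res = minimize(
        _nca_negloss_and_grad,
        w0,
        args=(A, same, lam, n),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iterations, "ftol": cfg.tolerance},
    )
    w = res.x
    w2 = w * w
    # snap negligible weights to zero so the heavy-regularization limit falls
    # back to index order through the stable tie rule
    w2 = np.where(w2 < 1e-12 * max(1.0, w2.max()), 0.0, w2)
    ranking = np.argsort(-w2, kind="stable") + 1  # ties -> lower index
    return w, ranking


def evaluate_prefixes(
    Xn: np.ndarray,
    y: np.ndarray,
    ranking: np.ndarray,
    start: int = 1,
    stop: int | None = None,
    cv: CVConfig | None = None,
) -> tuple[np.ndarray, int]:
    """1-NN misclassification rate of each ranking prefix, sizes start..stop.

    One fixed seeded fold partition is reused for every prefix size; L1
    distances are accumulated column-by-column so the whole sweep costs one
    pass over the pairwise matrix per added feature.
    Returns (loss curve, folds actually used).
    """
    cv = cv or CVConfig()
    Xn = np.asarray(Xn, dtype=float)
    y = np.asarray(y)
    ranking = np.asarray(ranking, dtype=int)
    stop = stop if stop is not None else len(ranking)
    if not (1 <= start <= stop <= len(ranking)):
        raise ValueError(f"need 1 <= start <= stop <= {len(ranking)}")
    folds = fold_indices(y, cv)
    n = len(y)
    D = np.zeros((n, n))
    loss = np.empty(stop - start + 1)
    for j in range(1, stop + 1):
        col = Xn[:, ranking[j - 1] - 1]
        D += np.abs(col[:, None] - col[None, :])
        if j >= start:
            pred = oof_predictions_from_distances(D, y, folds)
            loss[j - start] = float(np.mean(pred != y))
    return loss, len(folds)


def choose(loss: np.ndarray, start: int = 1) -> int:
    """Smallest prefix size attaining the minimum loss (greedy argmin)."""
    loss = np.asarray(loss)
    if loss.size == 0:
        raise ValueError("empty loss curve")
    return start + int(np.argmin(loss))  # argmin returns the first minimum


def inca(
    X: np.ndarray,
    y: np.ndarray,
    start: int = 1,
    stop: int | None = None,
    nca_config: NCAConfig | None = None,
    cv: CVConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> SelectionResult:
    """Full iterative-NCA selection: normalize, weight, sweep prefixes, choose."""
    X = np.asarray(X, dtype=float)
    stop = stop if stop is not None else X.shape[1]
    Xn = minmax_normalize(X, epsilon)
    weights, ranking = nca_weights(Xn, y, nca_config)
    loss, folds_used = evaluate_prefixes(Xn, y, ranking, start, stop, cv)
    chosen = choose(loss, start)
    return SelectionResult(
        weights=weights,
        ranking=ranking,
        loss=loss,
        start=start,
        stop=stop,
        chosen_size=chosen,
        sel_indexes=ranking[:chosen].copy(),
        folds_used=folds_used,
    )


def nested_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    start: int = 1,
    stop: int | None = None,
    nca_config: NCAConfig | None = None,
    cv: CVConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> EvalReport:
    """Selection-bias-free evaluation: INCA rerun inside each training fold.

    The default (non-nested) pipeline selects features on all labels before
    cross-validating, which inflates accuracy; here each outer fold's test
    beats never influence the ranking or the prefix choice that classifies
    them.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = fold_indices(y, cv)
    pred = np.empty_like(y)
    all_idx = np.arange(len(y))
    for test in folds:
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        inner = inca(X[train], y[train], start, stop, nca_config, cv, epsilon)
        cols = inner.sel_indexes - 1
        # apply the training fold's min-max scaling to both sides
        mins = X[train][:, cols].min(axis=0)
        maxs = X[train][:, cols].max(axis=0)
        denom = maxs - mins + epsilon
        pred[test] = knn_predict(
            (X[train][:, cols] - mins) / denom,
            y[train],
            (X[test][:, cols] - mins) / denom,
        )
    return report_from_predictions(y, pred, len(folds))
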