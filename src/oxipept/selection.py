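"""Split-importance feature ranking and top-k subset sweeping.

A gradient-boosted decision-tree ensemble (LGBM) is fitted to the encoded
training data, and each feature's importance is its *split count* — the
number of tree nodes across the whole ensemble that split on it:

    importance(f) = sum over trees t, nodes n of 1[ split feature of (t,n) == f ]

Features are ranked by descending split count (ties broken by original
feature index, so rankings are stable), and nested top-k prefixes are
swept with an RBF-SVM to find the most compact subset that preserves
accuracy.  By default each candidate k is scored by stratified 5-fold
cross-validation on the training split; ``paper_mode=True`` instead
scores on the supplied held-out evaluation set, reproducing the published
protocol at the cost of using test data for selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classification import FINAL_SVM_PARAMS, predict, train_classifier
from .encoders import FeatureBlock
from .evaluation import MetricsReport, cross_validate, evaluate_predictions

__all__ = [
    "FeatureRanking",
    "SweepResult",
    "default_sweep_grid",
    "rank_features",
    "sweep_topk",
    "apply_selection",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Feature indices in descending split-count order."""

    order: tuple[int, ...]
    importance: tuple[int, ...]  # aligned with order, non-increasing
    trainer_seed: int

    def __post_init__(self) -> None:
        n = len(self.order)
        if sorted(self.order) != list(range(n)):
            raise ValueError("order must be a permutation of feature indices")
        imp = np.asarray(self.importance)
        if imp.shape != (n,) or np.any(imp < 0):
            raise ValueError("importance must be non-negative and aligned with order")
        if np.any(np.diff(imp) > 0):
            raise ValueError("importance must be non-increasing along order")

    def top(self, k: int) -> tuple[int, ...]:
        if not 0 < k <= len(self.order):
            raise ValueError(f"k must be in 1..{len(self.order)}, got {k}")
        return self.order[:k]


@dataclass(frozen=True)
class SweepResult:
    grid: tuple[int, ...]
    per_k_metrics: tuple[MetricsReport, ...]
    best_k: int
    selection_rule: str

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(set(self.grid)):
            raise ValueError("grid must be strictly increasing")
        if self.best_k not in self.grid:
            raise ValueError("best_k must be a grid member")


def default_sweep_grid(total_dim: int | None = None) -> list[int]:
    """The k = 5, 10, ..., 300 sweep grid (clipped to the feature count)."""
    grid = list(range(5, 301, 5))
    if total_dim is not None:
        grid = [k for k in grid if k <= total_dim]
    return grid


def rank_features(
    X: np.ndarray, y: Sequence[int], *, seed: int = 0, n_estimators: int = 100
) -> FeatureRanking:
    """Rank features by LGBM split counts, descending.

    Deterministic given the seed; every feature receives a count (possibly
    zero — a constant feature is never split on and ranks last among its
    tie group, i.e. by original index).
    """
    from lightgbm import LGBMClassifier

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be finite")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"need >= 2 samples per class, got {counts.tolist()}")
    clf = LGBMClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    clf.fit(X, y)
    splits = clf.booster_.feature_importance(importance_type="split")
    splits = np.asarray(splits, dtype=np.int64)
    # stable argsort on -splits keeps original index order within ties
    order = np.argsort(-splits, kind="stable")
    return FeatureRanking(
        order=tuple(int(i) for i in order),
        importance=tuple(int(splits[i]) for i in order),
        trainer_seed=seed,
    )


def sweep_topk(
    X_train: np.ndarray,
    y_train: Sequence[int],
    ranking: FeatureRanking,
    grid: Sequence[int] | None = None,
    *,
    X_eval: np.ndarray | None = None,
    y_eval: Sequence[int] | None = None,
    paper_mode: bool = False,
    svm_params: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Sweep nested top-k feature prefixes with an RBF-SVM.

    For each k in the grid the SVM is trained on the top-k ranked columns
    and scored either by stratified ``folds``-fold CV on the training data
    (default) or on the held-out ``(X_eval, y_eval)`` set when
    ``paper_mode=True``.  ``best_k`` maximizes ACC with MCC as tie-break;
    remaining ties resolve to the smallest k (parsimony).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if grid is None:
        grid = default_sweep_grid(X_train.shape[1])
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("sweep grid is empty")
    if grid[-1] > X_train.shape[1]:
        raise ValueError(
            f"grid max {grid[-1]} exceeds feature count {X_train.shape[1]}"
        )
    if paper_mode and (X_eval is None or y_eval is None):
        raise ValueError("paper_mode requires an evaluation set")
    params = dict(svm_params or FINAL_SVM_PARAMS)

    reports: list[MetricsReport] = []
    for k in grid:
        cols = list(ranking.top(k))
        if paper_mode:
            model = train_classifier(
                X_train[:, cols], y_train, "svm", params, seed=seed
            )
            labels, scores = predict(model, np.asarray(X_eval, dtype=float)[:, cols])
            reports.append(evaluate_predictions(np.asarray(y_eval, dtype=int), labels, scores))
        else:
            mean, _ = cross_validate(
                X_train[:, cols], y_train, "svm", params, folds=folds, seed=seed
            )
            reports.append(mean)

    best_i = 0
    for i in range(1, len(grid)):
        r, b = reports[i], reports[best_i]
        if (r.ACC, r.MCC) > (b.ACC, b.MCC):
            best_i = i
    rule = (
        "max ACC on held-out eval set, MCC tie-break, smallest k"
        if paper_mode
        else f"max mean {folds}-fold CV ACC on training set, MCC tie-break, smallest k"
    )
    return SweepResult(
        grid=tuple(grid),
        per_k_metrics=tuple(reports),
        best_k=grid[best_i],
        selection_rule=rule,
    )


def apply_selection(block: FeatureBlock, ranking: FeatureRanking, k: int) -> FeatureBlock:
    """Project a feature block onto the top-k ranked dimensions.

    The result lists values in ranking order with their original labels;
    selecting k then k' < k equals selecting k' directly (nestedness).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > block.dim:
        raise ValueError(f"k={k} exceeds block dimension {block.dim}")
    if len(ranking.order) != block.dim:
        raise ValueError(
            f"ranking covers {len(ranking.order)} features, block has {block.dim}"
        )
    cols = list(ranking.top(k))
    return FeatureBlock(
        name=f"{block.name}.top{k}",
        values=block.values[cols],
        labels=tuple(block.labels[i] for i in cols),
    )
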