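"""Model evaluation: the seven metrics, cross-validation, the Friedman
rank test, and 2-D embedding for qualitative feature-space inspection.

Metric definitions (from confusion counts TP/TN/FP/FN):

    ACC = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Sp  = TN / (TN + FP)                      (specificity)
    Pre = TP / (TP + FP)                      (precision)
    F1  = 2 * Pre * Sn / (Pre + Sn)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    AUC = rank-based area under the ROC curve (needs real-valued scores)

Zero-denominator policy: Sn/Sp/Pre/F1 report 0 with a logged warning when
their denominator is 0; MCC reports 0 when any marginal is 0.  This keeps
degenerate classifiers comparable instead of propagating NaN.

The Friedman test ranks k treatments within each of N blocks and tests
whether the rank sums R_j could arise under exchangeability:

    chi2_F = 12 / (N k (k+1)) * sum_j R_j^2  -  3 N (k+1)

with a chi-square reference distribution on k-1 degrees of freedom.  Ties
receive average ranks; the classical statistic above has no tie
correction, so a tie-corrected variant is reported alongside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FriedmanResult",
    "Embedding2D",
    "confusion_from_predictions",
    "compute_metrics",
    "cross_validate",
    "friedman_test",
    "embed_2d",
]

#: Metrics averaged into the grid-comparison summary score
#: (all independently tested metrics except F1).
MEAN_SCORE_METRICS = ("ACC", "MCC", "Sn", "Sp", "AUC", "Pre")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    MCC: float
    Sn: float
    Sp: float
    Pre: float
    AUC: float
    F1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.ACC, "MCC": self.MCC, "Sn": self.Sn, "Sp": self.Sp,
            "Pre": self.Pre, "AUC": self.AUC, "F1": self.F1,
        }

    @property
    def mean_score(self) -> float:
        """Mean of ACC, MCC, Sn, Sp, AUC, Pre — the grid comparison score."""
        d = self.as_dict()
        return float(np.mean([d[m] for m in MEAN_SCORE_METRICS]))


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    scores: tuple[Sequence[float], Sequence[int]] | None = None,
) -> MetricsReport:
    """Compute the seven-metric report from confusion counts.

    ``scores`` is an optional ``(score, label)`` pair of parallel arrays
    used for AUC; without it AUC is reported as 0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    acc = (tp + tn) / counts.total
    sn = _safe_div(tp, tp + fn, "Sn")
    sp = _safe_div(tn, tn + fp, "Sp")
    pre = _safe_div(tp, tp + fp, "Pre")
    f1 = _safe_div(2 * pre * sn, pre + sn, "F1")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC undefined (zero marginal); reporting 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    if scores is not None:
        s, y = scores
        auc = float(roc_auc_score(np.asarray(y, dtype=int), np.asarray(s, dtype=float)))
    else:
        logger.warning("AUC requires scores; reporting 0")
        auc = 0.0
    return MetricsReport(
        ACC=float(acc), MCC=float(mcc), Sn=float(sn), Sp=float(sp),
        Pre=float(pre), AUC=auc, F1=float(f1),
    )


def evaluate_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Convenience wrapper: confusion counts + metrics in one call."""
    counts = confusion_from_predictions(y_true, y_pred)
    return compute_metrics(
        counts, (scores, y_true) if scores is not None else None
    )


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    algorithm: str,
    hyperparameters: dict | None = None,
    *,
    folds: int = 5,
    seed: int = 0,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold cross-validation of one classifier configuration.

    Returns the metric-wise mean report and the per-fold reports.  Fold
    assignment is deterministic given the seed.
    """
    from sklearn.model_selection import StratifiedKFold

    from .classification import predict, train_classifier

    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_classifier(
            X[train_idx], y[train_idx], algorithm, hyperparameters, seed=seed
        )
        labels, scores = predict(model, X[test_idx])
        fold_reports.append(evaluate_predictions(y[test_idx], labels, scores))
    mean = MetricsReport(
        **{
            k: float(np.mean([r.as_dict()[k] for r in fold_reports]))
            for k in fold_reports[0].as_dict()
        }
    )
    return mean, fold_reports


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    chi2_tie_corrected: float
    N: int
    k: int
    rank_sums: tuple[float, ...]
    p_value: float

    def __post_init__(self) -> None:
        expected = self.N * self.k * (self.k + 1) / 2
        if abs(sum(self.rank_sums) - expected) > 1e-8:
            raise ValueError("rank sums do not total N*k*(k+1)/2")


def friedman_test(scores: np.ndarray) -> FriedmanResult:
    """Friedman rank test on an (N blocks x k treatments) score matrix.

    Within each block the k treatments are ranked (average ranks on ties,
    rank 1 = smallest).  The classical chi-square statistic is reported
    together with a tie-corrected variant; the p-value uses the corrected
    statistic against chi-square with k-1 degrees of freedom.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {scores.shape}")
    N, k = scores.shape
    if N < 2 or k < 2:
        raise ValueError(f"need N >= 2 blocks and k >= 2 treatments, got {N}x{k}")
    ranks = np.vstack([stats.rankdata(row) for row in scores])
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (N * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * N * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (N k (k^2 - 1))
    tie_term = 0.0
    for row in scores:
        _, t = np.unique(row, return_counts=True)
        tie_term += float(np.sum(t**3 - t))
    correction = 1.0 - tie_term / (N * k * (k**2 - 1))
    chi2_corr = chi2 / correction if correction > 0 else float("nan")
    p = float(stats.chi2.sf(chi2_corr, df=k - 1)) if np.isfinite(chi2_corr) else 1.0
    return FriedmanResult(
        chi2=float(chi2),
        chi2_tie_corrected=float(chi2_corr),
        N=N,
        k=k,
        rank_sums=tuple(float(r) for r in rank_sums),
        p_value=p,
    )


@dataclass(frozen=True)
class Embedding2D:
    coordinates: np.ndarray  # (n, 2)
    parameters: dict
    seed: int


#: Default projection parameters for feature-space visualization.
DEFAULT_EMBED_PARAMS = {
    "metric": "wminkowski",
    "n_neighbors": 10,
    "min_dist": 0.2,
    "target_weight": 0.2,
}


def embed_2d(
    X: np.ndarray,
    labels: Sequence[int] | None = None,
    parameters: dict | None = None,
    *,
    seed: int = 0,
) -> Embedding2D:
    """Project a feature matrix to 2-D with UMAP (supervised if labels given).

    Deterministic given the seed.  The weighted-Minkowski metric defaults
    to uniform weights (plain Minkowski, p=2) unless ``metric_kwds`` is
    supplied in ``parameters``.
    """
    import umap  # deferred: numba JIT import cost

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError(f"need >= 10 records to embed, got {X.shape[0]}")
    params = dict(DEFAULT_EMBED_PARAMS)
    if parameters:
        params.update(parameters)
    if X.shape[0] <= params["n_neighbors"]:
        raise ValueError(
            f"n_neighbors={params['n_neighbors']} needs > that many records"
        )
    metric = params["metric"]
    metric_kwds = params.get("metric_kwds")
    if metric == "wminkowski" and not metric_kwds:
        metric_kwds = {"w": np.ones(X.shape[1]), "p": 2}
    reducer = umap.UMAP(
        n_components=2,
        metric=metric,
        metric_kwds=metric_kwds,
        n_neighbors=params["n_neighbors"],
        min_dist=params["min_dist"],
        target_weight=params["target_weight"],
        random_state=seed,
    )
    y = np.asarray(labels, dtype=int) if labels is not None else None
    coords = reducer.fit_transform(X, y=y)
    return Embedding2D(np.asarray(coords), params, seed)
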