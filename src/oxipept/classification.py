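"""Train/test splitting, the six baseline classifier families, and the
final RBF-SVM.

The classifier grid spans six families — SVM, gradient-boosted trees
(LGBM), logistic regression, random forest, k-nearest neighbours, and
Gaussian naive Bayes — each at library-default hyperparameters with a
fixed seed.  The final deployed model is an RBF-kernel SVM at the tuned
operating point ``C = 2.782559402207126``, ``gamma = 0.005994842503189409``.

Scores used for ranking/AUC are the SVM's signed decision-function value
(no probability calibration) and the class-1 probability for the other
learners; both are monotone confidences, which is all AUC needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .encoders import FeatureSetSpec
from .sequence_io import LabeledDataset

__all__ = [
    "ALGORITHMS",
    "FINAL_SVM_PARAMS",
    "SplitSpec",
    "TrainedModel",
    "split_dataset",
    "train_classifier",
    "predict",
    "run_grid",
    "save_model",
    "load_model",
]

ALGORITHMS = ("svm", "lgbm", "lr", "rf", "knn", "gnb")

#: Operating point of the final RBF-SVM.
FINAL_SVM_PARAMS = {
    "kernel": "rbf",
    "C": 2.782559402207126,
    "gamma": 0.005994842503189409,
}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split configuration (default 8:2)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it.

    ``selected_indices``, when present, is applied to incoming feature
    matrices before prediction, so callers always pass full-width
    encodings.
    """

    algorithm: str
    hyperparameters: dict
    feature_spec: FeatureSetSpec | None
    selected_indices: list[int] | None
    estimator: object
    training_seed: int
    training_dim: int

    def _project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected_indices is not None:
            expected_full = self.training_dim
            if X.shape[1] == len(self.selected_indices):
                return X  # already projected
            if X.shape[1] < max(self.selected_indices) + 1:
                raise ValueError(
                    f"dim mismatch: expected >= {max(self.selected_indices) + 1} "
                    f"(full encoding) or {len(self.selected_indices)} (selected), "
                    f"got {X.shape[1]}"
                )
            return X[:, self.selected_indices]
        if X.shape[1] != self.training_dim:
            raise ValueError(
                f"dim mismatch: expected {self.training_dim}, got {X.shape[1]}"
            )
        return X


def split_dataset(
    data: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random split into train/test, deterministic given seed.

    Per class, floor((1 - train_fraction) * n_class) records go to the
    test set; a balanced 3022-sample set at 8:2 yields 604 test records.
    """
    y = np.asarray(data.labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts.tolist()}")
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    classes = np.unique(y) if spec.stratified else [None]
    for cls in classes:
        idx = np.flatnonzero(y == cls) if cls is not None else np.arange(len(y))
        n_test = int(np.floor((1.0 - spec.train_fraction) * idx.size))
        n_test = max(n_test, 1)
        chosen = rng.permutation(idx)[:n_test]
        test_idx.extend(int(i) for i in chosen)
    test_set = sorted(test_idx)
    train_set = [i for i in range(len(y)) if i not in set(test_set)]
    return data.subset(train_set), data.subset(test_set)


def _make_estimator(algorithm: str, hyperparameters: dict | None, seed: int):
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    hp = dict(hyperparameters or {})
    if algorithm == "svm":
        hp.setdefault("kernel", FINAL_SVM_PARAMS["kernel"])
        hp.setdefault("C", FINAL_SVM_PARAMS["C"])
        hp.setdefault("gamma", FINAL_SVM_PARAMS["gamma"])
        return SVC(random_state=seed, **hp)
    if algorithm == "lgbm":
        return LGBMClassifier(random_state=seed, verbose=-1, **hp)
    if algorithm == "lr":
        hp.setdefault("max_iter", 5000)
        return LogisticRegression(random_state=seed, **hp)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if algorithm == "gnb":
        return GaussianNB(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; valid: {list(ALGORITHMS)}")


def train_classifier(
    X: np.ndarray,
    y: Sequence[int],
    algorithm: str = "svm",
    hyperparameters: dict | None = None,
    *,
    seed: int = 0,
    feature_spec: FeatureSetSpec | None = None,
    selected_indices: Sequence[int] | None = None,
) -> TrainedModel:
    """Fit one classifier configuration.

    If ``selected_indices`` is given, training uses (and the model will
    apply) only those feature columns of the full-width encoding.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    bad_cols = np.flatnonzero(~np.all(np.isfinite(X), axis=0))
    if bad_cols.size:
        raise ValueError(f"non-finite values in feature column(s) {bad_cols[:5].tolist()}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    full_dim = X.shape[1]
    sel = list(int(i) for i in selected_indices) if selected_indices is not None else None
    if sel is not None:
        X = X[:, sel]
    est = _make_estimator(algorithm, hyperparameters, seed)
    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        hyperparameters=dict(hyperparameters or {}),
        feature_spec=feature_spec,
        selected_indices=sel,
        estimator=est,
        training_seed=seed,
        training_dim=full_dim,
    )


def predict(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and real-valued confidence scores.

    Scores are the SVM's decision-function value or, for probabilistic
    learners, the class-1 probability; in both cases larger means more
    confidently positive and thresholding at the decision boundary
    reproduces the label.
    """
    Xp = model._project(X)
    labels = np.asarray(model.estimator.predict(Xp), dtype=int)
    if hasattr(model.estimator, "decision_function"):
        scores = np.asarray(model.estimator.decision_function(Xp), dtype=float)
    else:
        scores = np.asarray(model.estimator.predict_proba(Xp)[:, 1], dtype=float)
    return labels, scores


def run_grid(
    train: LabeledDataset,
    test: LabeledDataset,
    resources,
    specs: Sequence[FeatureSetSpec] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
    *,
    seed: int = 0,
):
    """Evaluate every feature-set x algorithm combination on a held-out set.

    The full design — 15 encoder subsets crossed with the 6 classifier
    families — instantiates 90 configurations.  Each spec is encoded once;
    each cell reports the seven test-set metrics plus the summary
    ``mean_score`` (mean of ACC, MCC, Sn, Sp, AUC, Pre) used to compare
    cells.  Returns a pandas DataFrame with one row per cell.
    """
    import pandas as pd

    from .encoders import encode_dataset, enumerate_feature_sets
    from .evaluation import evaluate_predictions

    if specs is None:
        specs = enumerate_feature_sets()
    rows = []
    y_train = np.asarray(train.labels, dtype=int)
    y_test = np.asarray(test.labels, dtype=int)
    for spec in specs:
        X_train, _ = encode_dataset(train, spec, resources)
        X_test, _ = encode_dataset(test, spec, resources)
        for algo in algorithms:
            model = train_classifier(X_train, y_train, algo, seed=seed, feature_spec=spec)
            labels, scores = predict(model, X_test)
            report = evaluate_predictions(y_test, labels, scores)
            rows.append(
                {"feature_set": spec.name, "algorithm": algo}
                | report.as_dict()
                | {"mean_score": report.mean_score}
            )
    return pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model bundle: metadata JSON + opaque fitted state."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "algorithm": model.algorithm,
        "hyperparameters": model.hyperparameters,
        "feature_spec": list(model.feature_spec.members) if model.feature_spec else None,
        "selected_indices": model.selected_indices,
        "training_seed": model.training_seed,
        "training_dim": model.training_dim,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    joblib.dump(model.estimator, path / "estimator.joblib")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    estimator = joblib.load(path / "estimator.joblib")
    spec = (
        FeatureSetSpec(tuple(meta["feature_spec"])) if meta["feature_spec"] else None
    )
    return TrainedModel(
        algorithm=meta["algorithm"],
        hyperparameters=meta["hyperparameters"],
        feature_spec=spec,
        selected_indices=meta["selected_indices"],
        estimator=estimator,
        training_seed=meta["training_seed"],
        training_dim=meta["training_dim"],
    )
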