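"""Growth-class modeling harness.

Repeated k-fold cross-validation (5 splits x 5 repeats = 25 evaluations,
random state 1) around two grid-searched classifier kinds, SVM and random
forest.  Hyperparameters are selected by a nested inner 3-fold grid search
on each outer training portion (selection metric: accuracy), which keeps
model selection free of test-fold leakage; standard scaling is fit inside
each training portion for the same reason.  Each run yields 25 train/test
accuracy and f1-weighted samples plus pooled test predictions for confusion
analysis.

:class:`GrowthClassifier` is a scikit-learn estimator (fit/predict,
get_params/set_params) and composes with sklearn model selection; the
module-level functions are thin wrappers around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, RepeatedKFold, RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CVConfig",
    "HyperGrid",
    "GrowthClassifier",
    "ModelRunResult",
    "preprocess_features",
    "run_model",
    "f1_weighted",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Outer evaluation protocol: repeated k-fold."""

    splits: int = 5
    repeats: int = 5
    random_state: int = 1
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.splits < 2 or self.repeats < 1:
            raise ValueError("need splits >= 2 and repeats >= 1")

    @property
    def n_evaluations(self) -> int:
        return self.splits * self.repeats

    def splitter(self):
        cls = RepeatedStratifiedKFold if self.stratified else RepeatedKFold
        return cls(n_splits=self.splits, n_repeats=self.repeats, random_state=self.random_state)


#: Published full search grids.  The random-forest ``max_samples`` values are
#: absolute bootstrap sample counts as printed.
FULL_SVM_GRID: list[dict] = [
    {"clf__kernel": ["linear"], "clf__C": [0.001, 0.01, 0.1, 1, 10, 15, 20, 100, 1000]},
    {
        "clf__kernel": ["rbf"],
        "clf__C": [0.001, 0.01, 0.1, 1, 10, 15, 20, 100, 1000],
        "clf__gamma": [0.001, 0.01, 0.1, 1, 10],
    },
]
FULL_RFC_GRID: dict = {
    "clf__n_estimators": [25, 50, 100, 150, 300, 500],
    "clf__max_features": ["sqrt", "log2", None],
    "clf__max_depth": [3, 6, 9, 15, 20, 30],
    "clf__max_leaf_nodes": [3, 6, 9],
    "clf__max_samples": [2, 4, 6],
    "clf__min_samples_leaf": [1, 2, 4],
    "clf__criterion": ["entropy", "gini"],
}

#: Desk-scale grids: the same families, pruned to the informative ranges.
REDUCED_SVM_GRID: list[dict] = [
    {"clf__kernel": ["linear"], "clf__C": [0.1, 1, 10, 100]},
    {"clf__kernel": ["rbf"], "clf__C": [0.1, 1, 10, 100], "clf__gamma": [0.01, 0.1, 1]},
]
REDUCED_RFC_GRID: dict = {
    "clf__n_estimators": [100],
    "clf__max_features": ["sqrt"],
    "clf__max_depth": [6, 15, 30],
    "clf__criterion": ["gini"],
}


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grids for the two classifier kinds."""

    svm: Sequence[Mapping] = field(default_factory=lambda: [dict(g) for g in FULL_SVM_GRID])
    rfc: Mapping = field(default_factory=lambda: dict(FULL_RFC_GRID))
    reduced: bool = False

    @classmethod
    def desk_scale(cls) -> "HyperGrid":
        return cls(svm=[dict(g) for g in REDUCED_SVM_GRID], rfc=dict(REDUCED_RFC_GRID), reduced=True)

    def for_kind(self, kind: str):
        if kind == "svm":
            return list(self.svm)
        if kind == "rfc":
            return dict(self.rfc)
        raise ValueError(f"unknown classifier kind {kind!r}; use 'svm' or 'rfc'")


def f1_weighted(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1; absent-class F1 counts as 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


class GrowthClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched, standard-scaled classifier for ordinal growth classes.

    Parameters
    ----------
    kind : 'svm' or 'rfc'.
    grid : param grid (sklearn format, ``clf__`` prefixes) or None for the
        full published grid of the chosen kind.
    inner_cv : folds of the selection grid search (default 3).
    random_state : seeds the forest and the inner shuffling.
    """

    def __init__(self, kind: str = "svm", grid=None, inner_cv: int = 3, random_state: int = 1):
        self.kind = kind
        self.grid = grid
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _base(self):
        if self.kind == "svm":
            return SVC(random_state=self.random_state)
        if self.kind == "rfc":
            return RandomForestClassifier(random_state=self.random_state)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes to fit")
        grid = self.grid if self.grid is not None else HyperGrid().for_kind(self.kind)
        pipeline = Pipeline([("scale", StandardScaler()), ("clf", self._base())])
        search = GridSearchCV(pipeline, grid, scoring="accuracy", cv=self.inner_cv, n_jobs=1, refit=True)
        search.fit(X, y)
        self.search_ = search
        self.best_params_ = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
        self.classes_ = search.best_estimator_.named_steps["clf"].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "search_")
        return self.search_.predict(np.asarray(X, dtype=float))


@dataclass
class ModelRunResult:
    """Outcome of one repeated-CV evaluation of one classifier on one group."""

    classifier_kind: str
    feature_group: int | None
    train_accuracy: list[float]
    test_accuracy: list[float]
    train_f1_weighted: list[float]
    test_f1_weighted: list[float]
    selected_params: list[dict]
    pooled_y_true: np.ndarray
    pooled_y_pred: np.ndarray
    pooled_index: np.ndarray  # sample identifiers of the pooled predictions
    skipped_splits: int = 0

    def summary(self) -> dict[str, float]:
        return {
            "train_accuracy_mean": float(np.mean(self.train_accuracy)),
            "train_accuracy_std": float(np.std(self.train_accuracy)),
            "test_accuracy_mean": float(np.mean(self.test_accuracy)),
            "test_accuracy_std": float(np.std(self.test_accuracy)),
            "train_f1_weighted_mean": float(np.mean(self.train_f1_weighted)),
            "train_f1_weighted_std": float(np.std(self.train_f1_weighted)),
            "test_f1_weighted_mean": float(np.mean(self.test_f1_weighted)),
            "test_f1_weighted_std": float(np.std(self.test_f1_weighted)),
        }


def preprocess_features(table: pd.DataFrame, label_column: str = "growth_class") -> tuple[pd.DataFrame, dict]:
    """Drop rows with missing features; report reference scaler parameters.

    Scaling during modeling is re-fit on each training fold (leakage-safe);
    the parameters returned here describe the cleaned table as a whole.
    """
    feature_cols = [c for c in table.columns if c not in (label_column, "count", "excluded")]
    cleaned = table.dropna(subset=feature_cols)
    if "excluded" in table.columns:
        cleaned = cleaned[~cleaned["excluded"].astype(bool)]
    n_dropped = len(table) - len(cleaned)
    if n_dropped:
        logger.info("preprocess_features: dropped %d rows with missing features", n_dropped)
    labels = cleaned[label_column]
    present = labels.unique()
    lost = set(table[label_column].unique()) - set(present)
    if lost:
        logger.warning("preprocess_features: class(es) %s fully eliminated by cleaning", sorted(lost))
    if len(present) < 2:
        raise ValueError("fewer than two classes remain after cleaning")
    stats = cleaned[feature_cols]
    scaler = {
        "mean": stats.mean().to_dict(),
        "std": stats.std(ddof=0).to_dict(),
        "n_dropped": n_dropped,
    }
    return cleaned, scaler


def run_model(
    table: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    kind: str,
    grid: HyperGrid | None = None,
    cv: CVConfig | None = None,
    feature_group: int | None = None,
) -> ModelRunResult:
    """Repeated-CV evaluation with nested grid search; deterministic given
    the config's random state."""
    cv = cv or CVConfig()
    grid = grid or HyperGrid()
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")

    train_acc, test_acc, train_f1, test_f1, params = [], [], [], [], []
    pooled_true, pooled_pred, pooled_idx = [], [], []
    skipped = 0
    split_args = (X, y) if cv.stratified else (X,)
    for train_idx, test_idx in cv.splitter().split(*split_args):
        if np.unique(y[train_idx]).size < 2:
            skipped += 1
            logger.warning("run_model: skipping degenerate split (single class in training portion)")
            continue
        model = GrowthClassifier(kind=kind, grid=grid.for_kind(kind), random_state=cv.random_state)
        model.fit(X[train_idx], y[train_idx])
        yhat_train = model.predict(X[train_idx])
        yhat_test = model.predict(X[test_idx])
        train_acc.append(float(accuracy_score(y[train_idx], yhat_train)))
        test_acc.append(float(accuracy_score(y[test_idx], yhat_test)))
        train_f1.append(f1_weighted(y[train_idx], yhat_train))
        test_f1.append(f1_weighted(y[test_idx], yhat_test))
        params.append(model.best_params_)
        pooled_true.append(y[test_idx])
        pooled_pred.append(yhat_test)
        pooled_idx.append(test_idx)

    return ModelRunResult(
        classifier_kind=kind,
        feature_group=feature_group,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        train_f1_weighted=train_f1,
        test_f1_weighted=test_f1,
        selected_params=params,
        pooled_y_true=np.concatenate(pooled_true) if pooled_true else np.empty(0, dtype=int),
        pooled_y_pred=np.concatenate(pooled_pred) if pooled_pred else np.empty(0, dtype=int),
        pooled_index=np.concatenate(pooled_idx) if pooled_idx else np.empty(0, dtype=int),
        skipped_splits=skipped,
    )
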