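"""Base-learner training with exhaustive grid search, and hard/soft
voting ensembles with weight optimization.

The classification ensemble combines a random forest, an extra-trees
classifier and AdaBoost. Soft voting averages predicted probabilities
with non-negative model weights (normalized internally, so weights are
scale-free); hard voting takes the majority label. Weights are tuned by
exhaustive scan of a lattice over [0, 2] in steps of 0.1 against F1 on
out-of-fold training predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
)
from sklearn.metrics import f1_score
from sklearn.model_selection import (
    KFold,
    ParameterGrid,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)

ALGORITHMS = ("adaboost", "extra_trees", "random_forest", "extra_trees_regressor")

#: Default hyperparameter grids. Deliberately compact: exhaustive
#: 10-fold search over each grid stays tractable on one core.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 3],
    },
    "extra_trees": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 3],
    },
    "adaboost": {
        "n_estimators": [50, 200],
        "learning_rate": [0.5, 1.0],
    },
    "extra_trees_regressor": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 3],
    },
}


def make_estimator(algorithm_id: str, seed: int = 0, **params):
    if algorithm_id == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm_id == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    if algorithm_id == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if algorithm_id == "extra_trees_regressor":
        return ExtraTreesRegressor(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")


@dataclass
class TrainedModel:
    """A fitted base learner bound to its descriptor subset."""

    algorithm_id: str
    descriptor_subset: list[str]
    hyperparameters: dict
    estimator: object
    cv_score: float
    task: str  # "classification" | "regression"

    def _X(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.descriptor_subset if c not in matrix.columns]
        if missing:
            raise ValueError(f"matrix lacks model columns: {missing[:5]}")
        return matrix[self.descriptor_subset].to_numpy(dtype=float)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._X(matrix))

    def predict_proba_active(self, matrix: pd.DataFrame) -> np.ndarray:
        """P(positive class) per compound (classification only)."""
        proba = self.estimator.predict_proba(self._X(matrix))
        positive_col = list(self.estimator.classes_).index(1)
        return proba[:, positive_col]


def grid_search_fit(
    matrix: pd.DataFrame,
    labels: Sequence,
    algorithm_id: str,
    grid: Mapping[str, list] | None = None,
    descriptor_subset: Sequence[str] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> TrainedModel:
    """Exhaustive grid search scored by mean k-fold CV (F1 for
    classification, R^2 for regression); the winner is refitted on the
    full training data. Ties keep the first combination in grid order.
    """
    grid = dict(grid) if grid is not None else DEFAULT_GRIDS[algorithm_id]
    if not grid:
        raise ValueError("grid must be non-empty")
    subset = list(descriptor_subset) if descriptor_subset is not None else list(matrix.columns)
    X = matrix[subset].to_numpy(dtype=float)
    y = np.asarray(labels)

    task = "regression" if algorithm_id.endswith("_regressor") else "classification"
    if task == "classification":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or counts.min() < cv_folds:
            raise ValueError("stratification error: every class needs >= cv_folds members")
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scoring = "f1"
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scoring = "r2"

    best_score, best_params = -np.inf, None
    for params in ParameterGrid(grid):
        est = make_estimator(algorithm_id, seed=seed, **params)
        score = float(np.mean(cross_val_score(est, X, y, cv=splitter, scoring=scoring)))
        if score > best_score:  # strict: first-in-grid wins ties
            best_score, best_params = score, params

    final = make_estimator(algorithm_id, seed=seed, **best_params)
    final.fit(X, y)
    return TrainedModel(
        algorithm_id=algorithm_id,
        descriptor_subset=subset,
        hyperparameters=dict(best_params),
        estimator=final,
        cv_score=best_score,
        task=task,
    )


def hard_vote(votes: Sequence) -> object:
    """Majority label among three binary votes (no ties possible)."""
    votes = list(votes)
    if len(votes) != 3:
        raise ValueError("hard voting expects exactly three votes")
    values = sorted(set(votes), key=lambda v: str(v))
    if len(values) == 1:
        return votes[0]
    counts = {v: votes.count(v) for v in values}
    return max(values, key=lambda v: counts[v])


def soft_vote(
    probabilities: Sequence[float],
    weights: Sequence[float],
    threshold: float = 0.5,
) -> tuple[float, int]:
    """Weighted mean probability P = sum(w_i p_i)/sum(w_i) and the label
    (1 = active iff P >= threshold)."""
    p = np.asarray(probabilities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    prob = float(np.dot(w, p) / w.sum())
    return prob, int(prob >= threshold)


@dataclass
class EnsembleModel:
    """Three base classifiers combined by hard or soft voting."""

    base_models: tuple[TrainedModel, TrainedModel, TrainedModel]
    mode: str = "soft"  # "hard" | "soft"
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        if len(self.base_models) != 3:
            raise ValueError("the ensemble combines exactly three base models")
        if sum(self.weights) <= 0 or min(self.weights) < 0:
            raise ValueError("weights must be non-negative with positive sum")

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        probs = np.column_stack(
            [m.predict_proba_active(matrix) for m in self.base_models]
        )
        w = np.asarray(self.weights, dtype=float)
        return probs @ w / w.sum()

    def base_probabilities(self, matrix: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [m.predict_proba_active(matrix) for m in self.base_models]
        )

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        if self.mode == "soft":
            return (self.predict_proba(matrix) >= self.threshold).astype(int)
        votes = np.column_stack([m.predict(matrix) for m in self.base_models])
        return np.array([hard_vote(row) for row in votes])


def optimize_weights(
    base_models: Sequence[TrainedModel],
    matrix: pd.DataFrame,
    labels: Sequence,
    weight_max: float = 2.0,
    step: float = 0.1,
    threshold: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    oof_probabilities: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Exhaustive scan of the weight lattice {0, step, ..., weight_max}^3
    (all-zero excluded), maximizing F1 of the soft vote.

    Base-model probabilities are out-of-fold cross-validated predictions
    on the supplied data (so the scan never scores in-sample fits); a
    precomputed (n, 3) probability array can be passed instead. Ties are
    broken by lowest total weight, then lexicographic order.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    y = np.asarray(labels)
    if oof_probabilities is not None:
        probs = np.asarray(oof_probabilities, dtype=float)
    else:
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cols = []
        for model in base_models:
            X = matrix[model.descriptor_subset].to_numpy(dtype=float)
            est = clone(model.estimator)
            oof = cross_val_predict(est, X, y, cv=splitter, method="predict_proba")
            positive_col = int(np.where(np.unique(y) == 1)[0][0])
            cols.append(oof[:, positive_col])
        probs = np.column_stack(cols)

    n_steps = int(round(weight_max / step))
    lattice = np.round(np.arange(n_steps + 1) * step, 10)
    best = None
    best_key = None
    for w in itertools.product(lattice, repeat=3):
        total = sum(w)
        if total == 0:
            continue
        p = probs @ np.asarray(w) / total
        pred = (p >= threshold).astype(int)
        score = f1_score(y, pred, zero_division=0)
        key = (-score, total, w)
        if best_key is None or key < best_key:
            best_key, best = key, w
    return tuple(float(x) for x in best)
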