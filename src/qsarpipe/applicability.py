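"""k-nearest-neighbour density applicability domain (AD).

Each training compound receives its own distance threshold derived from
the distribution of mean k-nearest-neighbour distances over the
training set: a global reference width (a percentile, median by
default, of the mean-kNN-distance distribution) is tightened for
compounds sitting in dense regions (whose own mean kNN distance is
below the reference). A query compound is inside the AD if it lies
within at least one training compound's threshold.

For a three-model soft-voting ensemble, each base model contributes a
reliability score of 0.33 when the query is inside its AD; the query is
inside the ensemble AD when the summed score exceeds 0.6, i.e. when at
least two of the three base models agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

PER_MODEL_SCORE = 0.33
ENSEMBLE_AD_CUTOFF = 0.6
_THRESHOLD_FLOOR = 1e-12  # keeps thresholds positive for duplicated points


@dataclass
class ADModel:
    """Per-model applicability domain state."""

    training_points: np.ndarray  # (n, d) scaled descriptor rows
    columns: list[str]
    k: int
    per_point_thresholds: np.ndarray  # (n,)
    reference_width: float
    metric: str = "euclidean"


@dataclass
class ADVerdict:
    per_model_inside: tuple[bool, bool, bool]
    per_model_score: tuple[float, float, float]
    ensemble_score: float
    inside_ensemble: bool


def mean_knn_distances(points: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """Mean distance from each point to its k nearest other points."""
    d = cdist(points, points, metric=metric)
    np.fill_diagonal(d, np.inf)
    nearest = np.sort(d, axis=1)[:, :k]
    return nearest.mean(axis=1)


def fit_ad(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 5,
    percentile: float = 50.0,
    metric: str = "euclidean",
) -> ADModel:
    """Fit the kNN-density AD on (scaled) training descriptors.

    ``percentile`` selects the reference width from the distribution of
    mean kNN distances (50 = median). Points whose own mean kNN
    distance is below the reference get that tighter value as their
    threshold; sparse-region points are capped at the reference width.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        points = matrix.to_numpy(dtype=float)
    else:
        points = np.asarray(matrix, dtype=float)
        columns = [f"x{i}" for i in range(points.shape[1])]
    n = points.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of training rows")
    mean_d = mean_knn_distances(points, k, metric)
    reference = float(np.percentile(mean_d, percentile))
    thresholds = np.minimum(mean_d, reference)
    thresholds = np.maximum(thresholds, _THRESHOLD_FLOOR)
    return ADModel(
        training_points=points,
        columns=columns,
        k=k,
        per_point_thresholds=thresholds,
        reference_width=reference,
        metric=metric,
    )


def query_ad(ad: ADModel, point: np.ndarray | pd.Series) -> bool:
    """Inside iff the query lies within at least one training
    compound's threshold."""
    q = np.asarray(point, dtype=float).ravel()
    if q.shape[0] != ad.training_points.shape[1]:
        raise ValueError(
            f"dimension mismatch: query has {q.shape[0]} features, "
            f"AD model expects {ad.training_points.shape[1]}"
        )
    d = cdist(q[None, :], ad.training_points, metric=ad.metric).ravel()
    return bool(np.any(d <= ad.per_point_thresholds))


def query_ad_batch(ad: ADModel, points: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        points = points[ad.columns].to_numpy(dtype=float)
    points = np.asarray(points, dtype=float)
    d = cdist(points, ad.training_points, metric=ad.metric)
    return np.any(d <= ad.per_point_thresholds[None, :], axis=1)


def ensemble_ad(verdicts: tuple[bool, bool, bool] | list[bool]) -> ADVerdict:
    """Aggregate three per-model AD verdicts: 0.33 per inside model,
    inside the ensemble AD iff the sum exceeds 0.6 (two or more)."""
    verdicts = tuple(bool(v) for v in verdicts)
    if len(verdicts) != 3:
        raise ValueError("exactly three per-model verdicts expected")
    scores = tuple(PER_MODEL_SCORE if v else 0.0 for v in verdicts)
    total = round(sum(scores), 10)
    return ADVerdict(
        per_model_inside=verdicts,
        per_model_score=scores,
        ensemble_score=total,
        inside_ensemble=total > ENSEMBLE_AD_CUTOFF,
    )
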