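"""Unsupervised feature reduction, imputation, scaling and
cluster-stratified splitting.

The pipeline order is fixed: drop constant/non-finite columns, remove
one member of every descriptor pair with |Pearson r| > 0.90, impute
remaining missing cells with k-nearest-neighbour means (k=3, uniform
weights), then standardize to zero mean / unit variance. Everything is
fitted on training data only and re-applied, frozen, to new compounds.

Train/validation splitting is semi-random: k-means clusters the
descriptor space first and each cluster is then split at the global
train fraction (75% by default), so both sets sample every region of
chemical space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.impute import KNNImputer

from .descriptors import DescriptorMatrix

CORRELATION_THRESHOLD = 0.90
KNN_IMPUTE_K = 3
TRAIN_FRACTION = 0.75


def drop_constant_infinite(df: pd.DataFrame) -> pd.DataFrame:
    """Remove columns that are constant over non-missing entries or
    contain any non-finite value."""
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    keep = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        observed = x[~np.isnan(x)]
        if observed.size == 0:
            continue
        if np.any(~np.isfinite(observed)):
            continue
        if np.all(observed == observed[0]):
            continue
        keep.append(col)
    return df[keep]


def correlation_filter(
    df: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> list[str]:
    """Greedy left-to-right decorrelation.

    Pearson r is computed on pairwise-complete observations. Scanning
    columns in matrix order, a column is dropped if its |r| with any
    already-retained column exceeds ``threshold``; hence among retained
    columns no pair exceeds it. Deterministic and order-dependent.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    corr = df.corr(method="pearson", min_periods=2).abs().to_numpy()
    cols = list(df.columns)
    retained_idx: list[int] = []
    for j in range(len(cols)):
        r_with_kept = corr[j, retained_idx] if retained_idx else np.array([])
        # NaN correlations (no overlapping observations) never trigger a drop
        if r_with_kept.size and np.any(r_with_kept[~np.isnan(r_with_kept)] > threshold):
            continue
        retained_idx.append(j)
    return [cols[j] for j in retained_idx]


def impute_knn(df: pd.DataFrame, k: int = KNN_IMPUTE_K) -> pd.DataFrame:
    """Fill missing cells with the unweighted mean of the column's values
    over the k nearest rows (NaN-aware Euclidean distance on mutually
    observed columns). Observed cells are untouched."""
    if df.isna().all(axis=0).any():
        bad = df.columns[df.isna().all(axis=0)].tolist()
        raise ValueError(
            f"uninformative descriptor; run drop/filter first: {bad}"
        )
    if not df.isna().any().any():
        return df.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(df.to_numpy(dtype=float))
    return pd.DataFrame(filled, index=df.index, columns=df.columns)


@dataclass
class ScalerState:
    """Per-column mean and (population) standard deviation."""

    means: pd.Series
    sds: pd.Series

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.means.index] - self.means) / self.sds


def fit_apply_scaler(df: pd.DataFrame) -> tuple[pd.DataFrame, ScalerState]:
    """Standardize each column to mean 0 / variance 1 (population sd,
    n denominator) and return the scaled frame plus the frozen state."""
    if df.isna().any().any():
        raise ValueError("scaler requires a complete matrix; impute first")
    means = df.mean(axis=0)
    sds = pd.Series(np.std(df.to_numpy(dtype=float), axis=0, ddof=0), index=df.columns)
    if (sds <= 0).any():
        bad = sds.index[sds <= 0].tolist()
        raise ValueError(f"zero-variance column(s) should have been dropped: {bad}")
    state = ScalerState(means=means, sds=sds)
    return state.apply(df), state


@dataclass
class PreprocessModel:
    """Frozen preprocessing state: retained columns, imputer training
    rows, and scaler statistics. ``transform`` re-applies the fitted
    pipeline to new compounds bit-reproducibly."""

    retained_columns: list[str] = field(default_factory=list)
    knn_k: int = KNN_IMPUTE_K
    imputer_rows: pd.DataFrame | None = None  # training rows, pre-imputation
    scaler: ScalerState | None = None

    def fit_transform(
        self,
        matrix: DescriptorMatrix | pd.DataFrame,
        correlation_threshold: float = CORRELATION_THRESHOLD,
    ) -> pd.DataFrame:
        df = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
        df = drop_constant_infinite(df)
        self.retained_columns = correlation_filter(df, correlation_threshold)
        df = df[self.retained_columns]
        self.imputer_rows = df.copy()
        complete = impute_knn(df, self.knn_k)
        # imputation can leave a column constant; re-check before scaling
        keep = [
            c
            for c in complete.columns
            if np.std(complete[c].to_numpy(dtype=float)) > 0
        ]
        self.retained_columns = keep
        self.imputer_rows = self.imputer_rows[keep]
        complete = complete[keep]
        scaled, self.scaler = fit_apply_scaler(complete)
        return scaled

    def transform(self, matrix: DescriptorMatrix | pd.DataFrame) -> pd.DataFrame:
        if self.scaler is None:
            raise RuntimeError("PreprocessModel is not fitted")
        df = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
        missing = [c for c in self.retained_columns if c not in df.columns]
        if missing:
            raise ValueError(f"input lacks fitted columns: {missing[:5]}")
        df = df[self.retained_columns].copy()
        df = df.replace([np.inf, -np.inf], np.nan)
        if df.isna().any().any():
            imputer = KNNImputer(n_neighbors=self.knn_k, weights="uniform")
            imputer.fit(self.imputer_rows.to_numpy(dtype=float))
            filled = imputer.transform(df.to_numpy(dtype=float))
            df = pd.DataFrame(filled, index=df.index, columns=df.columns)
        return self.scaler.apply(df)

    # -- serialization (versioned JSON archive) -------------------------

    def to_json(self) -> str:
        if self.scaler is None:
            raise RuntimeError("PreprocessModel is not fitted")
        payload = {
            "format_version": 1,
            "retained_columns": self.retained_columns,
            "knn_k": self.knn_k,
            "imputer_index": list(map(str, self.imputer_rows.index)),
            "imputer_rows": [
                [None if np.isnan(v) else v for v in row]
                for row in self.imputer_rows.to_numpy(dtype=float)
            ],
            "scaler_means": self.scaler.means.tolist(),
            "scaler_sds": self.scaler.sds.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessModel":
        payload = json.loads(text)
        cols = payload["retained_columns"]
        rows = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in payload["imputer_rows"]],
            index=payload["imputer_index"],
            columns=cols,
            dtype=float,
        )
        model = cls(retained_columns=cols, knn_k=payload["knn_k"], imputer_rows=rows)
        model.scaler = ScalerState(
            means=pd.Series(payload["scaler_means"], index=cols),
            sds=pd.Series(payload["scaler_sds"], index=cols),
        )
        return model


@dataclass
class SplitAssignment:
    train_ids: list
    validation_ids: list
    cluster_labels: dict
    train_fraction: float


def default_n_clusters(n: int) -> int:
    """Rule-of-thumb cluster count, round(sqrt(n/2)), at least 1."""
    return max(1, int(round(np.sqrt(n / 2.0))))


def cluster_stratified_split(
    df: pd.DataFrame,
    train_fraction: float = TRAIN_FRACTION,
    n_clusters: int | None = None,
    seed: int = 0,
) -> SplitAssignment:
    """k-means cluster the descriptor space, then split each cluster at
    the global train fraction with largest-remainder rounding.

    Clusters with fewer than 2 members go entirely to the training set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(df)
    if n_clusters is None:
        n_clusters = default_n_clusters(n)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_clusters = min(n_clusters, n)

    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(df.to_numpy(dtype=float))
    ids = np.asarray(df.index.tolist(), dtype=object)

    # largest-remainder apportionment of train counts across clusters
    cluster_ids = []
    quotas = []
    for c in range(n_clusters):
        members = ids[labels == c]
        if members.size == 0:
            continue
        cluster_ids.append(members)
        quotas.append(train_fraction * members.size)
    floors = [int(np.floor(q)) for q in quotas]
    total_train = int(round(train_fraction * n))
    remainders = np.array(quotas) - np.array(floors)
    counts = list(floors)
    extra = total_train - sum(floors)
    for j in np.argsort(-remainders, kind="stable")[: max(extra, 0)]:
        counts[j] += 1

    train, validation = [], []
    for members, k_train in zip(cluster_ids, counts):
        if members.size < 2:
            train.extend(members.tolist())
            continue
        perm = rng.permutation(members.size)
        shuffled = members[perm]
        k_train = min(max(k_train, 0), members.size)
        train.extend(shuffled[:k_train].tolist())
        validation.extend(shuffled[k_train:].tolist())

    return SplitAssignment(
        train_ids=train,
        validation_ids=validation,
        cluster_labels={i: int(l) for i, l in zip(ids, labels)},
        train_fraction=train_fraction,
    )
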