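"""Preprocessing oracles: constant/infinite dropping, decorrelation,
kNN imputation vs brute force, scaling, and the cluster-stratified
split."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics.pairwise import nan_euclidean_distances

import qsarpipe as qp
from qsarpipe.preprocessing import PreprocessModel, default_n_clusters

from conftest import random_missing_matrix


class TestDropConstantInfinite:
    def test_cases(self):
        df = pd.DataFrame(
            {
                "const": [1.0, 1.0, 1.0],
                "inf": [0.0, np.inf, 1.0],
                "ok": [0.0, 1.0, 0.0],
                "const_with_nan": [2.0, np.nan, 2.0],
            }
        )
        out = qp.drop_constant_infinite(df)
        assert list(out.columns) == ["ok"]

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            qp.drop_constant_infinite(pd.DataFrame({"a": [1.0]}))


class TestCorrelationFilter:
    def test_identical_pair_keeps_one(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        assert qp.correlation_filter(df) == ["a", "c"]

    def test_high_and_low_correlation(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "x": x,
                "x95": 0.95 * x + np.sqrt(1 - 0.95**2) * rng.normal(size=200),
                "half": 0.5 * x + np.sqrt(0.75) * rng.normal(size=200),
            }
        )
        kept = qp.correlation_filter(df)
        assert "x" in kept and "half" in kept
        r = abs(np.corrcoef(df["x"], df["x95"])[0, 1])
        assert ("x95" in kept) == (r <= 0.90)

    def test_posthoc_no_retained_pair_exceeds_threshold(self, rng):
        # random matrix plus planted near-duplicates
        base = rng.normal(size=(80, 12))
        df = pd.DataFrame(base, columns=[f"c{j}" for j in range(12)])
        for j in range(4):
            df[f"dup{j}"] = df[f"c{j}"] + 0.02 * rng.normal(size=80)
        kept = qp.correlation_filter(df, threshold=0.90)
        sub = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.90 + 1e-12

    def test_earlier_column_wins(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"later_loses": x, "dup": x + 1e-9})
        assert qp.correlation_filter(df) == ["later_loses"]


def brute_force_knn_impute(df: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Independent oracle: for each missing cell, average the column's
    observed values over the k nearest rows (NaN-aware Euclidean
    distance), considering only donor rows observed in that column."""
    X = df.to_numpy(dtype=float)
    D = nan_euclidean_distances(X, X)
    out = X.copy()
    n = X.shape[0]
    for i in range(n):
        for j in range(X.shape[1]):
            if not np.isnan(X[i, j]):
                continue
            donors = [
                r for r in range(n)
                if r != i and not np.isnan(X[r, j]) and not np.isnan(D[i, r])
            ]
            donors.sort(key=lambda r: D[i, r])
            chosen = donors[:k]
            out[i, j] = np.mean([X[r, j] for r in chosen])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class TestImputeKnn:
    def test_complete_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)))
        pd.testing.assert_frame_equal(qp.impute_knn(df), df)

    def test_single_missing_cell_equals_mean_of_3_nearest(self):
        df = pd.DataFrame(
            {
                "a": [0.0, 0.1, 0.2, 10.0],
                "b": [0.0, 0.1, 0.2, 10.0],
                "c": [1.0, 2.0, 3.0, np.nan],
            }
        )
        out = qp.impute_knn(df, k=3)
        # all three other rows are the 3 nearest
        assert out.loc[3, "c"] == pytest.approx((1 + 2 + 3) / 3)

    def test_twin_row_dominates_with_k1(self):
        df = pd.DataFrame(
            {"a": [0.0, 0.0, 50.0], "b": [1.0, 1.0, 9.0], "c": [7.0, np.nan, 0.0]}
        )
        out = qp.impute_knn(df, k=1)
        assert out.loc[1, "c"] == pytest.approx(7.0)

    @pytest.mark.parametrize("shape", [(8, 4), (15, 6), (20, 10)])
    def test_agrees_with_brute_force(self, rng, shape):
        df = random_missing_matrix(rng, *shape, missing_fraction=0.12)
        out = qp.impute_knn(df, k=3)
        oracle = brute_force_knn_impute(df, k=3)
        pd.testing.assert_frame_equal(out, oracle, atol=1e-10, rtol=0)

    def test_fully_missing_column_is_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="uninformative descriptor"):
            qp.impute_knn(df)

    def test_observed_cells_untouched(self, rng):
        df = random_missing_matrix(rng, 12, 5)
        out = qp.impute_knn(df)
        mask = ~df.isna().to_numpy()
        assert np.array_equal(out.to_numpy()[mask], df.to_numpy()[mask])


class TestScaler:
    def test_hand_case(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled, _ = qp.fit_apply_scaler(df)
        np.testing.assert_allclose(
            scaled["x"].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_training_columns_standardized(self, rng):
        df = pd.DataFrame(rng.normal(3, 5, size=(40, 6)))
        scaled, _ = qp.fit_apply_scaler(df)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.to_numpy().std(axis=0), 1.0, atol=1e-10)

    def test_apply_is_frozen_reuse_not_refit(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        scaled, state = qp.fit_apply_scaler(df)
        shifted = df + 10
        applied = state.apply(shifted)
        # frozen stats: shifted data does NOT come out centered
        assert abs(applied.mean(axis=0)).min() > 1.0
        pd.testing.assert_frame_equal(state.apply(df), scaled)

    def test_translation_invariance_of_scaled_vector(self, rng):
        x = rng.normal(size=25)
        a, _ = qp.fit_apply_scaler(pd.DataFrame({"x": x}))
        b, _ = qp.fit_apply_scaler(pd.DataFrame({"x": x + 42.0}))
        np.testing.assert_allclose(a["x"].to_numpy(), b["x"].to_numpy(), atol=1e-10)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            qp.fit_apply_scaler(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestSplit:
    def test_partition_and_fraction(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), index=[f"m{i}" for i in range(100)])
        split = qp.cluster_stratified_split(df, n_clusters=4, seed=0)
        train, val = set(split.train_ids), set(split.validation_ids)
        assert train.isdisjoint(val)
        assert train | val == set(df.index)
        assert len(train) == 75 and len(val) == 25

    def test_per_cluster_representation_on_blobs(self, rng):
        a = rng.normal(0, 0.3, size=(40, 2))
        b = rng.normal(10, 0.3, size=(40, 2))
        df = pd.DataFrame(np.vstack([a, b]), index=[f"m{i}" for i in range(80)])
        split = qp.cluster_stratified_split(df, n_clusters=2, seed=1)
        blob_a = {f"m{i}" for i in range(40)}
        for ids in (split.train_ids, split.validation_ids):
            assert set(ids) & blob_a
            assert set(ids) - blob_a

    def test_single_cluster_is_plain_split(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)))
        split = qp.cluster_stratified_split(df, n_clusters=1, seed=3)
        assert len(split.train_ids) == 30 and len(split.validation_ids) == 10

    def test_seed_reproducibility_and_sensitivity(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)))
        s1 = qp.cluster_stratified_split(df, n_clusters=3, seed=5)
        s2 = qp.cluster_stratified_split(df, n_clusters=3, seed=5)
        s3 = qp.cluster_stratified_split(df, n_clusters=3, seed=6)
        assert s1.train_ids == s2.train_ids
        assert s1.train_ids != s3.train_ids

    def test_default_cluster_rule(self):
        assert default_n_clusters(100) == 7
        assert default_n_clusters(2) == 1


class TestPreprocessModel:
    def test_fit_transform_reproducible_on_training_data(self, rng):
        df = random_missing_matrix(rng, 30, 8, missing_fraction=0.1)
        df["const"] = 1.0
        df["dup"] = df["c0"].fillna(0) + 1e-6 * rng.normal(size=30)
        model = PreprocessModel()
        fitted = model.fit_transform(df)
        reapplied = model.transform(df)
        pd.testing.assert_frame_equal(fitted, reapplied, atol=1e-10, rtol=0)
        assert "const" not in model.retained_columns

    def test_json_roundtrip_bit_reproducible(self, rng):
        df = random_missing_matrix(rng, 25, 6, missing_fraction=0.1)
        model = PreprocessModel()
        model.fit_transform(df)
        clone = PreprocessModel.from_json(model.to_json())
        new = random_missing_matrix(rng, 10, 6, missing_fraction=0.1)
        new.columns = df.columns
        pd.testing.assert_frame_equal(model.transform(new), clone.transform(new))
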