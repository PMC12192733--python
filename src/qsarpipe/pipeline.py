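"""End-to-end workflow: train a full model bundle from curated data and
run batch predictions on bare SMILES lists.

A *model bundle* holds everything prediction needs: the frozen
preprocessing state, the three base classifiers with their descriptor
subsets and soft-voting weights, the regression model, and one
applicability-domain model per fitted model. Prediction of a SMILES
batch standardizes each structure (bad rows become error rows, the
batch never aborts), computes descriptors, applies the stored
preprocessing, soft-votes a class probability, predicts pIC50/IC50,
and attaches per-model plus ensemble AD verdicts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .applicability import ADModel, ensemble_ad, fit_ad, query_ad_batch
from .curation import CuratedDataset, standardize_structure, to_ic50
from .descriptors import compute_descriptors
from .ensemble import (
    DEFAULT_GRIDS,
    EnsembleModel,
    TrainedModel,
    grid_search_fit,
    optimize_weights,
)
from .ga_selection import GAConfig, run_ga
from .preprocessing import PreprocessModel

BUNDLE_FORMAT_VERSION = 1
CLASSIFIER_ALGORITHMS = ("random_forest", "extra_trees", "adaboost")


@dataclass
class ModelBundle:
    """Serializable container for one trained classification+regression
    pipeline."""

    preprocess: PreprocessModel
    classifiers: tuple[TrainedModel, TrainedModel, TrainedModel]
    weights: tuple[float, float, float]
    regressor: TrainedModel
    ad_classification: tuple[ADModel, ADModel, ADModel]
    ad_regression: ADModel
    provider: str = "rdkit2d"
    threshold: float = 0.5
    manifest: dict = field(default_factory=dict)

    @property
    def ensemble(self) -> EnsembleModel:
        return EnsembleModel(
            base_models=self.classifiers, mode="soft",
            weights=self.weights, threshold=self.threshold,
        )

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"format_version": BUNDLE_FORMAT_VERSION, "bundle": self}
        joblib.dump(payload, path)
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        manifest = dict(self.manifest)
        manifest.update(
            {
                "format_version": BUNDLE_FORMAT_VERSION,
                "provider": self.provider,
                "weights": list(self.weights),
                "threshold": self.threshold,
                "classifier_subsets": {
                    m.algorithm_id: m.descriptor_subset for m in self.classifiers
                },
                "regressor_subset": self.regressor.descriptor_subset,
                "hyperparameters": {
                    m.algorithm_id: m.hyperparameters
                    for m in (*self.classifiers, self.regressor)
                },
            }
        )
        manifest_path.write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError("unsupported bundle format version")
        return payload["bundle"]


def train_bundle(
    dataset_cls: CuratedDataset,
    dataset_reg: CuratedDataset,
    provider: str = "rdkit2d",
    ga_config: GAConfig | None = None,
    grids: dict | None = None,
    cv_folds: int = 10,
    weight_cv_folds: int = 5,
    ad_k: int = 5,
    seed: int = 0,
) -> ModelBundle:
    """Train the full bundle from curated classification and regression
    datasets: descriptors -> preprocessing -> per-algorithm GA feature
    selection -> grid-search fitting -> soft-vote weight optimization ->
    AD models.
    """
    grids = grids or DEFAULT_GRIDS
    ga_config = ga_config or GAConfig(seed=seed)

    entries = dataset_cls.entries
    desc = compute_descriptors(
        entries["smiles"].tolist(), provider=provider,
        ids=entries["compound_id"].tolist(),
    )
    pre = PreprocessModel()
    X = pre.fit_transform(desc)
    y_cls = (entries["label"] == "active").astype(int).to_numpy()

    classifiers = []
    ad_models = []
    for i, algo in enumerate(CLASSIFIER_ALGORITHMS):
        ga = run_ga(
            X, y_cls, "classification",
            GAConfig(**{**ga_config.__dict__, "seed": ga_config.seed + i}),
        )
        subset = sorted(ga.best.members)
        model = grid_search_fit(
            X, y_cls, algo, grid=grids.get(algo),
            descriptor_subset=subset, cv_folds=cv_folds, seed=seed,
        )
        classifiers.append(model)
        ad_models.append(fit_ad(X[subset], k=min(ad_k, len(X) - 1)))
    classifiers = tuple(classifiers)

    weights = optimize_weights(
        classifiers, X, y_cls, cv_folds=weight_cv_folds, seed=seed
    )

    reg_entries = dataset_reg.entries
    desc_reg = compute_descriptors(
        reg_entries["smiles"].tolist(), provider=provider,
        ids=reg_entries["compound_id"].tolist(),
    )
    X_reg = pre.transform(desc_reg)
    y_reg = reg_entries["pic50"].to_numpy(dtype=float)
    ga_reg = run_ga(
        X_reg, y_reg, "regression",
        GAConfig(**{**ga_config.__dict__, "seed": ga_config.seed + 7}),
    )
    reg_subset = sorted(ga_reg.best.members)
    regressor = grid_search_fit(
        X_reg, y_reg, "extra_trees_regressor",
        grid=grids.get("extra_trees_regressor"),
        descriptor_subset=reg_subset, cv_folds=cv_folds, seed=seed,
    )
    ad_regression = fit_ad(X_reg[reg_subset], k=min(ad_k, len(X_reg) - 1))

    return ModelBundle(
        preprocess=pre,
        classifiers=classifiers,
        weights=weights,
        regressor=regressor,
        ad_classification=tuple(ad_models),
        ad_regression=ad_regression,
        provider=provider,
        manifest={"seed": seed, "cv_folds": cv_folds, "ad_k": ad_k,
                  "ga": {k: v for k, v in ga_config.__dict__.items()}},
    )


def predict_batch(
    smiles: Sequence[str],
    bundle: ModelBundle,
    ids: Sequence | None = None,
) -> pd.DataFrame:
    """Predict a batch of SMILES with a loaded bundle.

    Output has one row per input, in input order; rows whose structure
    fails validation carry the error in the ``error`` column and NaN
    predictions, and never abort the batch.
    """
    if ids is None:
        ids = [f"query_{i + 1}" for i in range(len(smiles))]
    rows = []
    valid_idx, valid_smiles = [], []
    for i, smi in enumerate(smiles):
        row = {
            "compound_id": ids[i],
            "input_smiles": smi,
            "standardized_smiles": None,
            "class_probability": np.nan,
            "class_label": None,
            "predicted_pic50": np.nan,
            "predicted_ic50_nm": np.nan,
            "ad_model_1": None, "ad_model_2": None, "ad_model_3": None,
            "ad_ensemble_score": np.nan,
            "ad_classification_inside": None,
            "ad_regression_inside": None,
            "error": None,
        }
        try:
            std, _ = standardize_structure(smi)
            row["standardized_smiles"] = std
            valid_idx.append(i)
            valid_smiles.append(std)
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)

    if valid_smiles:
        desc = compute_descriptors(
            valid_smiles, provider=bundle.provider,
            ids=[ids[i] for i in valid_idx],
        )
        X = bundle.preprocess.transform(desc)
        ens = bundle.ensemble
        probs = ens.predict_proba(X)
        pic50 = bundle.regressor.estimator.predict(
            X[bundle.regressor.descriptor_subset].to_numpy(dtype=float)
        )
        inside_cls = [
            query_ad_batch(ad, X[model.descriptor_subset])
            for ad, model in zip(bundle.ad_classification, bundle.classifiers)
        ]
        inside_reg = query_ad_batch(
            bundle.ad_regression, X[bundle.regressor.descriptor_subset]
        )
        for j, i in enumerate(valid_idx):
            verdict = ensemble_ad(tuple(col[j] for col in inside_cls))
            rows[i].update(
                {
                    "class_probability": float(probs[j]),
                    "class_label": "active" if probs[j] >= bundle.threshold else "inactive",
                    "predicted_pic50": float(pic50[j]),
                    "predicted_ic50_nm": to_ic50(float(pic50[j])),
                    "ad_model_1": bool(verdict.per_model_inside[0]),
                    "ad_model_2": bool(verdict.per_model_inside[1]),
                    "ad_model_3": bool(verdict.per_model_inside[2]),
                    "ad_ensemble_score": round(verdict.ensemble_score, 2),
                    "ad_classification_inside": verdict.inside_ensemble,
                    "ad_regression_inside": bool(inside_reg[j]),
                }
            )
    return pd.DataFrame(rows)


def write_predictions(results: pd.DataFrame, path) -> None:
    """CSV output with probabilities rounded to 3 decimals; use the
    DataFrame itself for full precision."""
    out = results.copy()
    out["class_probability"] = out["class_probability"].round(3)
    out.to_csv(path, index=False)
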