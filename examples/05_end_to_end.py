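"""End-to-end: curate the bundled molecule fixture, train a small
bundle (GA selection + grid search + weight tuning + AD models), and
predict a batch that includes an invalid SMILES."""

import qsarpipe as qp
from qsarpipe.ga_selection import GAConfig

records = qp.toy_molecule_set()
ds_cls = qp.resolve_duplicates(records, "classification")
ds_reg = qp.resolve_duplicates(records, "regression")
print(len(ds_cls), "curated,", len(ds_cls.rejection_log), "rejected")

tiny = {k: {"n_estimators": [15]} for k in
        ("random_forest", "extra_trees", "adaboost", "extra_trees_regressor")}
bundle = qp.train_bundle(
    ds_cls, ds_reg,
    ga_config=GAConfig(population_size=6, generations=2, cv_folds=3, seed=0),
    grids=tiny, cv_folds=3, weight_cv_folds=3, ad_k=3, seed=0,
)
print("soft-voting weights:", bundle.weights)

out = qp.predict_batch(["CC(=O)Oc1ccccc1C(=O)O", "C((("], bundle)
print(out[["input_smiles", "class_probability", "predicted_ic50_nm",
           "ad_ensemble_score", "error"]])
# The valid molecule gets a class probability, a regression IC50 and
# an AD verdict; the malformed SMILES becomes a per-row error and the
# batch completes.
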