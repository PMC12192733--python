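# qsarpipe

QSAR model construction and virtual screening for enzyme-inhibition
bioactivity data, built for the workflow used in early-stage inhibitor
discovery against targets such as human dipeptidyl peptidase 4 (DPP4):

* **curation** of ChEMBL-style IC50 exports — salt/water stripping,
  canonical duplicate resolution (geometric mean under a CV < 0.2
  concordance rule), the 50 nM activity label
  (active ⇔ IC50 ≤ 50 nM) and pIC50 = −log10(IC50 [M]);
* **molecular descriptors** from a pluggable RDKit-backed provider
  registry, organized into a 20-category vocabulary;
* **preprocessing** — constant/infinite removal, |r| > 0.90
  decorrelation, kNN imputation (k = 3, uniform weights), standard
  scaling, and a k-means cluster-stratified 75/25 train/validation
  split;
* **genetic-algorithm wrapper feature selection** with penalized
  cross-validated fitness (F1 or R² minus a per-descriptor penalty);
* **ensemble models** — random forest + extra trees + AdaBoost
  combined by hard voting or weighted soft voting
  P = Σ wᵢpᵢ / Σ wᵢ, with the weights tuned on a {0, 0.1, …, 2}³
  lattice; an extra-trees regressor for continuous IC50 prediction;
* **applicability domain** — per-model kNN-density thresholds; a query
  is inside the ensemble AD when ≥ 2 of the 3 base models (score
  0.33 each, cutoff > 0.6) contain it;
* **single-point assay analysis** — fluorescence slope between minutes
  10 and 20, % inhibition vs control, hit calls at > 15%, and a
  prediction-vs-experiment confusion summary (PPV/NPV/TPR/TNR/ACC).

The package is used from Python; a thin `qsarpipe` CLI mirrors the
pipeline stages (`curate`, `descriptors`, `preprocess`, `select`,
`train`, `evaluate`, `predict`, `assay`) for shell use. Short
narrative scripts for each capability live in `examples/`.

## Worked example

Train on the bundled ~30-molecule fixture (synthetic IC50s, planted
duplicates, a salt, a hydrate, one invalid SMILES) and predict a small
batch — this is `examples/05_end_to_end.py`, trimmed:

```python
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
out = qp.predict_batch(["CC(=O)Oc1ccccc1C(=O)O", "C((("], bundle)
print(out[["input_smiles", "class_probability", "predicted_ic50_nm",
           "ad_ensemble_score", "error"]])
```

prints

```
28 curated, 3 rejected
            input_smiles  class_probability  predicted_ic50_nm  ad_ensemble_score              error
0  CC(=O)Oc1ccccc1C(=O)O                0.0             8200.0               0.99               None
1                   C(((                NaN                NaN                NaN  invalid structure
```

Aspirin gets probability 0 of being a sub-50 nM inhibitor and a high
predicted IC50 (it is a training compound with a planted 8,200 nM
value, which the tree regressor reproduces), sits inside all three
base-model applicability domains (ensemble score 0.99), and the
malformed SMILES is surfaced as a per-row error without aborting the
batch. The 3 rejected records are the invalid entry and the
fixture's discordant duplicate pair; the concordant duplicate pair
merges into a single curated entry.

Soft voting with tuned weights, by hand:

```python
>>> qp.soft_vote((0.9, 0.4, 0.6), (0.1, 0.7, 0.2))
(0.49, 0)          # weighted mean probability, label inactive at 0.5
```

## Layout

```
src/qsarpipe/      curation, descriptors, preprocessing, ga_selection,
                   ensemble, evaluation, applicability, assay,
                   synthetic, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, defaults, numerical conventions, limitations
```
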