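"""Compute descriptors for a few molecules and run the preprocessing
pipeline: drop constants/infinities, decorrelate, impute, scale, and
split train/validation by chemical-space clusters."""

import qsarpipe as qp
from qsarpipe.preprocessing import PreprocessModel

smiles = [
    "CCO", "CCN", "CCC", "c1ccccc1", "c1ccccc1O", "c1ccccc1N",
    "CC(=O)O", "CC(=O)N", "CCOC(=O)C", "CN1CCCC1",
]
matrix = qp.compute_descriptors(smiles, ids=[f"m{i}" for i in range(10)])
print("descriptor matrix:", matrix.values.shape)
print("categories in play:", len(set(matrix.category_map.values())), "of", len(qp.list_categories()))

model = PreprocessModel()
scaled = model.fit_transform(matrix)
print("after preprocessing:", scaled.shape, "columns retained")
print("column means ~0:", float(abs(scaled.mean()).max()) < 1e-10)

split = qp.cluster_stratified_split(scaled, train_fraction=0.75, n_clusters=2, seed=0)
print("train:", sorted(split.train_ids))
print("validation:", sorted(split.validation_ids))
# Each k-means cluster contributes to both sets at the global 75/25
# fraction, so neither set misses a region of chemical space.
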