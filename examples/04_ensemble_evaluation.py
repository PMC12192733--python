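"""Train the three base classifiers, tune soft-voting weights, and
evaluate with the confusion-count metrics."""

import numpy as np

import qsarpipe as qp

syn = qp.make_synthetic_classification(
    n=300, d=15, n_informative=6, effect_size=2.0, seed=3
)
grid = {"n_estimators": [50]}
models = tuple(
    qp.grid_search_fit(syn.matrix, syn.labels, algo, grid=grid, cv_folds=5, seed=0)
    for algo in ("random_forest", "extra_trees", "adaboost")
)
weights = qp.optimize_weights(models, syn.matrix, syn.labels, cv_folds=5, seed=0)
print("tuned soft-voting weights:", weights)

ens = qp.EnsembleModel(base_models=models, mode="soft", weights=weights)
pred = ens.predict(syn.matrix)
counts = qp.confusion_from_labels(syn.labels, pred)
m = qp.classification_metrics(counts)
print(f"training-set F1 {m.f1:.3f}, MCC {m.mcc:.3f}, accuracy {m.accuracy:.3f}")

# soft voting is algebra on probabilities: weighted mean, scale-free
p, label = qp.soft_vote((0.9, 0.4, 0.6), (0.1, 0.7, 0.2))
print(f"soft vote of (0.9, 0.4, 0.6) with weights (0.1, 0.7, 0.2): "
      f"P(active)={p:.2f} -> {'active' if label else 'inactive'}")
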