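"""Fit a kNN-density applicability domain and query it, then apply the
three-model ensemble rule."""

import numpy as np

import qsarpipe as qp
from qsarpipe.applicability import query_ad_batch

rng = np.random.default_rng(0)
train = rng.normal(size=(120, 4))          # scaled training descriptors
ad = qp.fit_ad(train, k=5)
print(f"reference width (median mean-kNN distance): {ad.reference_width:.3f}")

in_dist = rng.normal(size=(50, 4))
shifted = rng.normal(8, 1, size=(50, 4))   # far outside the training cloud
print("inside fraction, in-distribution:", query_ad_batch(ad, in_dist).mean())
print("inside fraction, shifted:", query_ad_batch(ad, shifted).mean())

# ensemble rule: 0.33 per model, inside iff the sum exceeds 0.6
for verdicts in [(True, True, True), (True, True, False), (True, False, False)]:
    v = qp.ensemble_ad(verdicts)
    print(f"{verdicts} -> score {v.ensemble_score:.2f}, "
          f"{'inside' if v.inside_ensemble else 'outside'} ensemble AD")
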