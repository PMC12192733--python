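"""Analyze single-point enzyme-assay kinetics: slopes, % inhibition,
hit calls, and a prediction-vs-experiment confusion summary."""

import numpy as np
import pandas as pd

import qsarpipe as qp
from qsarpipe.assay import analyze_kinetics, screen_summary_text

# build a toy kinetics table: control turns over at 10 FLU/min,
# one strong inhibitor (70% inhibition), one borderline miss (12%)
t = np.arange(0, 31, 5.0)
rows = []
for cid, role, rate in [("control", "control", 10.0),
                        ("cpdA", "sample", 3.0),
                        ("cpdB", "sample", 8.8)]:
    rows += [{"compound_id": cid, "role": role, "time_min": ti, "flu": rate * ti}
             for ti in t]
hits = analyze_kinetics(pd.DataFrame(rows), cutoff=15.0)
for h in hits:
    print(f"{h.compound_id}: {h.percent_inhibition:.0f}% inhibition -> "
          f"{'hit' if h.active else 'miss'} (cutoff {h.cutoff:g}%)")

# score model predictions against the experimental calls
predictions = {"cpdA": True, "cpdB": True}   # model called both active
counts, report = qp.score_screen(predictions, hits)
print(screen_summary_text(counts, report))
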