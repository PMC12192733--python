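"""Curate a small activity table: standardize structures, resolve
duplicates, label activity and compute pIC50."""

import qsarpipe as qp
from qsarpipe.curation import ActivityRecord, resolve_duplicates

records = [
    ActivityRecord("A1", "CC(=O)[O-].[Na+].O", 40.0),   # salt + water
    ActivityRecord("A2", "CCOc1ccccc1", 100.0),
    ActivityRecord("A3", "c1ccccc1OCC", 110.0),          # same structure as A2
    ActivityRecord("A4", "CCN", 10.0),
    ActivityRecord("A5", "NCC", 1000.0),                 # discordant twin of A4
]

ds = resolve_duplicates(records, task="regression")
print(ds.entries[["compound_id", "smiles", "ic50", "pic50"]])
print("rejected:", ds.rejection_log)

# A1's sodium and water are stripped; A2/A3 collapse to the geometric
# mean sqrt(100*110) ~ 104.9 nM (CV < 0.2); A4/A5 disagree by 100x and
# are both rejected as discordant. pIC50 = 9 - log10(IC50 in nM).
print("label at 50 nM:", qp.label_activity(50.0), "| at 50.1 nM:", qp.label_activity(50.1))
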