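"""Bioactivity data curation: structure standardization, duplicate
resolution, activity labeling and pIC50 transforms.

The curation contract mirrors common ChEMBL-export hygiene for
single-target IC50 datasets:

* salts, counter-ions and waters are stripped, keeping the largest
  organic fragment;
* duplicates (same standardized structure) are collapsed — identical
  responses keep one entry, concordant IC50 groups (sd/mean < 0.2) are
  replaced by their geometric mean, discordant groups are rejected
  outright;
* classification labels use the 50 nM potency cutoff (active iff
  IC50 <= 50 nM); regression responses are pIC50 = -log10(IC50 [M]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ACTIVITY_THRESHOLD_NM = 50.0
DUPLICATE_CV_THRESHOLD = 0.2

RELATIONS = ("=", ">", "<", ">=", "<=")

Task = Literal["classification", "regression"]


@dataclass(frozen=True)
class ActivityRecord:
    """One compound-IC50 measurement.

    ``ic50`` is in nM and must be positive; ``relation`` is the
    qualifier attached to the reported value ("=" for exact).
    """

    compound_id: str
    smiles: str
    ic50: float
    relation: str = "="
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation qualifier {self.relation!r}")
        if not (self.ic50 > 0):
            raise ValueError("invalid potency: IC50 must be positive")


@dataclass
class CuratedDataset:
    """Curated, deduplicated dataset for one modeling task."""

    task: Task
    entries: pd.DataFrame  # columns: compound_id, smiles, label or pic50 (+ ic50)
    rejection_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def standardize_structure(smiles: str) -> tuple[str, str]:
    """Standardize a SMILES string: strip salts/waters, keep the largest
    organic fragment, and return ``(standardized_smiles, canonical_key)``.

    The canonical key is RDKit's canonical SMILES of the kept fragment,
    stable under input atom reordering.

    Raises
    ------
    ValueError
        with message "invalid structure" if the SMILES cannot be parsed.
    """
    if not smiles or not smiles.strip():
        raise ValueError("invalid structure")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("invalid structure")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = None
    best_rank = None
    for frag in frags:
        canon = Chem.MolToSmiles(frag)
        if canon in ("O", "[OH2]"):  # water is never the kept fragment
            continue
        has_carbon = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        # prefer organic fragments, then heavy-atom count; canonical
        # SMILES as the final deterministic tie-break
        rank = (has_carbon, frag.GetNumHeavyAtoms(), canon)
        if best_rank is None or rank > best_rank:
            best, best_rank = frag, rank
    if best is None:  # e.g. input was pure water
        raise ValueError("invalid structure")
    canonical = Chem.MolToSmiles(best)
    return canonical, canonical


def label_activity(ic50: float) -> str:
    """Binary potency label: ``"active"`` iff IC50 <= 50 nM."""
    if not (ic50 > 0):
        raise ValueError("invalid potency")
    return "active" if ic50 <= ACTIVITY_THRESHOLD_NM else "inactive"


def to_pic50(ic50_nm: float) -> float:
    """pIC50 = -log10(IC50 in molar); IC50 given in nM."""
    if not (ic50_nm > 0):
        raise ValueError("invalid potency")
    return 9.0 - math.log10(ic50_nm)


def to_ic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`; returns nM."""
    return 10.0 ** (9.0 - pic50)


def _geometric_mean(values: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(np.asarray(values, dtype=float)))))


def resolve_duplicates(
    records: Iterable[ActivityRecord],
    task: Task,
    sd_mode: str = "sample",
) -> CuratedDataset:
    """Group standardized records by canonical structure and resolve
    duplicates.

    Classification: all relation qualifiers are admitted; a group with
    conflicting binary labels is rejected, otherwise one entry is kept.

    Regression: only ``"="`` records are admitted (others are rejected
    with a reason); a group whose IC50 coefficient of variation
    (sd/mean) is below 0.2 collapses to its geometric mean, otherwise
    all members are rejected as discordant.

    ``sd_mode`` selects the standard-deviation convention for the
    sd/mean rule: "sample" (n-1 denominator, default) or "population".
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError("sd_mode must be 'sample' or 'population'")
    ddof = 1 if sd_mode == "sample" else 0

    groups: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    rejections: list[tuple[str, str]] = []

    for rec in records:
        if task == "regression" and rec.relation != "=":
            rejections.append((rec.compound_id, "non-exact IC50 qualifier"))
            continue
        try:
            std, key = standardize_structure(rec.smiles)
        except ValueError as exc:
            rejections.append((rec.compound_id, str(exc)))
            continue
        rec = ActivityRecord(rec.compound_id, std, rec.ic50, rec.relation, rec.source_tag)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    rows = []
    for key in order:
        members = groups[key]
        ids = [m.compound_id for m in members]
        values = [m.ic50 for m in members]
        if task == "classification":
            labels = {label_activity(v) for v in values}
            if len(labels) > 1:
                rejections.extend((i, "conflicting duplicate labels") for i in ids)
                continue
            rows.append(
                {
                    "compound_id": ids[0],
                    "smiles": members[0].smiles,
                    "ic50": _representative_ic50(values),
                    "label": labels.pop(),
                    "n_merged": len(members),
                }
            )
        else:
            if len(set(values)) == 1:
                ic50 = values[0]
            else:
                mean = float(np.mean(values))
                sd = float(np.std(values, ddof=ddof)) if len(values) > 1 else 0.0
                if sd / mean >= DUPLICATE_CV_THRESHOLD:
                    rejections.extend((i, "discordant duplicates") for i in ids)
                    continue
                ic50 = _geometric_mean(values)
            rows.append(
                {
                    "compound_id": ids[0],
                    "smiles": members[0].smiles,
                    "ic50": ic50,
                    "pic50": to_pic50(ic50),
                    "n_merged": len(members),
                }
            )

    columns = (
        ["compound_id", "smiles", "ic50", "label", "n_merged"]
        if task == "classification"
        else ["compound_id", "smiles", "ic50", "pic50", "n_merged"]
    )
    entries = pd.DataFrame(rows, columns=columns)
    return CuratedDataset(task=task, entries=entries, rejection_log=rejections)


def _representative_ic50(values: Sequence[float]) -> float:
    if len(set(values)) == 1:
        return values[0]
    return _geometric_mean(values)


def read_activity_table(
    path,
    smiles_col: str = "smiles",
    value_col: str = "ic50",
    relation_col: str | None = "relation",
    id_col: str = "compound_id",
    sep: str | None = None,
) -> list[ActivityRecord]:
    """Read an activity table (CSV/TSV) into :class:`ActivityRecord` s.

    Column names are configurable so ChEMBL activity exports
    (``canonical_smiles`` / ``standard_value`` / ``standard_relation`` /
    ``molecule_chembl_id``) map directly.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    records = []
    for _, row in df.iterrows():
        relation = str(row[relation_col]).strip().strip("'\"") if relation_col else "="
        records.append(
            ActivityRecord(
                compound_id=str(row[id_col]),
                smiles=str(row[smiles_col]),
                ic50=float(row[value_col]),
                relation=relation if relation in RELATIONS else "=",
            )
        )
    return records


def write_curated(dataset: CuratedDataset, entries_path, rejections_path=None) -> None:
    """Write the curated entries (and optionally the rejection log) as CSV."""
    dataset.entries.to_csv(entries_path, index=False)
    if rejections_path is not None:
        pd.DataFrame(dataset.rejection_log, columns=["compound_id", "reason"]).to_csv(
            rejections_path, index=False
        )
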