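"""Molecular descriptor computation behind a pluggable provider registry.

Descriptors are grouped into a fixed 20-category vocabulary covering the
usual cheminformatics blocks (autocorrelations, connectivity indexes,
E-state, Burden eigenvalues, MOE-type surface areas, functional-group
counts, ...). Providers map their own column names onto those category
labels; pipelines downstream are descriptor-agnostic and never depend on
a specific column being present.

Two providers ship by default, both backed by RDKit:

``rdkit2d``
    the full RDKit 2D descriptor list (~210 columns).
``rdkit2d3d``
    the 2D set plus 3D shape descriptors computed on a single
    deterministic ETKDG conformer (fixed embedding seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, Descriptors3D, AllChem

#: The fixed category vocabulary (20 labels).
CATEGORIES: tuple[str, ...] = (
    "Autocorrelations",
    "Functional Groups",
    "Bidimensional",
    "Connectivity indexes",
    "Topological charge",
    "Information indexes",
    "Atom centered",
    "Molecular properties",
    "Constitutionals",
    "Rdkit 3D",
    "CPSA",
    "Type MOE",
    "Edge Adjacency",
    "Topological",
    "Electro topological estate",
    "Burden Eigenvalues",
    "Physicochemical",
    "Eigenvalues",
    "Getaway",
    "Walk Path Counts",
)

_CONFORMER_SEED = 20240901  # fixed: one deterministic embedding per molecule


def list_categories() -> tuple[str, ...]:
    """Return the 20 descriptor category labels."""
    return CATEGORIES


def _categorize_rdkit2d(name: str) -> str:
    """Assign an RDKit 2D descriptor name to a category label."""
    if name.startswith("fr_"):
        return "Functional Groups"
    if name.startswith("BCUT2D_"):
        return "Burden Eigenvalues"
    if name.startswith(("PEOE_VSA", "SMR_VSA", "SlogP_VSA", "LabuteASA")):
        return "Type MOE"
    if name.startswith(("EState_VSA", "VSA_EState")) or "EStateIndex" in name:
        return "Electro topological estate"
    if name.startswith("Chi") or name in ("HallKierAlpha", "Kappa1", "Kappa2", "Kappa3", "Phi"):
        return "Connectivity indexes"
    if name in ("Ipc", "AvgIpc"):
        return "Information indexes"
    if name in ("BalabanJ", "BertzCT"):
        return "Topological"
    if name.startswith(("Num", "NHOH", "NO", "Ring", "HeavyAtom", "FractionCSP3")):
        return "Constitutionals"
    if name in ("MolWt", "ExactMolWt", "HeavyAtomMolWt", "qed", "SPS"):
        return "Constitutionals"
    if name.endswith("PartialCharge"):
        return "Topological charge"
    if name in ("MolLogP", "MolMR", "TPSA"):
        return "Physicochemical"
    return "Molecular properties"


@dataclass
class DescriptorMatrix:
    """Compounds x named numeric descriptors, with missing values allowed."""

    values: pd.DataFrame  # index: row ids, columns: descriptor names
    category_map: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("descriptor names must be unique")
        missing = [c for c in cols if c not in self.category_map]
        if missing:
            raise ValueError(f"columns without category: {missing[:5]}")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DescriptorProvider:
    """A named descriptor backend.

    ``compute_row`` maps an RDKit Mol to a dict of descriptor values; it
    must be deterministic and must never raise for a valid molecule —
    individual descriptor failures become NaN.
    """

    provider_id: str
    column_names: list[str]
    category_map: dict[str, str]
    compute_row: Callable[[Chem.Mol], dict[str, float]]


def _rdkit2d_row(mol: Chem.Mol) -> dict[str, float]:
    out = {}
    for name, fn in Descriptors.descList:
        try:
            v = fn(mol)
            out[name] = float(v) if v is not None else math.nan
        except Exception:
            out[name] = math.nan
    return out


_RDKIT3D_FUNCS = [
    ("Asphericity", Descriptors3D.Asphericity),
    ("Eccentricity", Descriptors3D.Eccentricity),
    ("InertialShapeFactor", Descriptors3D.InertialShapeFactor),
    ("NPR1", Descriptors3D.NPR1),
    ("NPR2", Descriptors3D.NPR2),
    ("PMI1", Descriptors3D.PMI1),
    ("PMI2", Descriptors3D.PMI2),
    ("PMI3", Descriptors3D.PMI3),
    ("RadiusOfGyration", Descriptors3D.RadiusOfGyration),
    ("SpherocityIndex", Descriptors3D.SpherocityIndex),
]


def _rdkit2d3d_row(mol: Chem.Mol) -> dict[str, float]:
    out = _rdkit2d_row(mol)
    mol3d = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _CONFORMER_SEED
    try:
        ok = AllChem.EmbedMolecule(mol3d, params)
    except Exception:
        ok = -1
    for name, fn in _RDKIT3D_FUNCS:
        if ok != 0:
            out[name] = math.nan
            continue
        try:
            out[name] = float(fn(mol3d))
        except Exception:
            out[name] = math.nan
    return out


def _build_registry() -> dict[str, DescriptorProvider]:
    names2d = [name for name, _ in Descriptors.descList]
    cmap2d = {n: _categorize_rdkit2d(n) for n in names2d}
    p2d = DescriptorProvider("rdkit2d", names2d, cmap2d, _rdkit2d_row)

    names3d = names2d + [n for n, _ in _RDKIT3D_FUNCS]
    cmap3d = dict(cmap2d)
    cmap3d.update({n: "Rdkit 3D" for n, _ in _RDKIT3D_FUNCS})
    p3d = DescriptorProvider("rdkit2d3d", names3d, cmap3d, _rdkit2d3d_row)
    return {p.provider_id: p for p in (p2d, p3d)}


_REGISTRY = _build_registry()


def get_provider(provider_id: str) -> DescriptorProvider:
    try:
        return _REGISTRY[provider_id]
    except KeyError:
        raise ValueError(
            f"unknown descriptor provider {provider_id!r}; "
            f"available: {sorted(_REGISTRY)}"
        ) from None


def available_providers() -> list[str]:
    return sorted(_REGISTRY)


def compute_descriptors(
    structures: Sequence[str],
    provider: str = "rdkit2d",
    ids: Sequence | None = None,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for standardized SMILES strings.

    One row per input structure, in input order. A descriptor whose
    calculation fails for a molecule yields NaN in that cell; the call
    never aborts on individual failures. Unparseable structures raise
    (inputs are expected to be pre-standardized).
    """
    prov = get_provider(provider)
    if ids is None:
        ids = list(range(len(structures)))
    rows = []
    for smi in structures:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid structure: {smi!r}")
        rows.append(prov.compute_row(mol))
    df = pd.DataFrame(rows, index=list(ids), columns=prov.column_names, dtype=float)
    return DescriptorMatrix(values=df, category_map=dict(prov.category_map))


def write_descriptors(matrix: DescriptorMatrix, values_path, category_path=None) -> None:
    """Write the wide descriptor CSV and an optional sidecar category map."""
    matrix.values.to_csv(values_path, index_label="compound_id")
    if category_path is not None:
        pd.Series(matrix.category_map, name="category").rename_axis("descriptor").to_csv(
            category_path
        )
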