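"""Synthetic data generators and a small hand-curated molecule fixture.

These make every stage of the pipeline testable without any external
download: descriptor-like matrices with a planted, known signal
(logistic link for classification, linear-plus-noise for regression),
optional correlated column blocks (to exercise decorrelation) and
missing cells (to exercise imputation), plus ~30 drug-like molecules
with synthetic IC50 values spanning 1-10,000 nM that include planted
duplicates, a salt form, a water-containing entry and one invalid
SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import ActivityRecord


@dataclass
class SyntheticTabular:
    matrix: pd.DataFrame
    labels: np.ndarray
    informative_columns: list[str]
    generation_params: dict = field(default_factory=dict)


def _base_features(
    n: int,
    d: int,
    rng: np.random.Generator,
    n_correlated: int,
    missing_fraction: float,
) -> pd.DataFrame:
    X = rng.standard_normal((n, d))
    cols = [f"desc_{j:03d}" for j in range(d)]
    df = pd.DataFrame(X, columns=cols)
    # correlated block: near-copies of the first n_correlated columns,
    # appended at the end so the correlation filter has work to do
    for j in range(n_correlated):
        src = cols[j % d]
        df[f"{src}_dup"] = df[src] + 0.01 * rng.standard_normal(n)
    if missing_fraction > 0:
        mask = rng.random(df.shape) < missing_fraction
        # never blank out a full column
        for k, col in enumerate(df.columns):
            if mask[:, k].all():
                mask[0, k] = False
        values = df.to_numpy()
        values[mask] = np.nan
        df = pd.DataFrame(values, columns=df.columns)
    return df


def make_synthetic_classification(
    n: int = 500,
    d: int = 100,
    n_informative: int = 10,
    effect_size: float = 1.0,
    class_balance: float = 0.5,
    seed: int = 0,
    n_correlated: int = 0,
    missing_fraction: float = 0.0,
) -> SyntheticTabular:
    """Standard-normal features; binary labels from a logistic link on
    the informative columns with slope ``effect_size``."""
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must be in (0, 1)")
    if n_informative > d:
        raise ValueError("n_informative must be <= d")
    rng = np.random.default_rng(seed)
    df = _base_features(n, d, rng, n_correlated, missing_fraction)
    informative = list(df.columns[:n_informative])
    if n_informative > 0:
        signal = np.nan_to_num(df[informative].to_numpy(dtype=float)).sum(axis=1)
        logits = effect_size * signal / np.sqrt(max(n_informative, 1))
    else:
        logits = np.zeros(n)
    intercept = np.log(class_balance / (1 - class_balance))
    p = 1.0 / (1.0 + np.exp(-(logits + intercept)))
    labels = (rng.random(n) < p).astype(int)
    return SyntheticTabular(
        matrix=df,
        labels=labels,
        informative_columns=informative,
        generation_params={
            "n": n, "d": d, "n_informative": n_informative,
            "effect_size": effect_size, "class_balance": class_balance,
            "seed": seed, "n_correlated": n_correlated,
            "missing_fraction": missing_fraction,
        },
    )


def make_synthetic_regression(
    n: int = 500,
    d: int = 100,
    n_informative: int = 10,
    coef_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_correlated: int = 0,
    missing_fraction: float = 0.0,
) -> SyntheticTabular:
    """Continuous response = linear combination of informative columns
    (+/- coef_scale coefficients) plus Gaussian noise.

    The population R^2 ceiling is
    ``n_informative * coef_scale**2 / (n_informative * coef_scale**2 + noise_sd**2)``
    (unit-variance independent features).
    """
    if n_informative > d:
        raise ValueError("n_informative must be <= d")
    rng = np.random.default_rng(seed)
    df = _base_features(n, d, rng, n_correlated, missing_fraction)
    informative = list(df.columns[:n_informative])
    coefs = coef_scale * np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    if n_informative > 0:
        signal = np.nan_to_num(df[informative].to_numpy(dtype=float)) @ coefs
    else:
        signal = np.zeros(n)
    y = signal + noise_sd * rng.standard_normal(n)
    var_signal = n_informative * coef_scale**2
    ceiling = var_signal / (var_signal + noise_sd**2) if (var_signal + noise_sd**2) else 0.0
    return SyntheticTabular(
        matrix=df,
        labels=y,
        informative_columns=informative,
        generation_params={
            "n": n, "d": d, "n_informative": n_informative,
            "coef_scale": coef_scale, "noise_sd": noise_sd, "seed": seed,
            "n_correlated": n_correlated, "missing_fraction": missing_fraction,
            "r2_ceiling": ceiling,
        },
    )


#: ~30 small drug-like molecules with hand-assigned synthetic IC50s (nM)
#: spanning 1-10,000 nM. Planted features: CPD024/CPD025 are the same
#: structure measured twice (concordant duplicate), CPD026 is a sodium
#: salt, CPD027 carries a crystallization water, CPD028 is an invalid
#: SMILES, CPD029/CPD030 are a discordant duplicate pair.
_TOY_MOLECULES: list[tuple[str, str, float, str]] = [
    ("CPD001", "CC(=O)Oc1ccccc1C(=O)O", 8200.0, "="),          # aspirin
    ("CPD002", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 3500.0, "="),     # ibuprofen
    ("CPD003", "CC(=O)Nc1ccc(O)cc1", 9600.0, "="),             # paracetamol
    ("CPD004", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 7400.0, "="),     # caffeine
    ("CPD005", "OC(=O)c1ccccc1O", 6100.0, "="),                # salicylic acid
    ("CPD006", "Clc1ccccc1C(=O)Nc1ccccc1", 410.0, "="),
    ("CPD007", "O=C(Nc1ccc(F)cc1)c1ccco1", 95.0, "="),
    ("CPD008", "CCOC(=O)c1ccc(N)cc1", 2300.0, "="),            # benzocaine
    ("CPD009", "CN1CCC(CC1)Oc1ccccc1", 150.0, "="),
    ("CPD010", "Nc1ncnc2n(cnc12)C1OC(CO)C(O)C1O", 45.0, "="),  # adenosine-like
    ("CPD011", "OCCN1CCN(CC1)c1ccccn1", 28.0, "="),
    ("CPD012", "Fc1ccc(cc1)C(=O)N1CCOCC1", 62.0, "="),
    ("CPD013", "CC(N)Cc1ccccc1", 8800.0, "="),                 # amphetamine
    ("CPD014", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", 1900.0, "="),   # naproxen
    ("CPD015", "NC(=O)c1ccc(cc1)S(N)(=O)=O", 5400.0, "="),
    ("CPD016", "CN(C)CCCN1c2ccccc2CCc2ccccc21", 330.0, "="),   # imipramine
    ("CPD017", "c1ccc2[nH]ccc2c1", 9900.0, "="),               # indole
    ("CPD018", "OC1CCCCC1N1CCCCC1", 740.0, "="),
    ("CPD019", "N#Cc1ccc(cc1)N1CCN(CC1)C(=O)C1CC1", 12.0, "="),
    ("CPD020", "CC1(C)CC(=O)N(Cc2ccc(F)cc2)C1=O", 36.0, "="),
    ("CPD021", "O=C(N1CCCC1)c1cnc2ccccc2c1", 18.0, "="),
    ("CPD022", "CC(C)n1cnc2c(N)ncnc21", 4.5, "="),
    ("CPD023", "CN1CCN(CC1)c1ncnc2[nH]cnc12", 1.2, "="),
    # concordant duplicate pair (same structure, close IC50s)
    ("CPD024", "COc1ccccc1N1CCN(CC1)C(=O)c1ccco1", 100.0, "="),
    ("CPD025", "O=C(c1ccco1)N1CCN(CC1)c1ccccc1OC", 110.0, "="),
    # sodium salt of a carboxylic acid
    ("CPD026", "CC(=O)[O-].[Na+]", 8700.0, "="),
    # crystallization water alongside the organic component
    ("CPD027", "O.Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1", 2700.0, "="),
    # planted invalid SMILES
    ("CPD028", "C1CC1(((", 500.0, "="),
    # discordant duplicate pair (same structure, wildly different IC50s)
    ("CPD029", "Brc1ccc(cc1)C(=O)NCCN1CCOCC1", 10.0, "="),
    ("CPD030", "O=C(NCCN1CCOCC1)c1ccc(Br)cc1", 1000.0, "="),
    ("CPD031", "CCN(CC)C(=O)c1ccc(N)cc1", 6400.0, "="),        # procainamide-like
    ("CPD032", "COc1cc2c(cc1OC)CCN(C)C2", 850.0, "="),
]


def toy_molecule_set() -> list[ActivityRecord]:
    """Fixed fixture of ~30 small molecules with synthetic IC50s.

    Includes deliberate duplicates (one concordant, one discordant
    pair), a salt form, a water-containing entry, and one invalid
    SMILES, so the whole curate -> train -> predict path can be
    exercised end-to-end.
    """
    return [
        ActivityRecord(compound_id=cid, smiles=smi, ic50=ic50, relation=rel,
                       source_tag="synthetic fixture")
        for cid, smi, ic50, rel in _TOY_MOLECULES
    ]
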