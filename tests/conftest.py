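import numpy as np
import pandas as pd
import pytest

import qsarpipe as qp


@pytest.fixture(scope="session")
def toy_records():
    return qp.toy_molecule_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_classification():
    """Medium synthetic classification problem with strong planted signal."""
    return qp.make_synthetic_classification(
        n=300, d=30, n_informative=6, effect_size=2.0, seed=7
    )


def random_missing_matrix(rng, n_rows, n_cols, missing_fraction=0.15):
    """Continuous random matrix with scattered missing cells and no
    fully-missing column/row."""
    X = rng.normal(size=(n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < missing_fraction
    for j in range(n_cols):
        if mask[:, j].all():
            mask[0, j] = False
    for i in range(n_rows):
        if mask[i, :].all():
            mask[i, 0] = False
    X = X.copy()
    X[mask] = np.nan
    return pd.DataFrame(X, columns=[f"c{j}" for j in range(n_cols)])
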