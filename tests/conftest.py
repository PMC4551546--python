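import numpy as np
import pandas as pd
import pytest

from qsarkit.standardize import MoleculeRecord, standardise_molecules


def records_from(*smiles: str) -> list[MoleculeRecord]:
    return [MoleculeRecord(id=f"m{i}", smiles_raw=s) for i, s in enumerate(smiles)]


@pytest.fixture
def std_records():
    """A handful of standardised small organics."""

    def make(*smiles):
        recs = standardise_molecules(records_from(*smiles))
        assert all(r.status == "kept" for r in recs)
        return recs

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_matrix(rng):
    """A random descriptor matrix with no degenerate columns."""
    X = rng.normal(size=(60, 8))
    return pd.DataFrame(X, columns=[f"d{j}" for j in range(8)])
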