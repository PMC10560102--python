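import numpy as np
import pandas as pd
import pytest

from logbbpred.chem_io import MoleculeRecord, canonicalize
from logbbpred.featurization import DescriptorTable


def record(smiles: str, logbb: float | None = None, rid: str = "x") -> MoleculeRecord:
    return MoleculeRecord(
        id=rid, smiles_raw=smiles, smiles_canonical=canonicalize(smiles), logbb=logbb
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_table():
    """5 compounds x 3 descriptors, no missing values."""
    frame = pd.DataFrame(
        {
            "mw": [16.0, 30.1, 44.1, 58.1, 72.2],
            "rings": [0.0, 0.0, 1.0, 1.0, 2.0],
            "logp": [0.5, 1.0, 1.4, 1.9, 2.3],
        },
        index=[f"c{i}" for i in range(5)],
    )
    return DescriptorTable(data=frame)
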