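import pandas as pd
import pytest

from herbtox.examples import load_example_retrieves


@pytest.fixture(scope="session")
def example_retrieves():
    return load_example_retrieves()


@pytest.fixture()
def toy_table():
    """5-row raw compound table; rows 2 and 4 (1-indexed) pass the ADME screen."""
    return pd.DataFrame(
        {
            "Molecule Name": [f"cpd-{i}" for i in range(1, 6)],
            "isomeric_smiles": ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "C1CCCCC1"],
            "OB": [0.1, 0.3, 0.5, 0.35, 0.2],
            "DL": [0.2, 0.18, 0.1, 0.5, 0.3],
            "Herb": ["herb-A"] * 5,
        }
    )
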