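import numpy as np
import pandas as pd
import pytest

from milletmyco.io import CountTable, SampleMetadata
from milletmyco.simulate import SimConfig, generate_dataset
from milletmyco.diversity import rarefy


@pytest.fixture(scope="session")
def default_dataset():
    """One full 60-sample simulated survey at the default design."""
    return generate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def rarefied_default(default_dataset):
    table, metadata, *_ = default_dataset
    rt = rarefy(table, 25_556, seed=7)
    return rt, metadata.select_samples(rt.sample_ids)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 0, 3], [1, 2, 0], [0, 4, 4], [2, 2, 2]],
        index=["O1", "O2", "O3", "O4"],
        columns=["sA", "sB", "sC"],
    )
    return CountTable(counts)


@pytest.fixture
def toy_metadata(toy_table):
    return SampleMetadata(
        pd.DataFrame(
            {
                "site": ["S1", "S1", "S2"],
                "plant_type": ["cultivated", "wild", "wild"],
                "plot": ["P1", "P1", "P2"],
                "total_P": [70.0, 80.0, 60.0],
                "pH_H2O": [6.1, 6.3, 6.0],
            },
            index=toy_table.sample_ids,
        )
    )
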