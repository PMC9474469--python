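import numpy as np
import pandas as pd
import pytest

from elsanet import AbundanceTable


@pytest.fixture
def toy_counts() -> AbundanceTable:
    """Six samples (2 treatments x 3 generations), four OTUs."""
    data = pd.DataFrame(
        {
            "OTU_a": [40, 35, 30, 10, 12, 14],
            "OTU_b": [30, 30, 30, 50, 48, 46],
            "OTU_c": [20, 25, 30, 30, 30, 30],
            "OTU_d": [10, 10, 10, 10, 10, 10],
        },
        index=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame(
        {
            "treatment": ["t1"] * 3 + ["t2"] * 3,
            "generation": [1, 2, 3, 1, 2, 3],
            "replicate": [1, 1, 1, 1, 1, 1],
        },
        index=data.index,
    )
    return AbundanceTable(data, meta, units="counts")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
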