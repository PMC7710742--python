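import numpy as np
import pandas as pd
import pytest

from hmcmap import GenomeTable, SampleTable, SignalMatrix


@pytest.fixture
def toy_genome():
    return GenomeTable({"chr1": 3000, "chr2": 2000})


@pytest.fixture
def small_matrix():
    """3 genes × 4 samples (2 tissues × 2 donors)."""
    df = pd.DataFrame(
        {
            "A_d1": [2.0, 40.0, 5.0],
            "A_d2": [4.0, 40.0, 5.0],
            "B_d1": [3.0, 10.0, 5.0],
            "B_d2": [3.0, 10.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    return SignalMatrix(df)


@pytest.fixture
def small_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["A_d1", "A_d2", "B_d1", "B_d2"],
                "tissue": ["A", "A", "B", "B"],
                "donor": ["d1", "d2", "d1", "d2"],
            }
        )
    )
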