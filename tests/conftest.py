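import numpy as np
import pandas as pd
import pytest

from repde import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples (2 R, 2 S), hand-sized linear intensities."""
    values = pd.DataFrame(
        {
            "R1": [100.0, 50.0, 8.0],
            "R2": [110.0, 55.0, 9.0],
            "S1": [80.0, 60.0, 2.0],
            "S2": [85.0, 58.0, 2.5],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ExpressionMatrix(values, {"R1": "R", "R2": "R", "S1": "S", "S2": "S"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150715)
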