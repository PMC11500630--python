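import numpy as np
import pandas as pd
import pytest

from impbench.core_data import MixedDataset, VariableSchema


@pytest.fixture
def mixed_toy():
    """6-row mixed-type table with two missing cells."""
    schema = [
        VariableSchema("x", "continuous"),
        VariableSchema("grp", "categorical", categories=("a", "b", "c")),
    ]
    frame = pd.DataFrame(
        {
            "x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0],
            "grp": ["a", "a", "b", np.nan, "c", "b"],
        }
    )
    return MixedDataset(schema, frame)


@pytest.fixture
def correlated_gaussian():
    """Complete 3-variable Gaussian with strong correlation (rho ~ 0.85)."""
    rng = np.random.default_rng(424242)
    n = 150
    z = rng.standard_normal(n)
    frame = pd.DataFrame(
        {
            "v1": 10 + 2 * z + 0.6 * rng.standard_normal(n),
            "v2": -5 + 3 * z + 0.9 * rng.standard_normal(n),
            "v3": 50 - 4 * z + 1.2 * rng.standard_normal(n),
        }
    )
    schema = [VariableSchema(c, "continuous") for c in frame.columns]
    return MixedDataset(schema, frame)
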