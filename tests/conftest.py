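import warnings

import numpy as np
import pandas as pd
import pytest

import omicdiv as od

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def preset_dataset():
    """One realisation of the seasonal/diel preset (6 samples, depth 4070)."""
    spec, samples = od.seasonal_preset(seed=11)
    return od.generate_community_series(spec, samples)


@pytest.fixture
def small_counts():
    """Tiny deterministic count table: 5 features x 4 samples, two groups with
    disjoint dominant features."""
    return pd.DataFrame(
        {
            "a1": [30, 20, 5, 0, 0],
            "a2": [28, 22, 4, 1, 0],
            "b1": [0, 1, 5, 30, 19],
            "b2": [0, 0, 4, 28, 23],
        },
        index=[f"f{i}" for i in range(5)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
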