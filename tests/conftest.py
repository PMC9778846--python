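import warnings

import numpy as np
import pandas as pd
import pytest

from calcmicro import SimConfig, simulate_profiles

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def study():
    """One simulated study (table, metadata, ground truth) shared read-only."""
    return simulate_profiles(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_counts():
    """Tiny hand-made count table: 4 taxa x 4 samples, no zeros."""
    return pd.DataFrame(
        {
            "s1": [1, 2, 4, 8],
            "s2": [2, 4, 8, 16],
            "s3": [5, 5, 5, 5],
            "s4": [10, 1, 1, 10],
        },
        index=["Genus1 spA", "Genus1 spB", "Genus2 spC", "Genus3 spD"],
    )


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
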