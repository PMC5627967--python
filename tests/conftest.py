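import numpy as np
import pytest

from fabricsense import ApparatusConfig
from fabricsense.dynamics import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """10+10 jersey trials, 0 N vs 3 N, the standard study conditions."""
    return generate_dataset(ApparatusConfig(), trials_per_condition=10,
                            conditions=(0.0, 3.0), master_seed=42)


@pytest.fixture(scope="session")
def short_config():
    """One-second trials for cheap dynamics unit tests."""
    return ApparatusConfig(duration=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
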