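import numpy as np
import pytest
from hypothesis import settings

from sigmacall import SyntheticConfig, load_housekeeping_table
from sigmacall.synthetic_data import generate

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def housekeeping():
    return load_housekeeping_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset shared by read-track tests."""
    cfg = SyntheticConfig(replicon_length=20_000, n_promoters=20, seed=123)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
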