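import numpy as np
import pytest

from phonotaxnet.synthetic_data import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded 218-pattern dataset with the default design, shared read-only."""
    return generate_dataset(rng=20260923)
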