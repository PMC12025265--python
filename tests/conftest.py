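import numpy as np
import pytest

from spinebmd import phantom


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    return phantom.PhantomConfig(image_size=64, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Forty 64x64 phantom samples shared across tests."""
    return [phantom.synthesize_sample(small_config, i) for i in range(40)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
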