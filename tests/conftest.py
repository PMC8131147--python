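import numpy as np
import pytest

from emofuse import pipeline as pl
from emofuse import synthetic as sy


@pytest.fixture(scope="session")
def small_dataset():
    """18 balanced trials at default study conditions."""
    return sy.generate_dataset(sy.SynthConfig(n_trials=18, seed=11))


@pytest.fixture(scope="session")
def small_config():
    return pl.RunConfig(seed=3, epochs=2, batch_size=8)


@pytest.fixture(scope="session")
def small_features(small_dataset, small_config):
    return pl.extract_features(small_dataset, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
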