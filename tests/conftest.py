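import numpy as np
import pytest

from sanipath import McmcSettings, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def light_mcmc():
    """Trimmed sampler settings for unit tests; long enough to mix on the
    small models used here."""
    return McmcSettings(chains=2, iterations=2000, burn_in=500, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
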