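import numpy as np
import pytest

from islandevo import Config, make_fixture


@pytest.fixture
def config() -> Config:
    return Config()


@pytest.fixture
def tiny_config() -> Config:
    """Heavily scaled config for fast end-to-end runs (evolve 100 steps)."""
    return Config().scaled(1000)


@pytest.fixture
def desk_config() -> Config:
    """The supported desk-scale study configuration."""
    return Config().scaled(100)


@pytest.fixture
def founder(config):
    return make_fixture("founder", config, seed=0)


@pytest.fixture
def midweb(config):
    return make_fixture("midweb", config, seed=0)


@pytest.fixture
def forest(config):
    return make_fixture("pre_invasion_forest", config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
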