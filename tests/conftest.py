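import numpy as np
import pytest

from troponin_cea import ModelConfig, build_strategies, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def strategies(params, config):
    return {s.name: s for s in build_strategies(params, config)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
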