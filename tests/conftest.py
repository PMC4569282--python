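import numpy as np
import pytest

from turtlelrp.life_history import LifeHistoryConfig, build_transition_matrix


@pytest.fixture(scope="session")
def life_cfg():
    return LifeHistoryConfig()


@pytest.fixture(scope="session")
def means_params(life_cfg):
    return life_cfg.means()


@pytest.fixture(scope="session")
def means_matrix(means_params):
    """The 14x14 means-case transition matrix at the mean growth rate 1.05."""
    return build_transition_matrix(means_params, target_lambda=1.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)
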