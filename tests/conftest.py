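import numpy as np
import pytest

from loudadapt.design import make_exp1_design, make_exp3_design
from loudadapt.observer import default_observer_params, simulate_session


@pytest.fixture(scope="session")
def exp1_design():
    return make_exp1_design("baseline", seed=7)


@pytest.fixture(scope="session")
def exp3_quiet_design():
    return make_exp3_design("quiet", seed=7)


@pytest.fixture(scope="session")
def default_params():
    return default_observer_params()


@pytest.fixture(scope="session")
def simulated_records(exp1_design, default_params):
    return simulate_session(exp1_design, default_params, seed=11, subject="s0")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
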