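import numpy as np
import pytest

import lcachoice as lc


@pytest.fixture(scope="session")
def params() -> lc.ModelParameters:
    """The calibrated default parameter set."""
    return lc.default_parameters()


@pytest.fixture(scope="session")
def sim_design():
    return lc.build_design(lc.SIMULATION_PRESET)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
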