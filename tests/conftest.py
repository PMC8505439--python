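import numpy as np
import pytest

from vortexfit import OpticalConfig
from vortexfit.optics_model import build_pupil


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture(scope="session")
def pupil(config):
    return build_pupil(config)


@pytest.fixture(scope="session")
def standard_config(config):
    return config.with_(vortex_charge=0)


@pytest.fixture(scope="session")
def standard_pupil(standard_config):
    return build_pupil(standard_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
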