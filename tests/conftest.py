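import numpy as np
import pytest

from gastric_cea import (ModelSettings, WeibullParams, load_default_config,
                         run_base_case)

# Published Weibull survivor parameters (time in 6-week cycles)
SO_PFS = WeibullParams(0.017869, 1.055532)
SO_OS = WeibullParams(0.005483, 1.19)
XELOX_PFS = WeibullParams(0.010007, 1.055532)
XELOX_OS = WeibullParams(0.003948, 1.19)
S1_PFS = WeibullParams(0.011079, 1.055532)
S1_OS = WeibullParams(0.003728, 1.19)

CURVES = {
    "SO": (SO_PFS, SO_OS),
    "XELOX": (XELOX_PFS, XELOX_OS),
    "S-1": (S1_PFS, S1_OS),
}


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def base_case(config):
    return run_base_case(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20131210)
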