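import numpy as np
import pytest

from angioswitch.config import params_from_config, reference_config


@pytest.fixture(scope="session")
def bif_config():
    return reference_config("bifurcation")


@pytest.fixture(scope="session")
def bif_params(bif_config):
    """Reference parameter set of the bistability/hysteresis analyses."""
    return params_from_config(bif_config)


@pytest.fixture(scope="session")
def matrix_config():
    return reference_config("matrix")


@pytest.fixture(scope="session")
def matrix_params(matrix_config):
    """Reference parameter set of the low-VEGF patterning-time matrices."""
    return params_from_config(matrix_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
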