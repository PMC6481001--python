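import numpy as np
import pytest

from chondrosim import Grid1D, default_parameters, nondimensionalise


@pytest.fixture(scope="session")
def dimless():
    """Reference dimensionless parameter set."""
    return nondimensionalise(default_parameters())


@pytest.fixture(scope="session")
def grid200():
    return Grid1D(200)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
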