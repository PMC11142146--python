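import numpy as np
import pytest

from trtsim.params import ModelParameters


@pytest.fixture(scope="session")
def basic():
    """Reference parameter set."""
    return ModelParameters.basic()


@pytest.fixture(scope="session")
def pure(basic):
    """Reference parameters without drug impurity."""
    return basic.replace(eta=0.0)


@pytest.fixture(scope="session")
def fast_sim():
    """Solver settings for population-scale tests: endpoint accuracy traded
    for speed."""
    return dict(rtol=1e-6, atol=1e-10, grid_per_day=6, refine_nmin=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
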