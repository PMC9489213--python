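import numpy as np
import pytest

from sytfuse import best_fit_parameters


@pytest.fixture(scope="session")
def params3():
    """Best-fit parameter set for the three-slot model."""
    return best_fit_parameters(3)


@pytest.fixture(scope="session")
def small_params():
    """A small, fast state space (3 syts, 2 slots) with moderate rates."""
    return best_fit_parameters(3).replace(n_syts=3, M_slots=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
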