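import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

from thrombosim import default_parameters, init_steady_state


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def build():
    """Default full-model build at steady state (shared across tests)."""
    return init_steady_state()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
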