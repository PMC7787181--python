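import numpy as np
import pytest

from chromarch.simulate import SimParams, simulate_genome


@pytest.fixture(scope="session")
def params():
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def genome(params):
    """One shared synthetic genome (sequences, truth) for the session."""
    return simulate_genome(params)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
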