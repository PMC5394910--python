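import numpy as np
import pytest

from nsctfuse import make_phantom_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair_64():
    """One small phantom pair shared by pipeline-level tests."""
    return make_phantom_pair(7, size=64)


@pytest.fixture(scope="session")
def phantom_pair_128():
    return make_phantom_pair(7, size=128)
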