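import numpy as np
import pytest

from wbdecode.core import Arena
from wbdecode.preprocessing import make_frequency_bank


@pytest.fixture(scope="session")
def arena():
    return Arena(175.0, 125.0)


@pytest.fixture(scope="session")
def wideband_bank():
    """The canonical 26-band bank from 15 kHz down to 2 Hz."""
    return make_frequency_bank(15000.0, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
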