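import numpy as np
import pytest

from oispec import BaselineState, default_spectra


@pytest.fixture(scope="session")
def spectra():
    return default_spectra()


@pytest.fixture(scope="session")
def baseline():
    return BaselineState()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
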