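import numpy as np
import pytest

from consonance import TimbreParams
from consonance.composite import composite_profile


@pytest.fixture(scope="session")
def grid15():
    return np.linspace(0.0, 15.0, 1000)


@pytest.fixture(scope="session")
def harmonic_timbre():
    return TimbreParams.harmonic()


@pytest.fixture(scope="session")
def composite_profile_harmonic(grid15, harmonic_timbre):
    return composite_profile(grid15, harmonic_timbre)


@pytest.fixture(scope="session")
def composite_profile_stretched(grid15):
    return composite_profile(grid15, TimbreParams.stretched(2.1))
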