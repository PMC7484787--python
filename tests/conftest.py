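import numpy as np
import pytest

from mcflim.decay import delta_irf, gaussian_irf
from mcflim import synthetic


@pytest.fixture(scope="session")
def dirac():
    return delta_irf()


@pytest.fixture(scope="session")
def girf():
    return gaussian_irf()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-composition 407-cell synthetic cohort, drawn once per session."""
    return synthetic.generate_cohort(rng=np.random.default_rng(20_240_901))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
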