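import numpy as np
import pytest

from fcsreact.params import from_dimensionless


@pytest.fixture(scope="session")
def fig_point():
    """The reference intermediate-rate parameter point
    (tau_B/tau_D = 1/6, beta = 0.5, v = 1, hence R tau_B = 7/3)."""
    return from_dimensionless(1.0 / 6.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def immobile_point():
    """Immobile binding sites (D = 0) in the fast-diffusion regime."""
    return from_dimensionless(0.0, 0.5, 1e3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240322)
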