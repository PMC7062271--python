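import numpy as np
import pytest

from amura.phantom import make_scheme

TAU = 0.05


@pytest.fixture(scope="session")
def scheme64():
    """64-direction electrostatic-repulsion scheme shared across tests."""
    return make_scheme(64, seed=1)


@pytest.fixture(scope="session")
def scheme128():
    return make_scheme(128, seed=1)


def isotropic_expected(d0: float, tau: float = TAU) -> dict[str, float]:
    """Closed-form isotropic Gaussian limits of the three measures."""
    x = 4.0 * np.pi * tau * d0
    return {"RTOP": x ** -1.5, "RTPP": x ** -0.5, "RTAP": x ** -1.0}
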