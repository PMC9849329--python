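import numpy as np
import pytest

from cosplice.commitment import FEW_STEPS, CommitmentParams


@pytest.fixture(scope="session")
def vpol_grid():
    """Log-spaced polymerase velocity grid spanning 1-1000 nt/s."""
    return np.logspace(0, 3, 50)


@pytest.fixture(scope="session")
def basic_params():
    """Basic commitment model without RBP escape."""
    return CommitmentParams(ki=0.1, ks=0.1, kesc=0.0)


@pytest.fixture(scope="session")
def few_steps():
    return FEW_STEPS


@pytest.fixture(scope="session")
def random_rate_sets():
    """Seeded random (ki, ks, kesc, vpol) draws in the physiological box."""
    rng = np.random.default_rng(20230118)
    n = 120
    rates = 10.0 ** rng.uniform(-3, 1, size=(n, 3))
    vpol = 10.0 ** rng.uniform(0, 3, size=n)
    return rates, vpol
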