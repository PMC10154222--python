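import numpy as np
import pytest

from topomech import DsDnaElasticity, McSettings


@pytest.fixture(scope="session")
def elasticity():
    return DsDnaElasticity()


@pytest.fixture(scope="session")
def inextensible():
    """Effectively inextensible dsDNA for closed-form comparisons."""
    return DsDnaElasticity(stretch_modulus=1e9)


@pytest.fixture(scope="session")
def quick_mc():
    """Small MC schedule for unit tests."""
    return McSettings(n_equil=10_000, n_prod=50_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
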