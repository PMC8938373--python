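import numpy as np
import pytest

from nbackerp.montage import make_montage


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4+4-subject cohort with default effects (shared across tests)."""
    from nbackerp.simulate import simulate_cohort

    return simulate_cohort(4, seed=2024)
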