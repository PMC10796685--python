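import numpy as np
import pytest

import bimanual as bm


@pytest.fixture(scope="session")
def small_pop():
    """48-channel population with laterality, suppression and decorrelation."""
    return bm.sample_population(
        n_channels=48,
        rho_x=0.5,
        rho_y=0.5,
        lat_scale=1.0,
        suppression=(1.0, 0.66),
        context_correlation=(0.85, 0.45),
        seed=7,
    )


@pytest.fixture(scope="session")
def uni_pop():
    """Population without bimanual tuning changes (for decoding tests)."""
    return bm.sample_population(
        n_channels=48,
        rho_x=0.5,
        rho_y=0.5,
        lat_scale=1.0,
        suppression=(1.0, 1.0),
        context_correlation=None,
        seed=3,
    )


@pytest.fixture(scope="session")
def session_noiseless(small_pop):
    """Delayed-movement session with all three trial types, no noise."""
    return bm.generate_session(small_pop, n_per_type=24, types=(0, 1, 2), seed=5)


@pytest.fixture(scope="session")
def session_noisy(small_pop):
    return bm.generate_session(
        small_pop, n_per_type=24, types=(0, 1, 2), seed=5, noise=bm.NoiseModel(4.0)
    )
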