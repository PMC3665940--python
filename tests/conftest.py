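import numpy as np
import pytest

from cpgdrnn import GaitGenConfig, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless, jitter-free 3 km/h trial (20 s @ 100 Hz)."""
    return generate_trial(
        GaitGenConfig(velocity_kmh=3.0, duration_s=20.0, noise_sd=0.0, cycle_jitter=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def default_trial():
    """3 km/h trial with the default noise and cycle jitter."""
    return generate_trial(GaitGenConfig(velocity_kmh=3.0, duration_s=20.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
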