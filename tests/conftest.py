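import numpy as np
import pytest

import mycometry as m

# scaled-down study configurations shared across the suite; session scope
# keeps the simulation cost paid once


@pytest.fixture(scope="session")
def clean_config():
    """Noise- and gradient-free scaled culture, three frames."""
    return m.scaled_study_config(
        0.12, seed=5, noise_sd=0.0, illum_gradient_amp=0.0,
        frame_times_h=(0.0, 23.0, 29.0),
    )


@pytest.fixture(scope="session")
def clean_series(clean_config):
    return m.generate_series(clean_config)


@pytest.fixture(scope="session")
def noisy_config():
    """Default-noise scaled culture over the full observation schedule."""
    return m.scaled_study_config(0.15, seed=11)


@pytest.fixture(scope="session")
def noisy_series(noisy_config):
    return m.generate_series(noisy_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
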