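import numpy as np
import pytest

import evaquant as ev


@pytest.fixture(scope="session")
def noise_free_params():
    """Small noise-free field: 4 nuclei, 2 foci each, known ratio 0.8,
    integer chromatic shift so registration resampling is exact."""
    return ev.SimParams(
        image_shape=(512, 512),
        n_nuclei=4,
        foci_per_nucleus=2,
        true_ratio=0.8,
        shot_noise=False,
        read_sigma=0.0,
        texture_strength=0.0,
        chromatic_shift=(2.0, -1.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def noise_free_specimen(noise_free_params):
    return ev.generate_specimen(noise_free_params)


@pytest.fixture(scope="session")
def noisy_params():
    """Simulator defaults (shot + read noise on) at a fixed seed."""
    return ev.SimParams(n_nuclei=6, foci_per_nucleus=(1, 4), true_ratio=0.8, seed=2)


@pytest.fixture(scope="session")
def noisy_specimen(noisy_params):
    return ev.generate_specimen(noisy_params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
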