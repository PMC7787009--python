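import numpy as np
import pytest

from repsim import PlantedDesign, generate_behavior, generate_eeg_like, generate_fmri_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return PlantedDesign(
        n_conditions=4, n_subjects=3, n_trials=5, signal_effect=1.5, noise_sd=1.0, seed=7
    )


@pytest.fixture
def behavior_data(small_design):
    return generate_behavior(small_design)


@pytest.fixture
def eeg_data(small_design):
    return generate_eeg_like(small_design, n_channels=3, n_times=20)


@pytest.fixture
def fmri_data(small_design):
    return generate_fmri_like(small_design, image_size=(6, 6, 6))
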