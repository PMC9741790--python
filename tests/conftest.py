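import numpy as np
import pytest

from gaitent.synthetic import GaitParams, generate_recording


@pytest.fixture
def clean_params():
    """Deterministic, perfectly periodic gait: no noise, jitter, cv or drift."""
    return GaitParams(
        stride_time_cv=0.0,
        waveform_noise_sd=0.0,
        within_cycle_shape_jitter=0.0,
        drift_rate=0.0,
        n_strides=10,
        mean_stride_time=1.06,
        seed=0,
    )


@pytest.fixture
def clean_recording(clean_params):
    return generate_recording(clean_params)


@pytest.fixture
def noisy_params():
    """Realistic stride-time variability and channel noise."""
    return GaitParams(
        stride_time_cv=0.02,
        waveform_noise_sd={"copap": 0.2, "copml": 0.1, "vgrf": 4.0},
        within_cycle_shape_jitter=0.1,
        n_strides=30,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
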