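import numpy as np
import pytest

from palmpulse.synth import NoiseParams, PulseModelParams, generate_clean_ppg


@pytest.fixture(scope="session")
def default_params():
    return PulseModelParams()


@pytest.fixture(scope="session")
def clean_pulse(default_params):
    """20 s, 100 Hz annotated pulse at 72 bpm."""
    return generate_clean_ppg(default_params, 20.0, 100.0, seed=42)


@pytest.fixture(scope="session")
def periodic_pulse():
    """Degenerate single-lobe, zero-HRV pulse: strictly periodic at 1 Hz."""
    params = PulseModelParams(
        heart_rate_bpm=60.0, hrv_cv=0.0, notch_depth=0.0, second_peak_amp=0.0
    )
    return generate_clean_ppg(params, 20.0, 100.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseParams()
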