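import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from smsweep import (  # noqa: E402
    SweepConfig, CameraModel, KineticModel, dual_channel_layout,
)


@pytest.fixture
def blinking_sweep() -> SweepConfig:
    """5-step, 96 mV sweep: 4-ms substeps spaced 6 px."""
    return SweepConfig(n_steps=5, voltage_mV=96.0, slope_px_per_mV=0.25,
                       exposure_ms=20.0, frame_lag_ms=1.7)


@pytest.fixture
def quiet_camera() -> CameraModel:
    """Unity-gain, noise-free camera for deterministic expectations."""
    return CameraModel(em_gain=1.0, read_noise_sd=0.0, baseline=0.0)


@pytest.fixture
def always_bright() -> KineticModel:
    """A molecule pinned to the bright state (k_off = 0)."""
    return KineticModel(k_on=1.0, k_off=0.0, bright_rate=60.0)


@pytest.fixture
def small_layout():
    return dual_channel_layout(height=64, channel_width=48)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
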