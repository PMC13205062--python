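"""Shared fixtures: simulated sessions reused across test modules."""
import warnings

import numpy as np
import pytest

from fatigue3.config import RunConfig
from fatigue3.synthetic import make_scenario, simulate_session

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


ZERO_NOISE = dict(
    mayer_amp_um=0.0,
    resp_amp_um=0.0,
    pulse_amp_hbo_um=0.0,
    pulse_amp_hbr_um=0.0,
    od_noise_sd=0.0,
    od_noise_sd_short=0.0,
    motion_spike_rate_per_min=0.0,
    drift_od_amp=0.0,
    eeg_noise_sd_uv=0.0,
    ocular_rate_per_min=0.0,
    crosstalk_amp_uv=0.0,
)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def active_session():
    """One full-length active session with all noise sources at defaults."""
    spec = make_scenario("active", seed=11)
    return simulate_session(spec) + (spec,)


@pytest.fixture(scope="session")
def clean_session():
    """Zero-noise session with constant drive hemodynamics (exactness checks)."""
    spec = make_scenario(
        "active",
        seed=12,
        overrides=dict(
            ZERO_NOISE,
            hbo_um={"NonF": 0.3, "ModF": 0.3, "SevF": 0.3},
            hbr_um={"NonF": -0.1, "ModF": -0.1, "SevF": -0.1},
        ),
    )
    return simulate_session(spec) + (spec,)


@pytest.fixture(scope="session")
def short_session():
    """A 12-minute session for I/O round trips (small files, fast)."""
    spec = make_scenario(
        "active",
        seed=13,
        overrides=dict(drive_s=720.0, transition_times_min=(4.0, 8.0)),
    )
    return simulate_session(spec) + (spec,)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
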