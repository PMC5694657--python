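import numpy as np
import pytest

from hrvsdi import SimulationParams, simulate_case
from hrvsdi.synthetic import StateProfile


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free rendering so detection oracles are exact."""
    return SimulationParams(duration=600.0, seed=7,
                            powerline_amplitude=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_case(clean_params):
    """(profile, rr, record, true_peaks, assessors) for a clean case."""
    return simulate_case(clean_params)


def constant_profile(doa_level: float, duration: float) -> StateProfile:
    """Flat DoA trajectory (bypasses the four-stage generator)."""
    times = np.arange(0.0, duration, 1.0)
    stage = "awake" if doa_level > 65 else "maintenance"
    return StateProfile(times=times, doa=np.full(times.size, float(doa_level)),
                        stage_labels=np.full(times.size, stage, dtype=object))
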