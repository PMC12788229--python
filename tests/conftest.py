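import numpy as np
import pytest

from csirr.synth import make_schedule, synth_respiratory_waveform, synth_session


@pytest.fixture(scope="session")
def short_schedule():
    """Two-level schedule (12 -> 15 brpm, 60 s dwell), 120 s total."""
    return make_schedule(12, 3, 15, 60)


@pytest.fixture(scope="session")
def constant_waveform():
    """Noise-free 12 brpm waveform, 90 s at 50 Hz."""
    sched = make_schedule(12, 3, 12, 90)
    return synth_respiratory_waveform(sched, 50.0, jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def moderate_short_session(short_schedule):
    """Moderate-profile 120 s session with matched airflow and waveform."""
    return synth_session("moderate", short_schedule, seed=7)


def tone(freq_hz: float, duration_s: float, fs: float, amp: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)
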