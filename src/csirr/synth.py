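"""Synthetic CSI sessions, airflow traces, and metronome schedules.

The generator emulates a paced-breathing protocol: a metronome steps the
target rate from 6 to 33 brpm in 3 brpm increments every 120 s, and the
subject's chest displacement modulates the magnitude of a subset of Wi-Fi
OFDM subcarriers.  Each coupled subcarrier receives a gain- and phase-shifted
copy of a shared respiratory waveform on top of a static baseline, 1/f-like
drift, white noise, and optional broadband motion bursts.  A matched nasal
airflow trace (32 Hz) is produced from the same waveform so the reference-RR
pipeline can be exercised end to end.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

__all__ = [
    "MetronomeSchedule",
    "RespiratoryWaveform",
    "CsiSession",
    "AirflowTrace",
    "PROFILES",
    "make_schedule",
    "synth_respiratory_waveform",
    "synth_csi",
    "synth_airflow",
    "synth_session",
]

#: Named noise profiles for :func:`synth_csi` / :func:`synth_session`.
#: ``clean`` is a best-case recording: no drift, motion or pacing jitter and
#: only a small sensor noise floor (an exactly noise-free ensemble is
#: singular: PCA splits the breath harmonics of phase-lagged periodic copies
#: into separate spuriously high-quality components, a geometry no real
#: capture exhibits).  ``moderate`` is the default validation condition (a
#: fifth of subcarriers respiration-coupled, visible drift and white noise,
#: two motion bursts); ``noisy`` stresses the quality indices.
PROFILES: dict[str, dict[str, Any]] = {
    "clean": dict(
        coupled_fraction=0.2,
        modulation_depth=0.05,
        drift_scale=0.0,
        noise_scale=0.1,
        motion_events=0,
        jitter=0.0,
    ),
    "moderate": dict(
        coupled_fraction=0.2,
        modulation_depth=0.05,
        drift_scale=0.5,
        noise_scale=0.3,
        motion_events=2,
        jitter=0.5,
    ),
    "noisy": dict(
        coupled_fraction=0.2,
        modulation_depth=0.05,
        drift_scale=1.5,
        noise_scale=1.0,
        motion_events=4,
        jitter=1.0,
    ),
}


@dataclass(frozen=True)
class MetronomeSchedule:
    """Step schedule of paced breathing rates.

    ``steps`` is an ordered list of ``(onset_time_s, rate_brpm)``; each level
    is held for ``dwell`` seconds and the rate is a right-continuous step
    function of time.
    """

    start_rate: float
    increment: float
    end_rate: float
    dwell: float
    steps: tuple[tuple[float, float], ...]

    @property
    def duration(self) -> float:
        """Total schedule length in seconds."""
        return len(self.steps) * self.dwell

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.steps])

    def rate_at(self, t: float | np.ndarray) -> np.ndarray:
        """Scheduled rate (brpm) at time ``t``; right-continuous, clamped to
        the last level beyond the schedule end."""
        onsets = np.array([on for on, _ in self.steps])
        idx = np.clip(np.searchsorted(onsets, np.asarray(t, float), side="right") - 1,
                      0, len(self.steps) - 1)
        return self.rates[idx]


@dataclass
class RespiratoryWaveform:
    """Chest-displacement surrogate with per-sample ground-truth rate."""

    samples: np.ndarray          # unitless displacement, bounded
    sampling_rate: float         # Hz
    instantaneous_rate: np.ndarray  # brpm, same length as samples

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def truth_1hz(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth RR sampled at 1 Hz (time stamps, brpm)."""
        t = np.arange(0.0, self.duration, 1.0)
        idx = np.minimum((t * self.sampling_rate).astype(int), len(self.samples) - 1)
        return t, self.instantaneous_rate[idx]


@dataclass
class CsiSession:
    """Timestamped subcarrier-magnitude matrix with sampling metadata.

    ``magnitudes`` is T x K (K = 256 by default), non-negative and finite;
    ``timestamps`` are seconds at a nominal 50 Hz packet rate.  ``metadata``
    carries the sampling rate, subcarrier count, session id, and (for
    synthetic sessions) the 1 Hz ground-truth RR series.
    """

    magnitudes: np.ndarray
    timestamps: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, float)
        self.timestamps = np.asarray(self.timestamps, float)
        if self.magnitudes.ndim != 2:
            raise ValueError("magnitudes must be a T x K matrix")
        if len(self.timestamps) != self.magnitudes.shape[0]:
            raise ValueError("timestamps length must match magnitude rows")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("magnitudes must be finite")

    @property
    def n_subcarriers(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def duration(self) -> float:
        md = self.metadata
        if "sampling_rate" in md:
            return self.magnitudes.shape[0] / md["sampling_rate"]
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class AirflowTrace:
    """Nasal-pressure-like signal (unitless) at a fixed sampling rate."""

    pressure: np.ndarray
    sampling_rate: float = 32.0

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure values must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.pressure)) / self.sampling_rate


def make_schedule(start: float = 6.0, increment: float = 3.0,
                  end: float = 33.0, dwell: float = 120.0) -> MetronomeSchedule:
    """Build a paced-breathing metronome schedule.

    Levels run ``start, start+increment, ..., end`` (every level at most
    ``end``), each held for ``dwell`` seconds.  The default 6:3:33:120
    protocol has 10 levels and lasts 20 minutes.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    if start > end:
        raise ValueError("start rate must not exceed end rate")
    rates = np.arange(start, end + increment / 2, increment)
    rates = rates[rates <= end + 1e-9]
    steps = tuple((i * dwell, float(r)) for i, r in enumerate(rates))
    return MetronomeSchedule(start, increment, float(rates[-1]), dwell, steps)


def _breath_shape(cycle_frac: np.ndarray, inhale_fraction: float) -> np.ndarray:
    """Raised-cosine breath cycle with inhale/exhale asymmetry.

    Rises 0 -> 1 over the inhale fraction of the cycle and falls 1 -> 0 over
    the remainder; centred to [-0.5, 0.5].  The asymmetry introduces mild
    harmonic content, as nasal-pressure waveforms are not pure sinusoids.
    """
    a = inhale_fraction
    y = np.where(
        cycle_frac < a,
        0.5 * (1.0 - np.cos(np.pi * cycle_frac / a)),
        0.5 * (1.0 + np.cos(np.pi * (cycle_frac - a) / (1.0 - a))),
    )
    return y - 0.5


def synth_respiratory_waveform(schedule: MetronomeSchedule,
                               sampling_rate: float = 50.0,
                               jitter: float = 0.5,
                               seed: int = 0,
                               inhale_fraction: float = 0.4) -> RespiratoryWaveform:
    """Phase-continuous breathing waveform tracking a metronome schedule.

    The instantaneous rate is the scheduled rate plus a bounded random-walk
    deviation clipped to ``+-jitter`` brpm (updated once per second and
    linearly interpolated), emulating imperfect metronome compliance.
    """
    max_rate_hz = schedule.rates.max() / 60.0
    if sampling_rate <= 2.0 * max_rate_hz:
        raise ValueError("sampling rate must exceed twice the fastest breathing rate")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    rate = schedule.rate_at(t).astype(float)
    if jitter > 0:
        n_sec = int(np.ceil(schedule.duration)) + 1
        walk = np.clip(np.cumsum(rng.normal(0.0, 0.15 * jitter, n_sec)),
                       -jitter, jitter)
        rate = rate + np.interp(t, np.arange(n_sec, dtype=float), walk)
    phase = np.cumsum(rate / 60.0) / sampling_rate  # breath cycles
    samples = _breath_shape(np.mod(phase, 1.0), inhale_fraction)
    return RespiratoryWaveform(samples, sampling_rate, rate)


def _lowpassed_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     cutoff_hz: float, fs: float) -> np.ndarray:
    """Integrated white noise low-passed below ``cutoff_hz``, unit std."""
    w = np.cumsum(rng.standard_normal(shape), axis=0)
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    d = signal.sosfiltfilt(sos, w, axis=0)
    d = d - d.mean(axis=0)
    std = d.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return d / std


def synth_csi(waveform: RespiratoryWaveform,
              n_subcarriers: int = 256,
              coupled_fraction: float = 0.2,
              modulation_depth: float = 0.05,
              drift_scale: float = 0.5,
              noise_scale: float = 0.3,
              motion_events: int = 2,
              seed: int = 0,
              timestamp_jitter: bool = False,
              motion_std: float = 3.0,
              motion_duration: float = 3.0,
              session_id: str = "synthetic") -> CsiSession:
    """Generate a CSI magnitude session modulated by a breathing waveform.

    A random subset of ``coupled_fraction`` of the subcarriers receives the
    waveform with a log-normal per-subcarrier gain (``modulation_depth``
    relative to a static baseline drawn in [10, 30]) and a phase lag uniform
    within one breath period; all subcarriers receive low-frequency drift and
    white noise, plus ``motion_events`` broadband high-variance bursts of
    ``motion_duration`` seconds.  Ground truth RR (1 Hz) is carried in
    ``metadata['ground_truth_rr']``.
    """
    if not 0.0 <= coupled_fraction <= 1.0:
        raise ValueError("coupled_fraction must lie in [0, 1]")
    if min(modulation_depth, drift_scale, noise_scale) < 0:
        raise ValueError("scales must be non-negative")
    n = len(waveform.samples)
    if n == 0:
        raise ValueError("waveform must be non-empty")
    fs = waveform.sampling_rate
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    baseline = rng.uniform(10.0, 30.0, n_subcarriers)
    mags = np.tile(baseline, (n, 1))

    n_coupled = int(round(coupled_fraction * n_subcarriers))
    coupled = np.sort(rng.choice(n_subcarriers, size=n_coupled, replace=False))
    if n_coupled:
        gains = modulation_depth * baseline[coupled] * rng.lognormal(0.0, 0.5, n_coupled)
        mean_period = 60.0 / waveform.instantaneous_rate.mean()
        lags = rng.uniform(0.0, mean_period, n_coupled)
        for j, (k, g, lag) in enumerate(zip(coupled, gains, lags)):
            shifted = np.interp(t - lag, t, waveform.samples,
                                left=waveform.samples[0], right=waveform.samples[-1])
            mags[:, k] += g * shifted

    if drift_scale > 0:
        mags += drift_scale * _lowpassed_noise(rng, (n, n_subcarriers), 0.05, fs)
    if noise_scale > 0:
        mags += noise_scale * rng.standard_normal((n, n_subcarriers))

    burst_len = int(round(motion_duration * fs))
    for _ in range(motion_events):
        start = rng.integers(0, max(1, n - burst_len))
        mags[start:start + burst_len] += motion_std * rng.standard_normal(
            (min(burst_len, n - start), n_subcarriers))

    np.clip(mags, 0.0, None, out=mags)

    timestamps = t.copy()
    if timestamp_jitter:
        dt = 1.0 / fs
        timestamps = t + rng.uniform(-0.2 * dt, 0.2 * dt, n)
        timestamps[0] = max(timestamps[0], 0.0)
        timestamps = np.sort(timestamps)

    truth_t, truth_rr = waveform.truth_1hz()
    metadata = {
        "sampling_rate": fs,
        "n_subcarriers": n_subcarriers,
        "session_id": session_id,
        "seed": int(seed),
        "coupled_subcarriers": coupled.tolist(),
        "ground_truth_rr": {"times": truth_t.tolist(), "rr": truth_rr.tolist()},
    }
    return CsiSession(mags, timestamps, metadata)


def synth_airflow(waveform: RespiratoryWaveform, noise_scale: float = 0.05,
                  seed: int = 0, sampling_rate: float = 32.0) -> AirflowTrace:
    """Nasal-pressure trace phase-locked to the breathing waveform.

    The waveform is resampled onto the airflow grid and contaminated with
    white noise and slow baseline wander scaled by ``noise_scale``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(waveform.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    pressure = np.interp(t, waveform.times, waveform.samples)
    if noise_scale > 0:
        pressure = (pressure
                    + 0.5 * noise_scale * rng.standard_normal(n)
                    + noise_scale * _lowpassed_noise(rng, (n,), 0.05, sampling_rate))
    return AirflowTrace(pressure, sampling_rate)


def synth_session(profile: str = "moderate",
                  schedule: MetronomeSchedule | None = None,
                  seed: int = 0,
                  sampling_rate: float = 50.0,
                  n_subcarriers: int = 256) -> tuple[CsiSession, AirflowTrace, RespiratoryWaveform]:
    """Generate a matched (CSI session, airflow trace, waveform) triple.

    ``profile`` selects one of :data:`PROFILES`; sub-seeds for the waveform,
    CSI and airflow stages are derived deterministically from ``seed``.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    params = dict(PROFILES[profile])
    jitter = params.pop("jitter")
    if schedule is None:
        schedule = make_schedule()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    wf = synth_respiratory_waveform(schedule, sampling_rate, jitter=jitter, seed=sub[0])
    session = synth_csi(wf, n_subcarriers=n_subcarriers, seed=sub[1],
                        session_id=f"{profile}-{seed}", **params)
    airflow = synth_airflow(wf, noise_scale=0.05 if params["noise_scale"] > 0 else 0.0,
                            seed=sub[2])
    return session, airflow, wf
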