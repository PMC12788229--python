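"""Reference respiratory rate from nasal airflow.

The airflow pressure signal is band-passed to the physiological breathing
range (5-35 brpm) with an 8th-order Butterworth IIR filter applied
forward-backward, breaths are detected with a quartile-thresholded peak
detector (peaks whose vertical separation from the nearest trough falls
below 0.3 x Q3 of the adjacent-extrema amplitude differences are discarded
recursively), and RR is computed per 30 s sliding window at a 1 s step as
(N_peaks - 1) / (t_last - t_first) x 60.  Windows where the reference
deviates from the metronome by more than a tolerance (default 4 brpm) are
flagged invalid, mirroring a compliance exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from csirr.synth import AirflowTrace, MetronomeSchedule

__all__ = [
    "PeakTrain",
    "ReferenceRrSeries",
    "bandpass_airflow",
    "detect_breath_peaks",
    "rr_from_peaks",
    "reference_rr",
    "apply_compliance_exclusion",
]

DISCARD_FACTOR = 0.3  # fraction of Q3 below which a peak-trough pair is spurious


@dataclass
class PeakTrain:
    """Breath peaks/troughs retained by the quartile-threshold detector."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    q3_threshold: float

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


@dataclass
class ReferenceRrSeries:
    """1 Hz reference RR with validity flags.

    An estimate at time ``t`` summarises the trailing window ``(t - W, t]``.
    Invalid windows (too few breaths, or metronome non-compliance) keep a NaN
    rate and ``valid=False``; they are never interpolated.
    """

    times: np.ndarray
    rr: np.ndarray
    valid: np.ndarray

    def copy(self) -> "ReferenceRrSeries":
        return ReferenceRrSeries(self.times.copy(), self.rr.copy(), self.valid.copy())


def bandpass_airflow(trace: AirflowTrace, low: float = 5.0,
                     high: float = 35.0) -> AirflowTrace:
    """Zero-phase 8th-order Butterworth bandpass over [low, high] brpm.

    Forward-backward application keeps breath peak timestamps unskewed at the
    cost of doubling the effective attenuation.
    """
    nyq_brpm = 60.0 * trace.sampling_rate / 2.0
    if not 0 < low < high < nyq_brpm:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(4, [low / 60.0, high / 60.0], btype="band",
                        fs=trace.sampling_rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(trace.pressure) <= padlen:
        raise ValueError("trace shorter than the filter warm-up length")
    return AirflowTrace(signal.sosfiltfilt(sos, trace.pressure), trace.sampling_rate)


def _alternating_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and types of strictly alternating local extrema.

    Returns (indices, is_peak).  Runs of equal-type extrema (plateaus) are
    collapsed to the most extreme member so peaks and troughs alternate.
    """
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    peaks = np.where(rising[:-1] & falling[1:])[0] + 1
    troughs = np.where(falling[:-1] & rising[1:])[0] + 1
    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.ones(len(peaks), bool), np.zeros(len(troughs), bool)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    if len(idx) == 0:
        return idx, kind
    keep_idx: list[int] = []
    keep_kind: list[bool] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = x[i] > x[prev] if k else x[i] < x[prev]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(bool(k))
    return np.array(keep_idx), np.array(keep_kind)


def detect_breath_peaks(filtered: AirflowTrace,
                        discard_factor: float = DISCARD_FACTOR) -> PeakTrain:
    """Quartile-thresholded breath peak detection.

    All alternating maxima/minima are found, Q3 of the absolute vertical
    differences between adjacent extrema is computed, and peaks whose
    smallest vertical separation from an adjacent trough is below
    ``0.3 * Q3`` are discarded recursively (removing the worst offender and
    merging its neighbouring troughs, then re-evaluating) until stable.
    """
    x = filtered.pressure
    t = filtered.times
    idx, kind = _alternating_extrema(x)
    if len(idx) < 2:
        return PeakTrain(np.array([]), np.array([]), 0.0)
    diffs = np.abs(np.diff(x[idx]))
    q3 = float(np.percentile(diffs, 75))
    thr = discard_factor * q3

    idx_l = list(idx)
    kind_l = list(kind)
    while True:
        worst_sep, worst_i = np.inf, -1
        for i, (j, k) in enumerate(zip(idx_l, kind_l)):
            if not k:
                continue
            seps = []
            if i > 0:
                seps.append(abs(x[j] - x[idx_l[i - 1]]))
            if i < len(idx_l) - 1:
                seps.append(abs(x[j] - x[idx_l[i + 1]]))
            if not seps:
                continue
            sep = min(seps)
            if sep < thr and sep < worst_sep:
                worst_sep, worst_i = sep, i
        if worst_i < 0:
            break
        # remove the peak and merge its adjacent troughs, keeping the deeper
        lo = worst_i - 1 if worst_i > 0 else None
        hi = worst_i + 1 if worst_i < len(idx_l) - 1 else None
        drop = {worst_i}
        if lo is not None and hi is not None:
            drop.add(lo if x[idx_l[lo]] > x[idx_l[hi]] else hi)
        idx_l = [j for i, j in enumerate(idx_l) if i not in drop]
        kind_l = [k for i, k in enumerate(kind_l) if i not in drop]

    idx_a = np.array(idx_l, dtype=int)
    kind_a = np.array(kind_l, dtype=bool)
    return PeakTrain(t[idx_a[kind_a]], t[idx_a[~kind_a]], q3)


def rr_from_peaks(train: PeakTrain, window: float = 30.0,
                  window_end: float | None = None) -> float:
    """RR (brpm) from breath peaks inside a trailing window.

    Uses the N-1 inter-peak intervals: ``(N - 1) / (t_last - t_first) * 60``.
    Returns NaN when fewer than two peaks fall inside the window.
    """
    pt = train.peak_times
    if window_end is not None:
        pt = pt[(pt > window_end - window) & (pt <= window_end)]
    if len(pt) < 2 or pt[-1] <= pt[0]:
        return float("nan")
    return (len(pt) - 1) / (pt[-1] - pt[0]) * 60.0


def reference_rr(trace: AirflowTrace, window: float = 30.0,
                 step: float = 1.0, low: float = 5.0,
                 high: float = 35.0) -> ReferenceRrSeries:
    """Reference RR series at 1/step Hz from a raw airflow trace.

    The trace is band-passed once, breaths are detected over the whole
    record, and each trailing window ``(t - window, t]`` is scored from the
    peaks it contains (Q3 thresholding is re-evaluated per window on the
    windowed signal, matching per-window processing).
    """
    duration = len(trace.pressure) / trace.sampling_rate
    if duration < window:
        raise ValueError("trace shorter than one analysis window")
    filtered = bandpass_airflow(trace, low, high)
    n_windows = int(np.floor((duration - window) / step)) + 1
    times = window + step * np.arange(n_windows)
    rr = np.full(n_windows, np.nan)
    fs = trace.sampling_rate
    for w, t_end in enumerate(times):
        i0 = int(round((t_end - window) * fs))
        i1 = int(round(t_end * fs))
        seg = AirflowTrace(filtered.pressure[i0:i1], fs)
        train = detect_breath_peaks(seg)
        val = rr_from_peaks(train, window)
        if np.isfinite(val) and 0.0 <= val <= 60.0:
            rr[w] = val
    valid = np.isfinite(rr)
    return ReferenceRrSeries(times, rr, valid)


def apply_compliance_exclusion(series: ReferenceRrSeries,
                               schedule: MetronomeSchedule,
                               tolerance: float = 4.0) -> ReferenceRrSeries:
    """Invalidate windows deviating from the metronome by more than ``tolerance``.

    The rule is strictly-greater-than: a deviation of exactly ``tolerance``
    brpm is kept.  Already-invalid windows stay invalid (idempotent).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    out = series.copy()
    sched = schedule.rate_at(out.times)
    with np.errstate(invalid="ignore"):
        bad = np.abs(out.rr - sched) > tolerance
    out.valid = out.valid & ~(bad & np.isfinite(out.rr))
    out.valid = out.valid & np.isfinite(out.rr)
    return out
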