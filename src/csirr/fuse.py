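"""Multi-source fusion of per-component RR candidates.

Each component rank carries its own one-dimensional Kalman filter on a
random-walk RR state: predict adds a fixed process variance per 1 s step,
and the update assimilates the window's combined RR estimate with a
measurement variance coupled to signal quality (base_variance / SQI**2).
Windows where a source has no usable candidate (SQI = 0 or no estimate)
produce predict-only steps and exclude that source from fusion.

Per window the filtered states are merged by an SQI- and residual-weighted
average: each source's fusion variance is r_i / SQI_i**2 with r_i the
posterior error variance of its Kalman filter, and the fused RR is the
product-form weighted mean, algebraically identical to the inverse-variance
weighted mean whenever all variances are finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from csirr.estimate import RrCandidate

__all__ = [
    "KalmanSourceState",
    "FusedRrSeries",
    "kalman_step",
    "source_variance",
    "fuse_window",
    "fuse_session",
]


@dataclass
class KalmanSourceState:
    """Scalar random-walk Kalman filter state for one RR source."""

    state_estimate: float        # brpm
    error_variance: float        # brpm^2
    process_variance: float = 0.1  # brpm^2 per 1 s step
    innovation: float = 0.0      # brpm, last update
    initialized: bool = False


@dataclass
class FusedRrSeries:
    """1 Hz fused RR with validity flags and per-window diagnostics."""

    times: np.ndarray
    rr: np.ndarray
    valid: np.ndarray
    sources_used: np.ndarray
    per_window_weights: list[dict[int, float]] = field(default_factory=list)


def kalman_step(state: KalmanSourceState, measurement: float | None,
                measurement_variance: float | None = None) -> KalmanSourceState:
    """One predict/update cycle of the scalar random-walk filter.

    Predict inflates the error variance by the process variance; an absent
    measurement (or infinite measurement variance) leaves the prediction as
    the posterior.  In the limits, a zero-variance measurement is adopted
    exactly and an infinite-variance one is ignored.
    """
    p = state.error_variance + state.process_variance
    x = state.state_estimate
    innovation = 0.0
    if measurement is not None and np.isfinite(measurement):
        if measurement_variance is None or measurement_variance < 0:
            raise ValueError("measurement variance must be non-negative")
        if np.isfinite(measurement_variance):
            innovation = measurement - x
            gain = p / (p + measurement_variance) if (p + measurement_variance) > 0 else 1.0
            x = x + gain * innovation
            p = (1.0 - gain) * p
            p = max(p, 1e-12)
    return KalmanSourceState(x, p, state.process_variance, innovation,
                             initialized=True)


def source_variance(residual: float, sqi: float) -> float:
    """Fusion variance of a source: residual / SQI**2.

    A zero SQI yields an infinite variance, excluding the source from the
    current window.
    """
    if residual < 0:
        raise ValueError("residual must be non-negative")
    if sqi <= 0:
        return float("inf")
    return residual / sqi ** 2


def fuse_window(candidates: Sequence[tuple[float, float]]) -> tuple[float, list[float]]:
    """Product-form weighted average of (rr, variance) pairs.

    ``w_k = prod_{i != k} var_i / sum_i prod_{j != i} var_j`` — equal to the
    inverse-variance weighted mean when all variances are finite and
    positive.  Sources with infinite variance are dropped first; zero
    variance is honoured exactly (that source dominates).  Raises when no
    source has finite variance.
    """
    finite = [(rr, v) for rr, v in candidates if np.isfinite(v) and np.isfinite(rr)]
    if not finite:
        raise ValueError("no source with finite variance")
    rrs = np.array([rr for rr, _ in finite])
    var = np.array([v for _, v in finite])
    n = len(finite)
    weights = np.empty(n)
    for k in range(n):
        weights[k] = np.prod(np.delete(var, k))
    total = weights.sum()
    if total <= 0:
        # at least one exact (zero-variance) source: split among them
        exact = var == 0
        weights = exact.astype(float)
        total = weights.sum()
    weights = weights / total
    return float(weights @ rrs), weights.tolist()


def fuse_session(candidate_stream: Sequence[tuple[float, Sequence[RrCandidate]]],
                 process_variance: float = 0.1,
                 base_measurement_variance: float = 1.0,
                 n_sources: int = 5,
                 band_brpm: tuple[float, float] = (5.0, 35.0),
                 init_variance: float | None = None,
                 residual: str = "posterior") -> FusedRrSeries:
    """Fuse an ordered stream of per-window candidate lists into a 1 Hz series.

    One Kalman state is maintained per component rank across windows (rank
    after CQI sorting identifies the source).  Per window each source with a
    finite combined RR and positive SQI is updated with measurement variance
    ``base / SQI**2``; its fusion variance is the Kalman residual divided by
    SQI**2, where ``residual`` selects the reading of "residual error":
    ``"posterior"`` (default) uses the posterior error variance,
    ``"innovation"`` the squared last innovation.  Windows with no usable
    source run predict-only and emit an invalid sample.  Fused values
    outside the physiological band are flagged invalid.
    """
    if residual not in ("posterior", "innovation"):
        raise ValueError("residual must be 'posterior' or 'innovation'")
    if init_variance is None:
        init_variance = ((band_brpm[1] - band_brpm[0]) / 4.0) ** 2
    states: dict[int, KalmanSourceState] = {}
    times, rr_out, valid, n_used, weights_out = [], [], [], [], []
    for t, candidates in candidate_stream:
        by_rank = {c.component_rank: c for c in candidates}
        fusable: list[tuple[int, float, float]] = []
        for rank in range(n_sources):
            cand = by_rank.get(rank)
            usable = (cand is not None and np.isfinite(cand.rr_combined)
                      and cand.sqi > 0)
            if rank not in states:
                if usable:
                    states[rank] = KalmanSourceState(
                        cand.rr_combined, init_variance, process_variance,
                        initialized=True)
                else:
                    continue  # never measured: stays out of fusion
            meas = cand.rr_combined if usable else None
            meas_var = (base_measurement_variance / cand.sqi ** 2
                        if usable else None)
            states[rank] = kalman_step(states[rank], meas, meas_var)
            if usable:
                r = (states[rank].error_variance if residual == "posterior"
                     else states[rank].innovation ** 2)
                var = source_variance(r, cand.sqi)
                if np.isfinite(var):
                    fusable.append((rank, states[rank].state_estimate, var))
        times.append(t)
        if fusable:
            fused, w = fuse_window([(rr, v) for _, rr, v in fusable])
            in_band = band_brpm[0] <= fused <= band_brpm[1]
            rr_out.append(fused)
            valid.append(bool(in_band))
            n_used.append(len(fusable))
            weights_out.append({rank: wi for (rank, _, _), wi in zip(fusable, w)})
        else:
            rr_out.append(float("nan"))
            valid.append(False)
            n_used.append(0)
            weights_out.append({})
    return FusedRrSeries(np.array(times), np.array(rr_out),
                         np.array(valid, bool), np.array(n_used),
                         weights_out)
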