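"""Windowed PCA of the CSI magnitude stream and component selection.

Each 30 s window (1500 samples at 50 Hz) of the T x K subcarrier-magnitude
matrix is mean-centred per subcarrier and decomposed into orthogonal
principal components ordered by explained variance.  Components are scored
with a component quality index (CQI), the product of three sub-indices:

* a binary variance index (1 for ranks up to the adaptive elbow where the
  cumulative-variance gradient drops below 1% per component),
* a continuous in-band spectral-energy ratio (share of spectral magnitude in
  the physiological band, 5-35 brpm by default),
* a binary spectral-peak-location index (1 when the dominant spectral peak
  lies at or above the minimum physiological rate, 5 brpm).

The top components by CQI (five by default) feed the RR estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from csirr.synth import CsiSession

__all__ = [
    "AnalysisWindow",
    "ComponentSet",
    "ingest_csi",
    "window_stream",
    "pca_window",
    "variance_index",
    "snr_index",
    "spectral_peak_index",
    "select_components",
    "decompose_window",
]

VARIANCE_GRADIENT = 0.01  # elbow rule: next component must add >= 1% variance


@dataclass
class AnalysisWindow:
    """One sliding-window slice of the regularised CSI stream.

    ``end_time`` follows the trailing-edge convention: the window covers
    ``(end_time - W, end_time]``.
    """

    end_time: float
    magnitudes: np.ndarray  # W x K
    sampling_rate: float = 50.0


@dataclass
class ComponentSet:
    """Per-window principal components with quality scores.

    ``projections`` holds the first ``m`` component time series (W x m) with
    deterministic sign (non-negative skewness); score arrays cover all
    available ranks, with CQI identically zero beyond the variance elbow.
    """

    end_time: float
    projections: np.ndarray
    explained_variance_ratios: np.ndarray
    cumulative_variance: np.ndarray
    sigma_threshold: float
    gamma_sigma: np.ndarray
    gamma_snr: np.ndarray
    gamma_peak: np.ndarray
    cqi: np.ndarray
    sampling_rate: float = 50.0
    selected_indices: list[int] = field(default_factory=list)  # 0-based ranks
    low_quality: bool = False
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_ratios)


def ingest_csi(session: CsiSession, target_rate: float | None = None,
               min_duration: float = 30.0) -> CsiSession:
    """Regularise a session onto a uniform sampling grid.

    Magnitudes are linearly interpolated per subcarrier onto a uniform grid
    at the metadata sampling rate (nominal 50 Hz); timestamp gaps longer
    than 1 s are recorded in ``metadata['gaps']``.  Sessions shorter than
    ``min_duration`` are rejected.
    """
    fs = target_rate or session.metadata.get("sampling_rate", 50.0)
    t = session.timestamps
    duration = (t[-1] - t[0]) + 1.0 / fs
    if duration < min_duration:
        raise ValueError(f"session shorter than {min_duration} s")
    gaps = np.diff(t)
    gap_idx = np.where(gaps > 1.0)[0]
    metadata = dict(session.metadata)
    metadata["gaps"] = [(float(t[i]), float(t[i + 1])) for i in gap_idx]
    metadata["sampling_rate"] = fs

    n_out = int(round(duration * fs))
    grid = t[0] + np.arange(n_out) / fs
    dt = np.diff(t)
    uniform = np.allclose(dt, 1.0 / fs, atol=1e-9) if len(dt) else True
    if uniform and n_out == len(t):
        mags = session.magnitudes
    else:
        mags = np.empty((n_out, session.n_subcarriers))
        for k in range(session.n_subcarriers):
            mags[:, k] = np.interp(grid, t, session.magnitudes[:, k])
    return CsiSession(mags, grid, metadata)


def window_stream(session: CsiSession, window: float = 30.0,
                  step: float = 1.0) -> Iterator[AnalysisWindow]:
    """Yield trailing-edge analysis windows at a fixed step.

    A session of duration D yields ``floor((D - window)/step) + 1`` windows;
    the first ends at ``t0 + window``.
    """
    fs = session.metadata.get("sampling_rate", 50.0)
    w_len = int(round(window * fs))
    s_len = int(round(step * fs))
    n = session.magnitudes.shape[0]
    t0 = session.timestamps[0]
    for start in range(0, n - w_len + 1, s_len):
        yield AnalysisWindow(
            end_time=t0 + (start + w_len) / fs,
            magnitudes=session.magnitudes[start:start + w_len],
            sampling_rate=fs,
        )


def _deterministic_sign(p: np.ndarray) -> float:
    """Sign fixing for an eigenvector projection: non-negative skewness,
    falling back to the sign of the largest-magnitude sample."""
    s = np.mean(p ** 3)
    if abs(s) > 1e-12 * (np.mean(p ** 2) ** 1.5 + 1e-300):
        return 1.0 if s >= 0 else -1.0
    m = p[np.argmax(np.abs(p))] if len(p) else 0.0
    return -1.0 if m < 0 else 1.0


def _pca_eig(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred data, descending eigenvalues and eigenvectors of the
    subcarrier covariance (unnormalised scatter matrix)."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return Xc, np.clip(vals[order], 0.0, None), vecs[:, order]


def _project(Xc: np.ndarray, vecs: np.ndarray, m: int) -> np.ndarray:
    proj = Xc @ vecs[:, :m]
    for j in range(m):
        proj[:, j] *= _deterministic_sign(proj[:, j])
    return proj


def _degenerate_set(win: AnalysisWindow) -> ComponentSet:
    proj = np.zeros((win.magnitudes.shape[0], 1))
    return ComponentSet(win.end_time, proj, np.array([1.0]), np.array([1.0]),
                        1.0, np.array([0.0]), np.array([0.0]), np.array([0.0]),
                        np.array([0.0]), win.sampling_rate, degenerate=True)


def pca_window(win: AnalysisWindow, n_projections: int | None = None) -> ComponentSet:
    """PCA of one analysis window via the subcarrier covariance matrix.

    Columns are mean-centred; eigenvalues are sorted descending and
    projections are computed for the first ``n_projections`` ranks (all by
    default) with deterministic sign.  A zero-variance window yields a
    single degenerate component whose CQI is forced to zero.
    """
    X = np.asarray(win.magnitudes, float)
    Xc, vals, vecs = _pca_eig(X)
    total = float(vals.sum())
    if total <= 0.0 or not np.isfinite(total):
        return _degenerate_set(win)
    evr = vals / total
    cum = np.cumsum(evr)
    m = len(vals) if n_projections is None else min(n_projections, len(vals))
    proj = _project(Xc, vecs, m)
    return ComponentSet(win.end_time, proj, evr, cum, 0.0,
                        np.zeros(len(vals)), np.zeros(len(vals)),
                        np.zeros(len(vals)), np.zeros(len(vals)),
                        win.sampling_rate)


def variance_index(cset: ComponentSet) -> np.ndarray:
    """Binary variance index from the cumulative-variance elbow.

    The retained count m* is the smallest rank whose next component adds
    less than 1% variance (at least one component is always retained; if no
    component falls below the gradient, all are retained).  The cumulative
    variance at m* becomes the adaptive threshold.
    """
    evr = cset.explained_variance_ratios
    m_star = len(evr)
    for m in range(1, len(evr)):
        if evr[m] < VARIANCE_GRADIENT:
            m_star = m
            break
    gamma = np.zeros(len(evr))
    gamma[:m_star] = 1.0
    cset.gamma_sigma = gamma
    cset.sigma_threshold = float(cset.cumulative_variance[m_star - 1])
    if cset.degenerate:
        cset.gamma_sigma = np.zeros(len(evr))
    return cset.gamma_sigma


def _magnitude_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of the mean-removed signal (no taper)."""
    x = np.asarray(x, float)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return freqs, mag


def snr_index(component: np.ndarray, sampling_rate: float,
              band_brpm: tuple[float, float] = (5.0, 35.0)) -> float:
    """In-band spectral-energy ratio of a component, in [0, 1].

    Share of the summed one-sided spectral magnitude falling within the
    physiological band (default 5-35 brpm, i.e. 0.083-0.583 Hz).
    """
    f1, f2 = band_brpm[0] / 60.0, band_brpm[1] / 60.0
    if not 0 < f1 < f2 < sampling_rate / 2:
        raise ValueError("band must lie inside (0, Nyquist)")
    freqs, mag = _magnitude_spectrum(component, sampling_rate)
    denom = mag.sum()
    if denom <= 0:
        return 0.0
    in_band = (freqs >= f1 - 1e-12) & (freqs <= f2 + 1e-12)
    return float(mag[in_band].sum() / denom)


def spectral_peak_index(component: np.ndarray, sampling_rate: float,
                        f_min_brpm: float = 5.0) -> float:
    """1 if the dominant (non-DC) spectral peak sits at or above ``f_min``.

    Guards against high-variance low-frequency drift components whose
    spectral mass concentrates below the physiological range.
    """
    freqs, mag = _magnitude_spectrum(component, sampling_rate)
    if len(mag) < 2 or mag[1:].max() <= 0:
        return 0.0
    f_peak = freqs[1 + int(np.argmax(mag[1:]))]
    return 1.0 if f_peak >= f_min_brpm / 60.0 - 1e-12 else 0.0


def select_components(cset: ComponentSet, n_keep: int = 5) -> ComponentSet:
    """Rank components by CQI and keep the top ``n_keep``.

    CQI is the product of the variance, SNR and spectral-peak indices; ties
    are broken by explained-variance rank.  When every CQI is zero the
    highest-variance components are kept and the set is flagged low quality.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    cset.cqi = cset.gamma_sigma * cset.gamma_snr * cset.gamma_peak
    n = cset.n_components
    order = sorted(range(n), key=lambda i: (-cset.cqi[i], i))
    cset.selected_indices = [i for i in order[:min(n_keep, n)]]
    cset.low_quality = bool(np.all(cset.cqi == 0))
    return cset


def decompose_window(win: AnalysisWindow, n_keep: int = 5,
                     band_brpm: tuple[float, float] = (5.0, 35.0),
                     f_min_brpm: float = 5.0) -> ComponentSet:
    """Full per-window decomposition: PCA, scoring, and top-CQI selection.

    Projections (and spectra) are only materialised for ranks that can be
    selected — up to the variance elbow or ``n_keep``, whichever is larger —
    since CQI vanishes identically beyond the elbow.
    """
    X = np.asarray(win.magnitudes, float)
    Xc, vals, vecs = _pca_eig(X)
    total = float(vals.sum())
    if total <= 0.0 or not np.isfinite(total):
        cset = _degenerate_set(win)
        variance_index(cset)
        return select_components(cset, n_keep)
    evr = vals / total
    cset = ComponentSet(win.end_time, np.empty((X.shape[0], 0)), evr,
                        np.cumsum(evr), 0.0,
                        np.zeros(len(vals)), np.zeros(len(vals)),
                        np.zeros(len(vals)), np.zeros(len(vals)),
                        win.sampling_rate)
    variance_index(cset)
    m_star = int(cset.gamma_sigma.sum())
    m_need = min(max(m_star, n_keep), len(vals))
    cset.projections = _project(Xc, vecs, m_need)
    for j in range(m_need):
        comp = cset.projections[:, j]
        cset.gamma_snr[j] = snr_index(comp, cset.sampling_rate, band_brpm)
        cset.gamma_peak[j] = spectral_peak_index(comp, cset.sampling_rate,
                                                 f_min_brpm)
    return select_components(cset, n_keep)
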