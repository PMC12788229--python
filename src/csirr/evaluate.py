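"""Agreement between estimated and reference respiratory rates.

Paired 1 Hz series are scored with MAE, RMSE, squared Pearson correlation,
Bland-Altman bias and 95% limits of agreement (bias +- 1.96 SD of the
differences, estimate minus reference), and the fraction of estimates within
+-2 brpm of the reference.  Reports are produced overall and per RR band
(below 12, 12-21, above 21 brpm by default), with band membership decided by
the mean of estimate and reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from csirr.fuse import FusedRrSeries
from csirr.reference import ReferenceRrSeries

__all__ = [
    "AgreementReport",
    "align_series",
    "agreement_metrics",
    "banded_report",
]

DEFAULT_BAND_EDGES = (12.0, 21.0)


@dataclass
class AgreementReport:
    """Agreement metrics between an estimate series and a reference."""

    mae: float
    rmse: float
    r_squared: float | None     # None when the reference has zero variance
    bias: float
    loa_low: float
    loa_high: float
    rr2brpm: float              # percent of pairs within +-2 brpm
    n_windows: int
    banded: dict[str, "AgreementReport"] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "mae": self.mae, "rmse": self.rmse, "r_squared": self.r_squared,
            "bias": self.bias, "loa_low": self.loa_low, "loa_high": self.loa_high,
            "rr2brpm": self.rr2brpm, "n_windows": self.n_windows,
        }
        if self.banded:
            d["banded"] = {k: v.to_dict() for k, v in self.banded.items()}
        return d


def align_series(est: FusedRrSeries,
                 ref: ReferenceRrSeries) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Pair estimate and reference samples at common 1 Hz time stamps.

    Only pairs where both series are valid are kept; counts of dropped
    samples are reported.  Raises when no valid overlapping pair exists.
    """
    common, ei, ri = np.intersect1d(np.round(est.times, 6),
                                    np.round(ref.times, 6),
                                    return_indices=True)
    if len(common) == 0:
        raise ValueError("estimate and reference series do not overlap")
    both = est.valid[ei] & ref.valid[ri]
    dropped = {
        "est_invalid": int(np.sum(~est.valid[ei] & ref.valid[ri])),
        "ref_invalid": int(np.sum(est.valid[ei] & ~ref.valid[ri])),
        "both_invalid": int(np.sum(~est.valid[ei] & ~ref.valid[ri])),
    }
    if not np.any(both):
        raise ValueError("no overlapping window is valid in both series")
    return est.rr[ei][both], ref.rr[ri][both], dropped


def agreement_metrics(est: np.ndarray, ref: np.ndarray) -> AgreementReport:
    """Agreement metrics for paired estimate/reference samples."""
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if len(est) != len(ref):
        raise ValueError("paired arrays must have equal length")
    if len(est) < 2:
        raise ValueError("need at least two pairs")
    diff = est - ref
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=0))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if np.std(ref) == 0 or np.std(est) == 0:
        r2 = None
    else:
        r, _ = stats.pearsonr(est, ref)
        r2 = float(r ** 2)
    rr2 = float(100.0 * np.mean(np.abs(diff) <= 2.0))
    return AgreementReport(mae, rmse, r2, bias, loa_low, loa_high, rr2, len(est))


def _empty_report() -> AgreementReport:
    nan = float("nan")
    return AgreementReport(nan, nan, None, nan, nan, nan, nan, 0)


def banded_report(est: np.ndarray, ref: np.ndarray,
                  band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES) -> AgreementReport:
    """Overall report with per-band sub-reports attached.

    Pairs are assigned to bands by the mean of estimate and reference;
    band intervals are inclusive on the lower edge ([12, 21) etc.).  Empty
    bands are reported with n = 0 and NaN metrics.
    """
    report = agreement_metrics(est, ref)
    mean = (np.asarray(est, float) + np.asarray(ref, float)) / 2.0
    edges = (-np.inf,) + tuple(band_edges) + (np.inf,)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (mean >= lo) & (mean < hi)
        if np.isinf(lo):
            name = f"<{hi:g}"
        elif np.isinf(hi):
            name = f">={lo:g}"
        else:
            name = f"{lo:g}-{hi:g}"
        if mask.sum() >= 2:
            report.banded[name] = agreement_metrics(est[mask], ref[mask])
        else:
            sub = _empty_report()
            sub.n_windows = int(mask.sum())
            report.banded[name] = sub
    return report
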