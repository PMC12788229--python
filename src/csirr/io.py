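"""File formats: CSI sessions, airflow traces, RR series, reports.

A CSI session is stored as either a CSV matrix (one row per packet, one
column per subcarrier) or a raw little-endian float32 binary, plus a JSON
sidecar holding the sampling rate, subcarrier count, shape and ground-truth
RR.  Airflow traces are single-column CSV with a JSON sidecar; RR series are
CSV (time, rr, valid); reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from csirr.fuse import FusedRrSeries
from csirr.reference import ReferenceRrSeries
from csirr.synth import AirflowTrace, CsiSession

__all__ = [
    "write_session", "read_session",
    "write_airflow", "read_airflow",
    "write_rr_series", "read_rr_series",
    "write_fused_series", "write_json",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_session(session: CsiSession, path: str | Path,
                  fmt: str = "bin") -> Path:
    """Write a session as CSV or float32 binary plus JSON sidecar."""
    path = Path(path)
    if fmt == "csv":
        np.savetxt(path, session.magnitudes, delimiter=",", fmt="%.6g")
    elif fmt == "bin":
        session.magnitudes.astype("<f4").tofile(path)
    else:
        raise ValueError("fmt must be 'csv' or 'bin'")
    sidecar = dict(session.metadata)
    sidecar.update({
        "format": fmt,
        "shape": list(session.magnitudes.shape),
        "timestamps_start": float(session.timestamps[0]),
        "timestamps": session.timestamps.tolist()
        if not _is_uniform(session) else None,
    })
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)
    return path


def _is_uniform(session: CsiSession) -> bool:
    fs = session.metadata.get("sampling_rate", 50.0)
    d = np.diff(session.timestamps)
    return bool(len(d) == 0 or np.allclose(d, 1.0 / fs, atol=1e-9))


def read_session(path: str | Path) -> CsiSession:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing session sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    shape = tuple(meta.pop("shape"))
    fmt = meta.pop("format")
    if fmt == "csv":
        mags = np.loadtxt(path, delimiter=",").reshape(shape)
    else:
        mags = np.fromfile(path, dtype="<f4").reshape(shape).astype(float)
    ts = meta.pop("timestamps", None)
    t0 = meta.pop("timestamps_start", 0.0)
    fs = meta.get("sampling_rate", 50.0)
    timestamps = (np.asarray(ts) if ts is not None
                  else t0 + np.arange(shape[0]) / fs)
    return CsiSession(mags, timestamps, meta)


def write_airflow(trace: AirflowTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, trace.pressure, fmt="%.8g")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"sampling_rate": trace.sampling_rate}, fh)
    return path


def read_airflow(path: str | Path) -> AirflowTrace:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing airflow sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return AirflowTrace(np.loadtxt(path), meta["sampling_rate"])


def write_rr_series(series: ReferenceRrSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": series.times, "rr": series.rr,
                  "valid": series.valid.astype(int)}).to_csv(path, index=False)
    return path


def read_rr_series(path: str | Path) -> ReferenceRrSeries:
    df = pd.read_csv(path)
    return ReferenceRrSeries(df["time"].to_numpy(float),
                             df["rr"].to_numpy(float),
                             df["valid"].to_numpy(int).astype(bool))


def write_fused_series(series: FusedRrSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": series.times, "rr": series.rr,
                  "valid": series.valid.astype(int),
                  "sources_used": series.sources_used}).to_csv(path, index=False)
    return path


def write_json(obj: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
    return path
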