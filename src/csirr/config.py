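"""Pipeline configuration.

Defaults reproduce the study constants: 30 s windows at a 1 s step, five
components, a 5-35 brpm physiological band, a 5 brpm minimum spectral-peak
frequency, and a 4 brpm agreement/compliance tolerance.  The narrower
6-33 brpm experimental band is available as the ``protocol_band`` preset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

__all__ = ["PipelineConfig", "PROTOCOL_BAND"]

#: Alternative band matching the metronome protocol extremes (6-33 brpm).
PROTOCOL_BAND = (6.0, 33.0)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    band: tuple[float, float] = (5.0, 35.0)   # brpm
    window: float = 30.0                      # s
    step: float = 1.0                         # s
    n_components: int = 5
    agreement_tolerance: float = 4.0          # brpm
    f_min: float = 5.0                        # brpm
    # BSSF onset detector
    bssf_box_width: float = 1.0               # s
    bssf_threshold_factor: float = 0.5
    # Kalman fusion
    process_variance: float = 0.1             # brpm^2 per step
    base_measurement_variance: float = 1.0    # brpm^2 at SQI = 1
    kalman_residual: str = "posterior"        # or "innovation"
    # filtering
    filter_order: int = 4
    seed: int = 0
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if self.agreement_tolerance <= 0:
            raise ValueError("agreement tolerance must be positive")
        if self.process_variance < 0 or self.base_measurement_variance <= 0:
            raise ValueError("Kalman variances must be positive")
        if self.kalman_residual not in ("posterior", "innovation"):
            raise ValueError("kalman_residual must be 'posterior' or 'innovation'")
        self.band = (float(low), float(high))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
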