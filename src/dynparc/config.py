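"""Pipeline configuration with units, validation and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end pipeline.

    Durations are in seconds and converted to integer TR counts at run
    time (rounded to the nearest TR; the realized duration is logged,
    e.g. 60 s at TR = 0.72 s realizes 83 TR = 59.76 s).
    """

    tr: float = 0.72                 # s, sampling interval
    n_discard: int = 10              # initial frames dropped
    detrend_order: int = 2           # constant + linear + quadratic
    band_low: float = 0.0167         # Hz
    band_high: float = 0.15          # Hz
    fwhm: float = 0.0                # mm, 0 disables smoothing
    gsr: bool = True
    window_sec: float = 60.0         # sliding-window length
    step_sec: float = 3.6            # sliding-window step
    rank_m: int = 50                 # stationary-FC centering rank
    eig_mode: str = "magnitude"
    k_min: int = 1
    k_max: int = 30
    k_fixed: int | None = None       # bypass consensus selection
    folds: int = 10
    n_init: int = 20
    consensus_n_init: int = 10
    min_region_size: int = 20        # voxels
    connectivity: int = 26
    seed: int = 42

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= 0.5 / self.tr:
            raise ValueError("band_high at or above Nyquist")
        if self.window_sec <= 0 or self.step_sec <= 0:
            raise ValueError("window_sec and step_sec must be positive")
        if self.rank_m < 0:
            raise ValueError("rank_m must be nonnegative")
        if self.eig_mode not in ("magnitude", "algebraic"):
            raise ValueError("eig_mode must be 'magnitude' or 'algebraic'")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid K range")
        if self.min_region_size < 1:
            raise ValueError("min_region_size must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def window_tr(self) -> int:
        return max(1, round(self.window_sec / self.tr))

    @property
    def step_tr(self) -> int:
        return max(1, round(self.step_sec / self.tr))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
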