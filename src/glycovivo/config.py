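"""Run configuration and default study conditions.

All tunables of the quantification pipeline live here with their standard
values: F = 0.7 for the thickness threshold, alpha = 0.05, the 15-s
observation window, 30-min permeability sampling, and the 0.377 um/px
calibration.  The per-endpoint cohort tables hold the per-hour population
means and SDs the emulation draws from, on the experimental schedule
(measurement hours per endpoint).

Published values are used where available (plasma syndecan-1 at 0/24 h;
thickness index at 0/24 h for arterioles and venules).  Hours described only
qualitatively (return to baseline, minima) carry plausible values consistent
with that description: syndecan-1 and TI back at
control level by 48 h; body weight minimal at 48 h and restored by 168 h;
blood pressure minimal at 24 h and restored by 72 h.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .frames import DEFAULT_PIXEL_SIZE_UM

__all__ = ["RunConfig", "COHORT_DEFAULTS", "ADHESION_DEFAULTS"]


#: Per-endpoint cohort parameters: schedule hours -> (mean, sd), plus n.
COHORT_DEFAULTS: dict[str, dict] = {
    "sdc1": {
        "units": "ng/mL",
        "n_per_time": 3,
        "schedule": [0, 24, 48, 96],
        "means": {0: 1.85, 24: 3.83, 48: 1.90, 96: 1.85},
        "sds": {0: 0.48, 24: 1.09, 48: 0.55, 96: 0.50},
    },
    "ti_arteriole": {
        "units": "um",
        "n_per_time": 21,
        "schedule": [0, 24, 48, 72],
        "means": {0: 1.28, 24: 1.79, 48: 1.35, 72: 1.30},
        "sds": {0: 0.27, 24: 0.62, 48: 0.30, 72: 0.28},
    },
    "ti_venule": {
        "units": "um",
        "n_per_time": 21,
        "schedule": [0, 24, 48, 72],
        "means": {0: 1.05, 24: 1.51, 48: 1.10, 72: 1.06},
        "sds": {0: 0.39, 24: 0.56, 48: 0.42, 72: 0.40},
    },
    "body_weight": {
        "units": "g",
        "n_per_time": 8,
        "schedule": [0, 24, 48, 72, 96, 120, 168, 216],
        "means": {0: 24.0, 24: 22.6, 48: 21.4, 72: 21.9, 96: 22.6,
                  120: 23.2, 168: 24.0, 216: 24.2},
        "sds": {0: 1.2, 24: 1.2, 48: 1.3, 72: 1.3, 96: 1.3,
                120: 1.3, 168: 1.2, 216: 1.2},
    },
    "blood_pressure": {
        "units": "mmHg",
        "n_per_time": 5,
        "schedule": [0, 24, 48, 72, 96],
        "means": {0: 98.0, 24: 76.0, 48: 84.0, 72: 95.0, 96: 97.0},
        "sds": {0: 8.0, 24: 10.0, 48: 9.0, 72: 8.0, 96: 8.0},
    },
}

#: Expected leukocyte counts per 100x100-um segment by hour: rolling rises
#: sharply at 24 h and falls back by 48 h; adhering changes only modestly.
ADHESION_DEFAULTS: dict = {
    "schedule": [0, 24, 48],
    "n_measurements": 12,          # 4 mice x 3 locations
    "rolling_mean": {0: 2.0, 24: 8.0, 48: 3.0},
    "adhering_mean": {0: 1.0, 24: 2.0, 48: 1.0},
    "flowing_mean": 6.0,
}


@dataclass
class RunConfig:
    """All tunables of an end-to-end emulation run."""

    pixel_size: float = DEFAULT_PIXEL_SIZE_UM   # um/px
    F: float = 0.7                              # threshold fraction
    displacement_epsilon: float = 2.0           # um over the 15-s window
    rolling_fraction: float = 0.5               # of reference speed
    match_radius: float = 5.0                   # um, dual-stain matching
    alpha: float = 0.05
    window_s: float = 15.0
    sample_interval_min: float = 30.0
    permeability_duration_min: float = 120.0
    centerline_speed: float = 100.0             # um/s
    seed: int = 0
    # image rendering for the TI endpoint
    scene_noise_sd: float = 5.0
    lumen_intensity: int = 80
    band_intensity: int = 200
    background_intensity: int = 10
    vessel_diameter: float = 30.0               # um
    # nested parameter tables
    cohorts: dict = field(default_factory=lambda: _deepcopy_defaults(COHORT_DEFAULTS))
    adhesion: dict = field(default_factory=lambda: _deepcopy_defaults(ADHESION_DEFAULTS))

    def __post_init__(self) -> None:
        if not 0 <= self.F <= 1:
            raise ValueError("F must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _deepcopy_defaults(d: dict) -> dict:
    return copy.deepcopy(d)
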