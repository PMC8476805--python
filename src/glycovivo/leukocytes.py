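"""Leukocyte-endothelium interaction counting from tracks and detections.

Cells observed over a 15-s window are classified as *adhering* (no net
movement beyond a small displacement tolerance), *rolling* (moving along the
vessel axis but slower than free-flowing blood) or *flowing*.  Counts are
calibrated to a reference vessel of 100 um length and 100 um diameter, so
counts from vessels of different geometry are comparable.

A second, dual-channel criterion distinguishes tight adherence: cells present
at the same position in a lectin-channel frame and a rhodamine-channel frame
captured 8 s later ("yellow" in the merged image) are tight-adherent; cells
seen in only one frame at that position are transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import ImageFrame

__all__ = [
    "VesselGeometry",
    "LeukocyteTrack",
    "ClassifierParams",
    "ClassifiedCounts",
    "DualStainPair",
    "classify_track",
    "count_and_normalize",
    "dual_stain_adherence",
]

OBSERVATION_WINDOW_S = 15.0


@dataclass
class VesselGeometry:
    """Geometry of the observed vessel segment (micrometre units)."""

    diameter_um: float
    segment_length_um: float
    axis_angle_deg: float = 0.0
    vessel_class: str = "venule"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.segment_length_um <= 0:
            raise ValueError("vessel diameter and segment length must be positive")

    @property
    def axis_unit(self) -> np.ndarray:
        th = math.radians(self.axis_angle_deg)
        return np.array([math.cos(th), math.sin(th)])


@dataclass
class LeukocyteTrack:
    """Time-stamped positions of one cell within the observation window."""

    track_id: int
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    vessel: VesselGeometry

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) < 2:
            raise ValueError("a track needs at least 2 samples")
        if not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass
class ClassifierParams:
    """Thresholds of the kinetic classification.

    displacement_epsilon : um
        Maximum displacement from the starting position for a cell to count
        as adhering over the full window (default 2 um, well below one cell
        diameter).
    rolling_fraction : dimensionless
        Cells with mean along-axis speed below this fraction of the free-flow
        reference speed are rolling (default 0.5).
    min_coverage : fraction of the window a track must span to be classified.
    """

    displacement_epsilon: float = 2.0
    rolling_fraction: float = 0.5
    min_coverage: float = 0.8
    window_s: float = OBSERVATION_WINDOW_S

    def __post_init__(self) -> None:
        if self.displacement_epsilon < 0:
            raise ValueError("displacement_epsilon must be >= 0")
        if not 0 < self.rolling_fraction < 1:
            raise ValueError("rolling_fraction must lie in (0, 1)")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")


@dataclass
class ClassifiedCounts:
    """Raw and geometry-normalized interaction counts for one vessel."""

    n_adhering: int
    n_rolling: int
    n_flowing: int
    n_indeterminate: int
    normalized_adhering: float
    normalized_rolling: float
    vessel_class: str
    normalization: str  # "length_and_diameter" or "length_only"


@dataclass
class DualStainPair:
    """Two-channel frame pair for the tight-adherence criterion."""

    frame_gcx: ImageFrame | None = None
    frame_leuko: ImageFrame | None = None
    lag_s: float = 8.0
    match_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if self.lag_s <= 0:
            raise ValueError("lag must be positive")
        if self.match_radius_um <= 0:
            raise ValueError("match_radius must be positive")


def classify_track(
    track: LeukocyteTrack,
    reference_speed: float,
    params: ClassifierParams | None = None,
) -> str:
    """Classify one track as adhering / rolling / flowing / indeterminate.

    Adhering: maximum displacement from the first sample stays within
    ``displacement_epsilon`` over the whole window.  Otherwise the mean
    along-axis speed (net along-axis displacement over track duration) decides
    rolling (< rolling_fraction x reference_speed) vs flowing.  Tracks
    covering less than ``min_coverage`` of the window are indeterminate.
    """
    params = params or ClassifierParams()
    if reference_speed <= 0:
        raise ValueError("reference_speed must be positive")
    if track.duration_s < params.min_coverage * params.window_s:
        return "indeterminate"
    pos = track.positions
    disp = np.linalg.norm(pos - pos[0], axis=1)
    if disp.max() <= params.displacement_epsilon:
        return "adhering"
    along = float(abs((pos[-1] - pos[0]) @ track.vessel.axis_unit))
    mean_speed = along / track.duration_s
    if mean_speed < params.rolling_fraction * reference_speed:
        return "rolling"
    return "flowing"


def count_and_normalize(
    tracks: list[LeukocyteTrack],
    vessel: VesselGeometry,
    reference_speed: float,
    params: ClassifierParams | None = None,
    normalization: str = "length_and_diameter",
) -> ClassifiedCounts:
    """Classify tracks and calibrate counts to a 100 um x 100 um segment.

    The default two-factor normalization multiplies raw counts by
    ``(100 / segment_length) * (100 / diameter)``; ``"length_only"`` applies
    only the length factor.  The form used is recorded in the result.
    """
    if normalization not in ("length_and_diameter", "length_only"):
        raise ValueError(f"unknown normalization {normalization!r}")
    labels = [classify_track(t, reference_speed, params) for t in tracks]
    n_adh = labels.count("adhering")
    n_roll = labels.count("rolling")
    n_flow = labels.count("flowing")
    n_ind = labels.count("indeterminate")
    factor = 100.0 / vessel.segment_length_um
    if normalization == "length_and_diameter":
        factor *= 100.0 / vessel.diameter_um
    return ClassifiedCounts(
        n_adhering=n_adh,
        n_rolling=n_roll,
        n_flowing=n_flow,
        n_indeterminate=n_ind,
        normalized_adhering=n_adh * factor,
        normalized_rolling=n_roll * factor,
        vessel_class=vessel.vessel_class,
        normalization=normalization,
    )


def dual_stain_adherence(
    pair: DualStainPair,
    detections_t0: np.ndarray,
    detections_lag: np.ndarray,
) -> np.ndarray:
    """Label each t0 detection tight-adherent or transient.

    A cell detected at time 0 is *tight-adherent* iff a detection exists in
    the lagged frame within ``match_radius_um`` of its position — the explicit
    form of the "yellow cell" criterion in merged two-colour images.  Both
    detection sets must share one coordinate frame.

    Returns an array of ``"tight-adherent"`` / ``"transient"`` labels, one per
    t0 detection.
    """
    det0 = np.atleast_2d(np.asarray(detections_t0, dtype=float))
    detl = np.atleast_2d(np.asarray(detections_lag, dtype=float))
    if det0.size == 0:
        return np.empty(0, dtype=object)
    labels = np.full(len(det0), "transient", dtype=object)
    if detl.size == 0:
        return labels
    tree = cKDTree(detl)
    dist, _ = tree.query(det0, k=1)
    labels[dist <= pair.match_radius_um] = "tight-adherent"
    return labels
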