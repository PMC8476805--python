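"""Ground-truth synthetic data for every stage of the pipeline.

Raw intravital image archives are rarely available for reanalysis, so
verification rests on simulated inputs with known truth:

* two-channel vessel scenes — a straight vessel of 20-50 um diameter rendered
  at a given axis angle, with a bright glycocalyx band of known sub-vessel
  thickness on each wall (emulating FITC-WGA lectin staining);
* leukocyte tracks of three kinetic classes (adhering / rolling / flowing)
  over the 15-s observation window;
* dye-leakage time-lapses whose interstitial ROI means rise linearly with a
  controllable leak rate over 0-120 min;
* physiological time-course tables (plasma syndecan-1, body weight, blood
  pressure, thickness index) drawn from configurable per-hour means and SDs.

Every generator is a pure function of its spec (which carries the seed):
identical spec => bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import DEFAULT_PIXEL_SIZE_UM, ImageFrame
from .leukocytes import LeukocyteTrack, VesselGeometry
from .permeability import SquareROI, TimelapseSeries
from .stats import TimeCourseTable
from .thickness import OrientedROI, axis_vectors

__all__ = [
    "SceneSpec",
    "SceneGroundTruth",
    "TrackSpec",
    "LeakSpec",
    "CohortSpec",
    "render_vessel_scene",
    "roi_on_wall",
    "simulate_tracks",
    "simulate_leak_series",
    "simulate_cohort",
]

VESSEL_DIAMETER_RANGE_UM = (20.0, 50.0)


# --------------------------------------------------------------------------
# vessel scenes


@dataclass
class SceneSpec:
    """Parameters of one synthetic vessel scene.

    Intensities are 8-bit gray levels; the glycocalyx band must be the bright
    structure (band > lumen and band > background), as in lectin staining.
    """

    vessel_diameter: float = 30.0          # um
    vessel_axis_angle: float = 0.0         # degrees, 0 = along image columns
    gcx_thickness_true: float = 1.885      # um (5 px at default calibration)
    lumen_intensity: int = 80
    band_intensity: int = 200
    background_intensity: int = 10
    noise_sd: float = 0.0                  # gray levels
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    image_shape: tuple[int, int] = (201, 241)
    seed: int = 0
    noise_model: str = "gaussian"          # or "poisson"

    def __post_init__(self) -> None:
        if self.band_intensity <= self.lumen_intensity:
            raise ValueError("band_intensity must exceed lumen_intensity")
        if self.band_intensity <= self.background_intensity:
            raise ValueError("band_intensity must exceed background_intensity")
        if self.gcx_thickness_true < 0:
            raise ValueError("gcx_thickness_true must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        lo, hi = VESSEL_DIAMETER_RANGE_UM
        if not lo <= self.vessel_diameter <= hi:
            warnings.warn(
                f"vessel diameter {self.vessel_diameter} um outside the "
                f"{lo}-{hi} um selection range",
                stacklevel=2,
            )


@dataclass
class SceneGroundTruth:
    """Everything the renderer knows about the scene it drew."""

    band_mask: np.ndarray          # bool, True exactly on band pixels
    center: tuple[float, float]    # (row, col) point on the vessel axis
    axis_angle: float              # degrees
    lumen_radius_px: float
    band_thickness_px: float
    spec: SceneSpec


def _signed_wall_distance(shape: tuple[int, int], center, angle_deg: float) -> np.ndarray:
    """Signed perpendicular distance (px) of each pixel centre from the axis."""
    u, w = axis_vectors(angle_deg)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) * w[0] + (cc - center[1]) * w[1]


def render_vessel_scene(spec: SceneSpec) -> tuple[ImageFrame, SceneGroundTruth]:
    """Render a straight vessel with a glycocalyx band on both walls.

    The lumen occupies signed perpendicular distance |d| < r; the band the
    half-open shell r <= |d| < r + t (so a band of integer pixel thickness is
    exactly that many pixels thick perpendicular to an axis-aligned vessel);
    background elsewhere.  Gaussian (or Poisson) noise is added and the image
    clipped to [0, 255].
    """
    h, wd = spec.image_shape
    center = ((h - 1) / 2.0, (wd - 1) / 2.0)
    r = spec.vessel_diameter / 2.0 / spec.pixel_size
    t = spec.gcx_thickness_true / spec.pixel_size
    _, w = axis_vectors(spec.vessel_axis_angle)
    max_reach = abs(w[0]) * (h - 1) / 2.0 + abs(w[1]) * (wd - 1) / 2.0
    if r + t >= max_reach:
        raise ValueError(
            f"image {h}x{wd} too small for vessel radius {r:.1f}px + "
            f"band {t:.1f}px at angle {spec.vessel_axis_angle}"
        )
    d = np.abs(_signed_wall_distance((h, wd), center, spec.vessel_axis_angle))
    lumen = d < r
    band = (d >= r) & (d < r + t)
    base = np.full((h, wd), float(spec.background_intensity))
    base[lumen] = spec.lumen_intensity
    base[band] = spec.band_intensity
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            base = base + rng.normal(0.0, spec.noise_sd, base.shape)
        else:
            base = rng.poisson(np.maximum(base, 0.0)).astype(float)
    img = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    frame = ImageFrame(img, pixel_size=spec.pixel_size, channel="fitc-wga")
    gt = SceneGroundTruth(
        band_mask=band,
        center=center,
        axis_angle=spec.vessel_axis_angle,
        lumen_radius_px=r,
        band_thickness_px=t,
        spec=spec,
    )
    return frame, gt


def roi_on_wall(
    gt: SceneGroundTruth,
    side: int = 1,
    width_px: int = 40,
    length_px: int = 200,
) -> OrientedROI:
    """Standard wall ROI centred on one glycocalyx band of a rendered scene.

    ``side`` (+1 / -1) selects the wall along the positive or negative
    perpendicular direction.  The ROI long axis follows the vessel axis; its
    width spans the band centre symmetrically, so it includes lumen on one
    side and background on the other, as the manual placement protocol
    prescribes.
    """
    if side not in (1, -1):
        raise ValueError("side must be +1 or -1")
    u, w = axis_vectors(gt.axis_angle)
    wall_d = side * (gt.lumen_radius_px + gt.band_thickness_px / 2.0)
    center = np.asarray(gt.center) + wall_d * w
    anchor = center - (length_px - 1) / 2.0 * u - (width_px - 1) / 2.0 * w
    return OrientedROI(
        anchor=(float(anchor[0]), float(anchor[1])),
        long_axis_angle=gt.axis_angle,
        width_px=width_px,
        length_px=length_px,
    )


# --------------------------------------------------------------------------
# leukocyte tracks


@dataclass
class TrackSpec:
    """Parameters of a simulated leukocyte track cohort.

    Adhering cells jitter around a fixed point (offsets norm-clipped to
    1.5 x jitter_sd, bounding any displacement by 3 x jitter_sd); rolling
    cells advance along the axis at ``rolling_speed_fraction x
    centerline_speed``; flowing cells at ``centerline_speed``.  Lateral
    positions stay inside the vessel; along-axis positions start inside the
    segment and may traverse beyond it, as real cells cross the field.
    """

    n_adhering: int = 5
    n_rolling: int = 5
    n_flowing: int = 5
    window: float = 15.0                   # s
    frame_rate: float = 2.0                # Hz
    centerline_speed: float = 100.0        # um/s
    rolling_speed_fraction: float = 0.2
    jitter_sd: float = 0.5                 # um
    segment_length: float = 100.0          # um
    vessel_diameter: float = 30.0          # um
    axis_angle_deg: float = 0.0
    vessel_class: str = "venule"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.frame_rate <= 0:
            raise ValueError("window and frame_rate must be positive")
        if not 0 < self.rolling_speed_fraction < 1:
            raise ValueError("rolling_speed_fraction must lie in (0, 1)")
        if min(self.n_adhering, self.n_rolling, self.n_flowing) < 0:
            raise ValueError("class counts must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def vessel(self) -> VesselGeometry:
        return VesselGeometry(
            diameter_um=self.vessel_diameter,
            segment_length_um=self.segment_length,
            axis_angle_deg=self.axis_angle_deg,
            vessel_class=self.vessel_class,
        )


def _clipped_jitter(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """(n, 2) jitter offsets with Euclidean norm clipped to 1.5*sd."""
    if sd == 0:
        return np.zeros((n, 2))
    off = rng.normal(0.0, sd, (n, 2))
    norm = np.linalg.norm(off, axis=1, keepdims=True)
    cap = 1.5 * sd
    scale = np.where(norm > cap, cap / np.maximum(norm, 1e-300), 1.0)
    return off * scale


def simulate_tracks(spec: TrackSpec) -> tuple[list[LeukocyteTrack], list[str]]:
    """Simulate tracks of the three kinetic classes with true labels.

    Each track has ``round(window * frame_rate) + 1`` samples (t = 0
    inclusive).  Returns the tracks and their ground-truth class labels in
    matching order (adhering first, then rolling, then flowing).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.window * spec.frame_rate)) + 1
    times = np.arange(n_samples) / spec.frame_rate
    vessel = spec.vessel
    u = vessel.axis_unit
    radius = spec.vessel_diameter / 2.0
    speeds = {
        "adhering": 0.0,
        "rolling": spec.rolling_speed_fraction * spec.centerline_speed,
        "flowing": spec.centerline_speed,
    }
    tracks: list[LeukocyteTrack] = []
    labels: list[str] = []
    track_id = 0
    for label, n in (
        ("adhering", spec.n_adhering),
        ("rolling", spec.n_rolling),
        ("flowing", spec.n_flowing),
    ):
        for _ in range(n):
            s0 = rng.uniform(0.0, spec.segment_length)     # along-axis start
            lat = rng.uniform(-0.9, 0.9) * radius          # lateral offset
            jit = _clipped_jitter(rng, spec.jitter_sd, n_samples)
            along = s0 + speeds[label] * times
            x = along * u[0] - lat * u[1] + jit[:, 0]
            y = along * u[1] + lat * u[0] + jit[:, 1]
            tracks.append(
                LeukocyteTrack(track_id=track_id, t_s=times, x_um=x, y_um=y,
                               vessel=vessel)
            )
            labels.append(label)
            track_id += 1
    return tracks, labels


# --------------------------------------------------------------------------
# leakage time-lapses


@dataclass
class LeakSpec:
    """Parameters of a simulated dye-leakage time-lapse.

    The expected ROI mean at time t (minutes) is
    ``baseline_intensity + leak_rate * t``; per-pixel Gaussian noise is added
    and frames are clipped to [0, 255].
    """

    times: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)  # minutes
    leak_rate: float = 0.0                 # gray levels / min
    baseline_intensity: float = 20.0
    noise_sd: float = 0.0
    n_rois: int = 3
    roi_size_um: float = 30.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if not times or times[0] != 0.0:
            raise ValueError("times must start at 0")
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be >= 0")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        self.times = times


def simulate_leak_series(spec: LeakSpec) -> tuple[TimelapseSeries, float]:
    """Simulate a time-lapse whose ROI means rise linearly with time.

    Frames are sized to hold ``n_rois`` non-overlapping square ROIs of
    ``roi_size_um`` side by side with margins.  Returns the series and the
    true leak rate (gray levels per minute).
    """
    rng = np.random.default_rng(spec.seed)
    size_px = round(spec.roi_size_um / spec.pixel_size)
    margin = 8
    h = size_px + 2 * margin
    w = spec.n_rois * (size_px + margin) + margin
    rois = [
        SquareROI(anchor=(margin, margin + i * (size_px + margin)),
                  size_px=size_px, roi_id=i, size_um=spec.roi_size_um)
        for i in range(spec.n_rois)
    ]
    frames = []
    for t in spec.times:
        base = np.full((h, w), spec.baseline_intensity + spec.leak_rate * t)
        if spec.noise_sd > 0:
            base = base + rng.normal(0.0, spec.noise_sd, base.shape)
        img = np.clip(np.rint(base), 0, 255).astype(np.uint8)
        frames.append((t, ImageFrame(img, pixel_size=spec.pixel_size,
                                     channel="tmr-dextran")))
    return TimelapseSeries(frames=frames, rois=rois), spec.leak_rate


# --------------------------------------------------------------------------
# physiological cohorts


@dataclass
class CohortSpec:
    """Parameters of a simulated physiological time-course cohort.

    ``group_means`` / ``group_sds`` map scheduled hours to the population
    mean and SD of the variable; ``n_per_time`` independent subjects are
    drawn per hour from a normal distribution, truncated at 0 for
    non-negative variables (concentrations and thickness indices).
    """

    SCHEDULE_HOURS = (0, 24, 48, 72, 96, 120, 168, 216)
    NONNEGATIVE_VARIABLES = ("sdc1", "ti_arteriole", "ti_venule")

    variable: str = "sdc1"
    schedule: tuple[int, ...] = (0, 24)
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    n_per_time: int = 3
    units: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [h for h in self.schedule if h not in self.SCHEDULE_HOURS]
        if bad:
            raise ValueError(
                f"hours {bad} not in the protocol grid {self.SCHEDULE_HOURS}"
            )
        if self.n_per_time < 2:
            raise ValueError("n_per_time must be >= 2 so SD is estimable")
        for h in self.schedule:
            if h not in self.group_means or h not in self.group_sds:
                raise ValueError(f"missing mean or SD for scheduled hour {h}")

    @property
    def truncate_at_zero(self) -> bool:
        return self.variable in self.NONNEGATIVE_VARIABLES


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal draws conditioned on being >= 0 (rejection sampling)."""
    out = rng.normal(mean, sd, n)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))


def simulate_cohort(spec: CohortSpec) -> TimeCourseTable:
    """Draw a per-subject time-course table from the spec's per-hour normals."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for h in spec.schedule:
        mean, sd = float(spec.group_means[h]), float(spec.group_sds[h])
        if spec.truncate_at_zero and sd > 0:
            values = _truncated_normal(rng, mean, sd, spec.n_per_time)
        else:
            values = rng.normal(mean, sd, spec.n_per_time)
        for i, v in enumerate(values):
            rows.append({"subject_id": f"{spec.variable}_{h}h_s{i}",
                         "hour": h, "value": float(v)})
    return TimeCourseTable(
        data=pd.DataFrame(rows), variable=spec.variable, units=spec.units
    )
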