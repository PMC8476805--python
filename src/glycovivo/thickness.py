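"""Glycocalyx thickness index (TI) from fluorescent vessel images.

The endothelial glycocalyx appears as a bright band along the vessel wall in
FITC-WGA lectin images.  Its thickness is estimated from a rectangular region
of interest (ROI), 40 x 200 px by default, placed over one wall with the long
axis following the flow direction:

1. a gray-level threshold ``Th = F * (Imax - Imin) + Imin`` is computed from
   the ROI histogram (``F`` defaults to 0.7);
2. the ROI is binarized at ``Th``; supra-threshold pixels are taken as the
   glycocalyx layer;
3. the supra-threshold pixel count divided by the 200-px axis length gives the
   mean band thickness in pixels (``ti_px``), converted to micrometres through
   the pixel calibration (``ti_um``).

ROI placement is user-supplied (anchor + axis angle); automatic wall tracing
is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import GeometryError, ImageFrame

__all__ = [
    "OrientedROI",
    "ThresholdParams",
    "TIResult",
    "extract_roi",
    "compute_threshold",
    "binarize_and_count",
    "compute_ti",
    "summarize_vessels",
]


def axis_vectors(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (row, col) along the ROI long axis and its width.

    Angle 0 points along +columns; the width direction is the long axis
    rotated by +90 degrees, i.e. +rows at angle 0.
    """
    th = math.radians(angle_deg)
    u = np.array([math.sin(th), math.cos(th)])   # long axis
    w = np.array([math.cos(th), -math.sin(th)])  # width
    return u, w


@dataclass
class OrientedROI:
    """Rectangular ROI with its long axis aligned to the flow direction.

    ``anchor`` is the (row, col) pixel of the patch corner (width index 0,
    length index 0).  Default dimensions are the standard 40 x 200 px; other
    sizes are an explicit override.
    """

    anchor: tuple[float, float]
    long_axis_angle: float = 0.0
    width_px: int = 40
    length_px: int = 200

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.length_px <= 0:
            raise ValueError("ROI dimensions must be positive")

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel (rows, cols) index arrays of shape (width, length)."""
        u, w = axis_vectors(self.long_axis_angle)
        i = np.arange(self.width_px)[:, None]
        j = np.arange(self.length_px)[None, :]
        rows = self.anchor[0] + j * u[0] + i * w[0]
        cols = self.anchor[1] + j * u[1] + i * w[1]
        return np.rint(rows).astype(int), np.rint(cols).astype(int)


@dataclass
class ThresholdParams:
    """Parameters of the histogram threshold ``Th = F*(Imax-Imin)+Imin``.

    ``F`` is a dimensionless fraction in [0, 1] (default 0.7).  Pixels are
    compared to ``Th`` with ``>=`` by default (``strict=True`` switches to
    ``>``); ``round_threshold`` optionally rounds ``Th`` to an integer gray
    level before comparison (off by default: ``Th`` is kept exact).
    """

    F: float = 0.7
    strict: bool = False
    round_threshold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")


@dataclass
class TIResult:
    """Thickness index for one ROI."""

    ti_um: float
    ti_px: float
    gcx_pixel_count: int
    threshold_used: float
    i_max: int
    i_min: int
    roi: OrientedROI
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "Imax": self.i_max,
            "Imin": self.i_min,
            "Th": self.threshold_used,
            "count": self.gcx_pixel_count,
            "ti_px": self.ti_px,
            "ti_um": self.ti_um,
            "degenerate_flag": self.degenerate,
        }


def extract_roi(frame: ImageFrame, roi: OrientedROI) -> np.ndarray:
    """Extract the oriented ROI as a (width, length) 8-bit patch.

    Resampling is nearest-neighbour so the 8-bit gray-level histogram that the
    threshold formula depends on is preserved exactly.
    """
    rows, cols = roi.pixel_coordinates()
    h, wd = frame.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= wd:
        raise GeometryError(
            f"ROI (anchor={roi.anchor}, angle={roi.long_axis_angle}, "
            f"{roi.width_px}x{roi.length_px}) extends outside the "
            f"{h}x{wd} image"
        )
    return frame.pixels[rows, cols]


def compute_threshold(patch: np.ndarray, params: ThresholdParams | None = None) -> float:
    """Gray-level threshold ``Th = F*(Imax - Imin) + Imin`` of a patch.

    Returned unrounded (exact up to float arithmetic) unless
    ``params.round_threshold`` is set.
    """
    params = params or ThresholdParams()
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("cannot threshold an empty patch")
    i_max = float(patch.max())
    i_min = float(patch.min())
    th = params.F * (i_max - i_min) + i_min
    if params.round_threshold:
        th = round(th)
    return th


def binarize_and_count(patch: np.ndarray, th: float, *, strict: bool = False) -> int:
    """Count glycocalyx pixels: intensities ``>= Th`` (or ``> Th`` if strict).

    The bright band becomes the counted class after the binarize-then-invert
    step of the original protocol; counting supra-threshold pixels directly is
    equivalent.
    """
    patch = np.asarray(patch)
    if strict:
        return int(np.count_nonzero(patch > th))
    return int(np.count_nonzero(patch >= th))


def compute_ti(
    frame: ImageFrame,
    roi: OrientedROI,
    params: ThresholdParams | None = None,
) -> TIResult:
    """Thickness index of the glycocalyx for one oriented wall ROI.

    Composes ROI extraction, thresholding and supra-threshold counting.
    ``ti_px = count / length_px`` and ``ti_um = ti_px * pixel_size``.  A flat
    patch (Imax == Imin) carries no band evidence: the result is flagged
    degenerate and TI reported as NaN rather than the full ROI area.
    """
    params = params or ThresholdParams()
    patch = extract_roi(frame, roi)
    i_max = int(patch.max())
    i_min = int(patch.min())
    th = compute_threshold(patch, params)
    if i_max == i_min:
        return TIResult(
            ti_um=float("nan"),
            ti_px=float("nan"),
            gcx_pixel_count=patch.size,
            threshold_used=th,
            i_max=i_max,
            i_min=i_min,
            roi=roi,
            degenerate=True,
        )
    count = binarize_and_count(patch, th, strict=params.strict)
    ti_px = count / roi.length_px
    return TIResult(
        ti_um=ti_px * frame.pixel_size,
        ti_px=ti_px,
        gcx_pixel_count=count,
        threshold_used=th,
        i_max=i_max,
        i_min=i_min,
        roi=roi,
    )


def summarize_vessels(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD summary of TI measurements per vessel class and hour.

    Parameters
    ----------
    results : DataFrame
        Columns ``vessel_class``, ``hour``, ``ti_um`` (one row per
        measurement; degenerate measurements should be excluded upstream).

    Returns
    -------
    DataFrame with columns ``vessel_class, hour, mean, sd, n`` where ``sd``
    uses the n-1 denominator.
    """
    required = {"vessel_class", "hour", "ti_um"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if results.empty:
        raise ValueError("no TI results to summarize")
    grouped = results.groupby(["vessel_class", "hour"], sort=True)["ti_um"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, ["vessel_class", "hour"]].to_records(index=False)
        raise ValueError(f"groups with fewer than 2 measurements: {list(bad)}")
    return out
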