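"""Reading and writing the pipeline's on-disk formats.

Images travel as 8-bit grayscale TIFF (PNG supported for documentation
figures); ground-truth masks as paired TIFF + JSON sidecar; tracks and
time-course tables as headered CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .frames import DEFAULT_PIXEL_SIZE_UM, ImageFrame
from .leukocytes import LeukocyteTrack, VesselGeometry
from .stats import TimeCourseTable
from .synthetic import SceneGroundTruth

__all__ = [
    "read_image",
    "write_image",
    "write_scene",
    "write_tracks",
    "read_tracks",
    "write_cohort",
    "read_cohort",
]


def read_image(path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
               channel: str = "") -> ImageFrame:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an RGB export to gray
        arr = arr.mean(axis=-1)
    return ImageFrame(np.clip(np.rint(arr), 0, 255).astype(np.uint8),
                      pixel_size=pixel_size, channel=channel)


def write_image(frame: ImageFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frame.pixels)
    else:
        iio.imwrite(path, frame.pixels)


def write_scene(frame: ImageFrame, gt: SceneGroundTruth, stem: Path) -> None:
    """Write a rendered scene: image TIFF, mask TIFF and JSON sidecar."""
    stem = Path(stem)
    write_image(frame, stem.with_suffix(".tif"))
    tifffile.imwrite(stem.parent / f"{stem.name}_mask.tif",
                     gt.band_mask.astype(np.uint8) * 255)
    sidecar = {
        "spec": dataclasses.asdict(gt.spec),
        "center_row_col": list(gt.center),
        "axis_angle_deg": gt.axis_angle,
        "lumen_radius_px": gt.lumen_radius_px,
        "band_thickness_px": gt.band_thickness_px,
    }
    with open(stem.parent / f"{stem.name}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)


def write_tracks(tracks: list[LeukocyteTrack], path,
                 labels: list[str] | None = None) -> None:
    rows = []
    for k, tr in enumerate(tracks):
        for t, x, y in zip(tr.t_s, tr.x_um, tr.y_um):
            row = {"track_id": tr.track_id, "t_s": t, "x_um": x, "y_um": y}
            if labels is not None:
                row["true_class"] = labels[k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_tracks(path, vessel: VesselGeometry) -> list[LeukocyteTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        tracks.append(LeukocyteTrack(
            track_id=int(tid), t_s=g["t_s"].to_numpy(),
            x_um=g["x_um"].to_numpy(), y_um=g["y_um"].to_numpy(),
            vessel=vessel))
    return tracks


def write_cohort(table: TimeCourseTable, path) -> None:
    table.data.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path, variable: str = "", units: str = "") -> TimeCourseTable:
    return TimeCourseTable(data=pd.read_csv(path), variable=variable,
                           units=units)
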