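"""Core image container shared by all quantification modules.

Intravital fluorescence images are acquired as 8-bit grayscale frames with a
known pixel calibration.  The default calibration, 0.377 um/px, corresponds to
a 200-px ROI axis spanning 75.4 um at the 20x objective used for glycocalyx
imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default pixel calibration in micrometres per pixel (75.4 um / 200 px).
DEFAULT_PIXEL_SIZE_UM = 0.377


class GeometryError(ValueError):
    """A region of interest does not fit inside the image."""


@dataclass
class ImageFrame:
    """A single 8-bit grayscale microscopy frame.

    Parameters
    ----------
    pixels : ndarray
        2-D array of gray levels in [0, 255]; stored as ``uint8``.
    pixel_size : float
        Physical size of one pixel in micrometres.
    channel : str
        Free-form channel tag, e.g. ``"fitc-wga"``, ``"rhodamine"``,
        ``"tmr-dextran"``.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={arr.ndim}")
        if arr.dtype != np.uint8:
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size
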