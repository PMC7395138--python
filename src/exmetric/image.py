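"""Raster image container and calibrated TIFF I/O.

All quantitative operations in this package run on :class:`RasterImage`,
a plain intensity grid carrying its physical pixel size in nanometres.
Images are written as single-channel grayscale TIFF with the pixel size
recorded both in the standard resolution tags and in ImageJ-style
metadata, so files round-trip through FIJI unchanged.

Coordinate convention (used package-wide): 0-based pixel indices, pixel
centers at integer coordinates, ``x`` = column (rightward), ``y`` = row
(downward); physical position = index * ``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when an image file carries no usable pixel-size calibration."""


@dataclass
class RasterImage:
    """A 2D image (or 3D stack, planes first) with physical calibration.

    Parameters
    ----------
    data:
        Intensity grid, ``(H, W)`` or ``(Z, H, W)``. Stored as float64.
    pixel_size_nm:
        Lateral pixel size in nanometres; must be positive.
    axial_step_nm:
        Optional slice spacing for stacks.
    channel_label:
        Free-text label of the imaged channel (e.g. ``"NHS ester"``).
    mask:
        Optional boolean validity mask (True = analyse); pixels outside
        are zeroed by preprocessing and ignored by registration metrics.
    """

    data: np.ndarray
    pixel_size_nm: float
    axial_step_nm: float | None = None
    channel_label: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or a 3D stack, got ndim={self.data.ndim}")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 3

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (width, height) of the pixel grid in nm."""
        h, w = self.data.shape[-2:]
        return (w * self.pixel_size_nm, h * self.pixel_size_nm)

    def with_data(self, data: np.ndarray) -> "RasterImage":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def write_image(path: str | Path, image: RasterImage) -> None:
    """Write a grayscale TIFF with the pixel size in resolution tags.

    Resolution is stored in pixels-per-centimetre (RESUNIT=CENTIMETER),
    plus an ImageJ metadata block for FIJI interoperability.
    """
    px_cm = 1e7 / image.pixel_size_nm  # pixels per cm
    meta = {"unit": "nm", "spacing": image.axial_step_nm or 1.0}
    tifffile.imwrite(
        str(path),
        image.data.astype(np.float32),
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
        imagej=True,
        metadata=meta,
    )


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> RasterImage:
    """Read a grayscale TIFF; pixel size from tags unless supplied.

    Raises
    ------
    CalibrationError
        If the file has no resolution tags and ``pixel_size_nm`` is None.
    ValueError
        For RGB/multisample inputs (only single-sample grayscale is a
        valid carrier for quantitative intensities here).
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path.name}: expected grayscale TIFF, got {page.samplesperpixel} samples/pixel"
            )
        data = tif.asarray()
        if pixel_size_nm is None:
            pixel_size_nm = _pixel_size_from_tags(page)
        if pixel_size_nm is None:
            raise CalibrationError(
                f"{path.name}: no pixel-size calibration in TIFF tags; "
                "pass pixel_size_nm explicitly"
            )
    return RasterImage(np.asarray(data, dtype=np.float64), float(pixel_size_nm))


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    unit_tag = tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", None)
    unit = getattr(unit, "value", unit)  # enum -> int
    # pixels per unit -> nm per pixel
    if unit == 3:  # centimeter
        return 1e7 * den / num
    if unit == 2:  # inch
        return 2.54e7 * den / num
    return None
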