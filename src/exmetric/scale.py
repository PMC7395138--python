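"""Linear expansion-factor estimation and expansion-scaling arithmetic.

The linear expansion factor of a gel-embedded specimen is estimated as
the square root of an area ratio: mean segmented nuclear cross-sectional
area post/pre, or the physical area ratio of landmark-matched crops of
a registered image pair. ``scale_convert`` performs the bookkeeping
between image-frame and specimen-frame lengths (divide or multiply by
the factor) and the volumetric decrowding factor (cube of the linear
factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .image import RasterImage


@dataclass
class ExpansionEstimate:
    linear_factor: float
    method: str  # "nuclear_area" | "landmark_crop" | "registration_scale"
    n_objects: int
    dispersion: float = float("nan")  # sd across objects/experiments

    def __post_init__(self) -> None:
        if not self.linear_factor > 0:
            raise ValueError("linear_factor must be > 0")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")


def nuclear_areas(
    image: RasterImage,
    min_area_um2: float = 20.0,
    threshold_value: float | None = None,
) -> list[float]:
    """Segment a nuclear-stain image and return component areas in µm².

    Otsu threshold, hole filling, connected components; components below
    ``min_area_um2`` or touching the image border are discarded (border
    objects are truncated and would bias the mean area).
    """
    data = image.data
    thr = threshold_value if threshold_value is not None else threshold_otsu(data)
    fg = ndimage.binary_fill_holes(data > thr)
    fg = clear_border(fg)
    lab = label(fg)
    px_um2 = (image.pixel_size_nm / 1000.0) ** 2
    areas = [r.area * px_um2 for r in regionprops(lab)]
    areas = [a for a in areas if a >= min_area_um2]
    if not areas:
        raise ValueError(
            f"no nucleus above {min_area_um2} um^2 survived segmentation"
        )
    return areas


def expansion_factor(pre_areas, post_areas) -> ExpansionEstimate:
    """sqrt(mean(post areas) / mean(pre areas))."""
    pre_a = np.asarray(list(pre_areas), dtype=float)
    post_a = np.asarray(list(post_areas), dtype=float)
    if len(pre_a) == 0 or len(post_a) == 0:
        raise ValueError("area lists must be nonempty")
    if np.any(pre_a <= 0) or np.any(post_a <= 0):
        raise ValueError("areas must be positive")
    factor = float(np.sqrt(post_a.mean() / pre_a.mean()))
    # per-object dispersion: sd of sqrt(post_i / mean(pre))
    disp = float(np.std(np.sqrt(post_a / pre_a.mean()), ddof=1)) if len(post_a) > 1 else float("nan")
    return ExpansionEstimate(factor, "nuclear_area",
                             n_objects=len(pre_a) + len(post_a), dispersion=disp)


def crop_factor(
    pre_crop_shape_px: tuple[int, int],
    post_crop_shape_px: tuple[int, int],
    pre_pixel_size_nm: float,
    post_pixel_size_nm: float,
) -> ExpansionEstimate:
    """Expansion factor from landmark-matched rectangular crops.

    The crops are the same four landmark features identified in the pre
    image and the (similarity-registered) post image; the factor is the
    square root of their physical area ratio.
    """
    (h0, w0), (h1, w1) = pre_crop_shape_px, post_crop_shape_px
    if h0 <= 0 or w0 <= 0 or h1 <= 0 or w1 <= 0:
        raise ValueError("crop rectangles must be non-degenerate")
    area_pre = h0 * w0 * pre_pixel_size_nm**2
    area_post = h1 * w1 * post_pixel_size_nm**2
    return ExpansionEstimate(float(np.sqrt(area_post / area_pre)),
                             "landmark_crop", n_objects=1)


def scale_convert(value: float, factor: float, direction: str) -> float:
    """Expansion-scaling arithmetic.

    - ``image_to_specimen``: divide an image-frame length by the factor
      (e.g. a 300 nm optical PSF at 13x expansion corresponds to ~23 nm
      in the specimen);
    - ``specimen_to_image``: multiply (3 nm protein spacing at 16x
      becomes ~48 nm in the gel);
    - ``volumetric``: the cube of the linear factor (the molecular
      decrowding ratio); ``value`` is ignored.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if value < 0:
        raise ValueError("value must be >= 0")
    if direction == "image_to_specimen":
        return value / factor
    if direction == "specimen_to_image":
        return value * factor
    if direction == "volumetric":
        return factor**3
    raise ValueError(f"unknown direction {direction!r}")
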