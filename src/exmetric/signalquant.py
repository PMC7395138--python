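"""Fluorescence-retention and labeling-efficiency quantification.

Protein retention across expansion rounds is read out as the
background-corrected total fluorescence signal (TFS) per field of view,
normalized per cell (nuclear count), per manually outlined ROI, or per
mask area, and corrected for camera exposure time. Channel bleedthrough
is removed by subtracting a constant fraction of the contaminating
channel. Conditions are compared with a classical unpaired two-tailed
t-test (pooled variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.segmentation import watershed

from .image import RasterImage


@dataclass
class FieldMeasurement:
    """One field of view's background-corrected totals."""

    total_signal: float
    background_level: float
    exposure_time_ms: float
    mode: str  # "per_cell" | "per_roi" | "per_mask_area"
    n_cells: int | None = None
    roi_area_um2: float | None = None

    @property
    def normalized_signal(self) -> float:
        """Signal per cell or per µm², per ms of exposure."""
        if self.mode == "per_cell":
            return self.total_signal / self.n_cells / self.exposure_time_ms
        return self.total_signal / self.roi_area_um2 / self.exposure_time_ms


def background_level(image: RasterImage, roi: np.ndarray) -> float:
    """Mean intensity inside a cell-free ROI mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.data.shape:
        raise ValueError("roi shape must match the image")
    if not roi.any():
        raise ValueError("background ROI is empty")
    return float(image.data[roi].mean())


def count_nuclei(
    image: RasterImage,
    min_size_px: int = 50,
    split: bool = False,
    threshold_value: float | None = None,
) -> int:
    """Count nuclei by connected components of the thresholded stain.

    With ``split`` enabled, touching nuclei are separated by a watershed
    on the distance transform seeded at its local maxima — the automated
    stand-in for the manual correction of merged objects.
    """
    data = image.data
    if data.max() == data.min():
        return 0
    thr = threshold_value if threshold_value is not None else threshold_otsu(data)
    fg = ndimage.binary_fill_holes(data > thr)
    lab = label(fg)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size_px
    keep[0] = False
    fg = keep[lab]
    if not fg.any():
        return 0
    if not split:
        return int(label(fg).max())
    dist = ndimage.distance_transform_edt(fg)
    coords = peak_local_max(dist, labels=fg, min_distance=5,
                            exclude_border=False)
    markers = np.zeros_like(dist, dtype=int)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        return int(label(fg).max())
    ws = watershed(-dist, markers, mask=fg)
    return int(len(np.unique(ws)) - (1 if 0 in ws else 0))


def total_signal(
    image: RasterImage,
    mode: str,
    background: float,
    n_cells: int | None = None,
    roi: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    exposure_ms: float = 1.0,
) -> FieldMeasurement:
    """Background-corrected total fluorescence, normalized by mode.

    - ``per_cell``: total over the whole field divided by the cell count;
    - ``per_roi``: total inside a manually outlined ROI divided by its area;
    - ``per_mask_area``: total inside the ROI (or field) divided by the
      area of a structure mask from a reference channel.

    All modes divide by the exposure time so different camera settings
    are comparable.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be > 0")
    data = image.data
    px_um2 = (image.pixel_size_nm / 1000.0) ** 2
    corrected = data - background
    if mode == "per_cell":
        if not n_cells:
            raise ValueError("per_cell mode requires n_cells >= 1")
        total = float(corrected.sum())
        return FieldMeasurement(total, background, exposure_ms, mode,
                                n_cells=n_cells)
    if mode == "per_roi":
        if roi is None or not np.asarray(roi, bool).any():
            raise ValueError("per_roi mode requires a nonempty roi")
        roi = np.asarray(roi, bool)
        total = float(corrected[roi].sum())
        return FieldMeasurement(total, background, exposure_ms, mode,
                                roi_area_um2=float(roi.sum() * px_um2))
    if mode == "per_mask_area":
        if mask is None or not np.asarray(mask, bool).any():
            raise ValueError("per_mask_area mode requires a nonempty mask")
        mask = np.asarray(mask, bool)
        region = mask if roi is None else (np.asarray(roi, bool))
        total = float(corrected[region].sum())
        return FieldMeasurement(total, background, exposure_ms, mode,
                                roi_area_um2=float(mask.sum() * px_um2))
    raise ValueError(f"unknown mode {mode!r}")


def bleedthrough_subtract(
    channel_a: RasterImage,
    channel_b: RasterImage,
    fraction: float,
) -> RasterImage:
    """a - fraction * b, clipped at zero (intensities are non-negative)."""
    if channel_a.data.shape != channel_b.data.shape:
        raise ValueError("channel shapes differ")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    out = np.maximum(channel_a.data - fraction * channel_b.data, 0.0)
    return channel_a.with_data(out)


def compare_groups(values_1, values_2, welch: bool = False) -> dict:
    """Unpaired two-tailed t-test plus the group-mean ratio.

    Pooled-variance by default (the convention of the commercial
    statistics packages used for such assays); set ``welch`` for the
    unequal-variance variant. The mean ratio (group 2 / group 1)
    supports retention statements such as "no decrease in signal".
    """
    a = np.asarray(list(values_1), dtype=float)
    b = np.asarray(list(values_2), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "t": float(t),
        "p": float(p),
        "mean_1": float(a.mean()),
        "mean_2": float(b.mean()),
        "ratio": float(b.mean() / a.mean()),
        "n_1": len(a),
        "n_2": len(b),
    }
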