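"""Organelle morphometry from post-expansion images.

Structural distances are read off thick line profiles (intensity
averaged across a band perpendicular to the line, the standard FIJI
convention) and corrected to biological units by dividing by the linear
expansion factor: cristae and Golgi inter-cisternal spacings from
peak-to-peak distances, ER tubule diameters from two crest points,
centriole roundness from the moments-equivalent ellipse of a binarized
axial view, and centriole length-to-width ratio from paired profiles
(where the expansion factor cancels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .image import RasterImage


@dataclass
class LineProfile:
    """Band-averaged intensity profile between two endpoints.

    Positions are physical (nm) along the line; intensities are the
    mean across ``thickness_px`` parallel sub-lines.
    """

    p0_px: np.ndarray
    p1_px: np.ndarray
    thickness_px: int
    positions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.thickness_px < 1 or self.thickness_px % 2 == 0:
            raise ValueError("thickness_px must be odd and >= 1")


@dataclass
class MorphometricResult:
    kind: str
    values_nm: np.ndarray  # raw image-frame values
    expansion_factor: float

    @property
    def corrected_nm(self) -> np.ndarray:
        return self.values_nm / self.expansion_factor

    @property
    def summary(self) -> dict:
        c = self.corrected_nm
        return {
            "kind": self.kind,
            "mean": float(np.mean(c)),
            "sd": float(np.std(c, ddof=1)) if len(c) > 1 else float("nan"),
            "median": float(np.median(c)),
            "iqr": float(np.subtract(*np.percentile(c, [75, 25]))),
            "n": len(c),
        }


def thick_line_profile(
    image: RasterImage,
    p0_px,
    p1_px,
    thickness_px: int = 10,
) -> LineProfile:
    """Sample a band of parallel lines and average across the thickness.

    Even thickness values are rounded up to the next odd number so the
    band is symmetric about the segment.
    """
    if thickness_px % 2 == 0:
        thickness_px += 1
    p0 = np.asarray(p0_px, dtype=float)
    p1 = np.asarray(p1_px, dtype=float)
    H, W = image.data.shape[-2:]
    for p in (p0, p1):
        if not (0 <= p[0] <= W - 1 and 0 <= p[1] <= H - 1):
            raise ValueError(f"endpoint {p} outside the image")
    d = p1 - p0
    length_px = float(np.linalg.norm(d))
    if length_px == 0:
        raise ValueError("endpoints coincide")
    d /= length_px
    normal = np.array([-d[1], d[0]])
    n_samples = int(np.ceil(length_px)) + 1
    t = np.linspace(0, length_px, n_samples)
    offsets = np.arange(thickness_px) - (thickness_px - 1) / 2
    base = p0[None, :] + t[:, None] * d[None, :]
    prof = np.zeros(n_samples)
    for off in offsets:
        pts = base + off * normal
        prof += ndimage.map_coordinates(image.data, [pts[:, 1], pts[:, 0]],
                                        order=1, mode="nearest")
    prof /= thickness_px
    return LineProfile(p0, p1, thickness_px, t * image.pixel_size_nm, prof)


def profile_peaks(
    profile: LineProfile,
    prominence_frac: float = 0.1,
    min_separation: int = 3,
) -> np.ndarray:
    """Positions (nm) of local maxima with relative-prominence gating."""
    y = profile.intensities
    dyn = float(y.max() - y.min())
    peaks, _ = find_peaks(y, prominence=prominence_frac * dyn,
                          distance=min_separation)
    return profile.positions_nm[peaks]


def peak_spacing(
    profile: LineProfile,
    expansion_factor: float,
    kind: str = "cristae_spacing",
    prominence_frac: float = 0.1,
    min_separation: int = 3,
) -> MorphometricResult:
    """Consecutive peak-to-peak separations, expansion-corrected to nm."""
    pos = profile_peaks(profile, prominence_frac, min_separation)
    if len(pos) < 2:
        raise ValueError(f"need >= 2 peaks for a spacing, detected {len(pos)}")
    return MorphometricResult(kind, np.diff(pos), expansion_factor)


def two_point_diameter(
    p_a_px,
    p_b_px,
    pixel_size_nm: float,
    expansion_factor: float,
) -> float:
    """Euclidean crest-to-crest distance, expansion-corrected (nm)."""
    a = np.asarray(p_a_px, dtype=float)
    b = np.asarray(p_b_px, dtype=float)
    d = float(np.linalg.norm(a - b))
    if d == 0:
        raise ValueError("points coincide")
    return d * pixel_size_nm / expansion_factor


def roundness(
    image_region: RasterImage,
    blur_sigma_px: float = 1.0,
    threshold_value: float | None = None,
    descriptor: str = "roundness",
) -> float:
    """Shape descriptor of the single thresholded object in a region.

    ``roundness`` is 4*area / (pi * major_axis^2) of the moments-
    equivalent ellipse (1 for a circle, b/a for an ellipse);
    ``circularity`` (4*pi*area/perimeter^2) is available as an
    alternative.
    """
    data = image_region.data
    if blur_sigma_px > 0:
        data = ndimage.gaussian_filter(data, blur_sigma_px)
    thr = threshold_value if threshold_value is not None else threshold_otsu(data)
    mask = ndimage.binary_fill_holes(data > thr)
    lab = label(mask)
    props = regionprops(lab)
    if len(props) != 1:
        raise ValueError(f"expected exactly one object, found {len(props)}")
    r = props[0]
    if descriptor == "roundness":
        return float(4.0 * r.area / (np.pi * r.axis_major_length**2))
    if descriptor == "circularity":
        return float(4.0 * np.pi * r.area / r.perimeter**2)
    raise ValueError(f"unknown descriptor {descriptor!r}")


def length_width_ratio(
    profile_length: LineProfile,
    profile_width: LineProfile,
    prominence_frac: float = 0.1,
    min_separation: int = 3,
) -> float:
    """Centriole length / width from two peak-to-peak profile distances.

    Each profile must contain exactly two dominant peaks (the barrel
    ends along the length; the two walls across the width); the
    expansion factor cancels in the ratio.
    """
    spans = []
    for name, prof in (("length", profile_length), ("width", profile_width)):
        pos = profile_peaks(prof, prominence_frac, min_separation)
        if len(pos) != 2:
            raise ValueError(
                f"{name} profile must have exactly 2 peaks, found {len(pos)}"
            )
        spans.append(pos[1] - pos[0])
    return float(spans[0] / spans[1])
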