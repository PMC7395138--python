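"""Ground-truthed synthetic specimens for expansion-microscopy metrology.

Real validation data for iterative expansion protocols (pre-/post-
expansion image pairs of the same field of view) are rarely deposited,
so this module generates them: vector-geometry scenes of nuclei,
microtubule filaments, mitochondria (optionally with cristae striping),
Golgi stacks and centrioles, imaged through a Gaussian PSF with
background and Poisson-Gaussian noise, and re-imaged after a known
deformation

    x  ->  s * M * (x + u(x))

composed of a global linear expansion ``s``, a unimodular anisotropy
(shear) matrix ``M`` and a smooth random residual field ``u`` expressed
in pre-expansion coordinates. Because primitives are deformed in
continuous coordinates (never by warping pixels), the ground truth —
the exact coordinate map, the true outline/centerline point set, and
every structural parameter (spacings, axis ratios, areas) — is known
without interpolation error.

All geometry is in nanometres of the pre-expansion (biological) frame
unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from ._rng import substream
from .image import RasterImage
from .registration import DeformationField
from .distortion import PointSet, RmsCurve, rms_vs_length


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

@dataclass
class Points:
    """Isolated point emitters (useful as PSF probes)."""

    coords_nm: np.ndarray  # (N, 2) as (x, y)
    intensity: float

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(self.coords_nm, dtype=float))
        w = np.full(len(pts), self.intensity / len(pts))
        return pts, w

    def reference_points(self, step_nm: float) -> np.ndarray:
        return np.atleast_2d(np.asarray(self.coords_nm, dtype=float))


@dataclass
class Ellipse:
    """Filled ellipse, or an annulus when ``ring_fraction`` > 0.

    ``ring_fraction`` is the wall thickness as a fraction of the outer
    semi-axes; the inner boundary is the outer one shrunk by that
    fraction, so the annulus has uniform relative thickness.
    """

    center_nm: np.ndarray
    semi_axes_nm: tuple[float, float]  # (a along x', b along y') before rotation
    angle_rad: float
    intensity: float
    ring_fraction: float = 0.0

    def _mask_samples(self, step_nm: float) -> np.ndarray:
        a, b = self.semi_axes_nm
        r = max(a, b)
        n = max(3, int(np.ceil(2 * r / step_nm)))
        g = (np.arange(n) + 0.5) / n * 2 * r - r
        xx, yy = np.meshgrid(g, g)
        rho2 = (xx / a) ** 2 + (yy / b) ** 2
        inside = rho2 <= 1.0
        if self.ring_fraction > 0:
            f = 1.0 - self.ring_fraction
            inner = (xx / (f * a)) ** 2 + (yy / (f * b)) ** 2 <= 1.0
            inside &= ~inner
        pts = np.column_stack([xx[inside], yy[inside]])
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return pts @ rot.T + np.asarray(self.center_nm)

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        pts = self._mask_samples(step_nm)
        w = np.full(len(pts), self.intensity / max(len(pts), 1))
        return pts, w

    def reference_points(self, step_nm: float) -> np.ndarray:
        """Outer boundary samples (the outline ground truth)."""
        a, b = self.semi_axes_nm
        n = max(16, int(np.ceil(2 * np.pi * max(a, b) / step_nm)))
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return pts @ rot.T + np.asarray(self.center_nm)

    @property
    def area_nm2(self) -> float:
        a, b = self.semi_axes_nm
        area = np.pi * a * b
        if self.ring_fraction > 0:
            area *= 1.0 - (1.0 - self.ring_fraction) ** 2
        return area


@dataclass
class Curve:
    """Open polyline of given physical width; intensity spread uniformly."""

    points_nm: np.ndarray  # (K, 2) ordered control points
    intensity: float
    width_nm: float = 0.0

    def _resampled(self, step_nm: float) -> np.ndarray:
        p = np.asarray(self.points_nm, dtype=float)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        n = max(2, int(np.ceil(total / step_nm)) + 1)
        t = np.linspace(0, total, n)
        x = np.interp(t, arclen, p[:, 0])
        y = np.interp(t, arclen, p[:, 1])
        return np.column_stack([x, y])

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        center = self._resampled(step_nm)
        if self.width_nm > step_nm:
            tang = np.gradient(center, axis=0)
            tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            n_off = int(np.ceil(self.width_nm / step_nm))
            offs = (np.arange(n_off) + 0.5) / n_off * self.width_nm - self.width_nm / 2
            pts = np.concatenate([center + o * normal for o in offs])
        else:
            pts = center
        w = np.full(len(pts), self.intensity / len(pts))
        return pts, w

    def reference_points(self, step_nm: float) -> np.ndarray:
        return self._resampled(step_nm)


@dataclass
class Capsule:
    """Filled stadium shape (segment dilated by a radius): mitochondrion body."""

    p0_nm: np.ndarray
    p1_nm: np.ndarray
    radius_nm: float
    intensity: float

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        p0 = np.asarray(self.p0_nm, float)
        p1 = np.asarray(self.p1_nm, float)
        lo = np.minimum(p0, p1) - self.radius_nm
        hi = np.maximum(p0, p1) + self.radius_nm
        nx = max(3, int(np.ceil((hi[0] - lo[0]) / step_nm)))
        ny = max(3, int(np.ceil((hi[1] - lo[1]) / step_nm)))
        gx = lo[0] + (np.arange(nx) + 0.5) / nx * (hi[0] - lo[0])
        gy = lo[1] + (np.arange(ny) + 0.5) / ny * (hi[1] - lo[1])
        xx, yy = np.meshgrid(gx, gy)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d = _dist_to_segment(pts, p0, p1)
        pts = pts[d <= self.radius_nm]
        w = np.full(len(pts), self.intensity / max(len(pts), 1))
        return pts, w

    def reference_points(self, step_nm: float) -> np.ndarray:
        p0 = np.asarray(self.p0_nm, float)
        p1 = np.asarray(self.p1_nm, float)
        n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step_nm)) + 1)
        t = np.linspace(0, 1, n)[:, None]
        return p0 + t * (p1 - p0)

    @property
    def area_nm2(self) -> float:
        length = float(np.linalg.norm(np.asarray(self.p1_nm) - np.asarray(self.p0_nm)))
        return 2 * self.radius_nm * length + np.pi * self.radius_nm**2


def _dist_to_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / max(L2, 1e-12), 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


@dataclass
class StripeSet:
    """Family of parallel straight segments at exact center-to-center spacing.

    Models cristae within a mitochondrion or the cisternae of a Golgi
    stack; ``spacing_nm`` is the ground-truth consecutive separation.
    """

    segments_nm: list  # list of (p0, p1) arrays
    spacing_nm: float
    intensity: float  # per segment
    width_nm: float = 0.0

    def _curves(self) -> list[Curve]:
        return [
            Curve(np.array([p0, p1]), self.intensity, self.width_nm)
            for p0, p1 in self.segments_nm
        ]

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        parts = [c.sample_points(step_nm) for c in self._curves()]
        return np.concatenate([p for p, _ in parts]), np.concatenate([w for _, w in parts])

    def reference_points(self, step_nm: float) -> np.ndarray:
        return np.concatenate([c.reference_points(step_nm) for c in self._curves()])


# --------------------------------------------------------------------------
# scene / imaging / deformation specs
# --------------------------------------------------------------------------

class GeometryError(ValueError):
    """A requested scene parameter combination is geometrically inconsistent."""


SCENE_KINDS = ("nuclei", "filaments", "mitochondria", "golgi", "centriole")


@dataclass
class PhantomScene:
    kind: str
    primitives: list
    field_size_nm: tuple[float, float]  # (width, height)
    seed: int
    structure: dict = field(default_factory=dict)  # true structural parameters

    @property
    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.primitives))

    def sample_points(self, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
        if not self.primitives:  # flat-background phantom
            return np.empty((0, 2)), np.empty(0)
        parts = [p.sample_points(step_nm) for p in self.primitives]
        pts = np.concatenate([p for p, _ in parts])
        w = np.concatenate([w for _, w in parts])
        return pts, w

    def reference_points_nm(self, step_nm: float = 100.0) -> np.ndarray:
        """Ground-truth outline (blob kinds) / centerline (linear kinds)."""
        return np.concatenate([p.reference_points(step_nm) for p in self.primitives])


@dataclass
class ImagingParams:
    """Acquisition model: Gaussian PSF, offset background, shot + read noise.

    ``poisson_scale`` is the number of detected photons per intensity
    unit (0 disables shot noise); ``exposure_time_ms`` scales the signal
    linearly and defaults to 1 so recorded intensities equal scene
    intensities.
    """

    pixel_size_nm: float = 100.0
    psf_sigma_nm: float = 120.0
    background_level: float = 10.0
    poisson_scale: float = 1.0
    gaussian_read_noise_sd: float = 2.0
    exposure_time_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")
        for name in ("background_level", "poisson_scale", "gaussian_read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.exposure_time_ms > 0:
            raise ValueError("exposure_time_ms must be > 0")


@dataclass
class DeformationSpec:
    """Forward model of the expansion: scale x shear x smooth residual field."""

    scale: float = 1.0
    shear: np.ndarray = field(default_factory=lambda: np.eye(2))
    nonrigid_amplitude_nm: float = 0.0
    nonrigid_correlation_length_nm: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shear = np.asarray(self.shear, dtype=float)
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if abs(np.linalg.det(self.shear) - 1.0) > 1e-9:
            raise ValueError(
                f"shear matrix must be unimodular, det={np.linalg.det(self.shear)!r}"
            )
        if self.nonrigid_amplitude_nm < 0:
            raise ValueError("nonrigid_amplitude_nm must be >= 0")
        if not self.nonrigid_correlation_length_nm > 0:
            raise ValueError("nonrigid_correlation_length_nm must be > 0")


class NonRigidField:
    """Smooth stationary random displacement field on the pre-expansion domain.

    Synthesized as white noise on a regular grid, band-limited by a hard
    isotropic spectral cutoff at wavenumber 2*pi/correlation_length
    (independently per component), then rescaled so the RMS vector
    magnitude over the domain equals the requested amplitude. Continuous
    evaluation uses cubic spline interpolation of the synthesis grid.
    """

    def __init__(
        self,
        field_size_nm: tuple[float, float],
        amplitude_nm: float,
        correlation_length_nm: float,
        seed: int,
        grid_n: int = 128,
    ) -> None:
        self.field_size_nm = field_size_nm
        self.amplitude_nm = amplitude_nm
        w, h = field_size_nm
        # margin so points slightly outside the nominal field still evaluate
        self._x0, self._y0 = -0.05 * w, -0.05 * h
        lx, ly = 1.1 * w, 1.1 * h
        rng = substream(seed, "nonrigid-field")
        kx = 2 * np.pi * np.fft.fftfreq(grid_n, d=lx / grid_n)
        ky = 2 * np.pi * np.fft.fftfreq(grid_n, d=ly / grid_n)
        kmag = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
        keep = (kmag <= 2 * np.pi / correlation_length_nm) & (kmag > 0)
        comps = []
        for _ in range(2):
            white = rng.standard_normal((grid_n, grid_n))
            spec = np.fft.fft2(white) * keep
            comps.append(np.real(np.fft.ifft2(spec)))
        u = np.stack(comps, axis=-1)  # (gy, gx, 2)
        # normalize over the nominal field, excluding the evaluation margin
        gxc = self._x0 + np.arange(grid_n) * lx / grid_n
        gyc = self._y0 + np.arange(grid_n) * ly / grid_n
        inside = ((gxc >= 0) & (gxc <= w))[None, :] & ((gyc >= 0) & (gyc <= h))[:, None]
        rms = float(np.sqrt(np.mean(np.sum(u[inside] ** 2, axis=-1))))
        u *= amplitude_nm / rms if rms > 0 else 0.0
        self.grid_u = u
        gx = self._x0 + np.arange(grid_n) * lx / grid_n
        gy = self._y0 + np.arange(grid_n) * ly / grid_n
        self._splines = [
            RectBivariateSpline(gy, gx, u[..., c], kx=3, ky=3) for c in range(2)
        ]

    def __call__(self, points_nm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_nm)
        ux = self._splines[0](p[:, 1], p[:, 0], grid=False)
        uy = self._splines[1](p[:, 1], p[:, 0], grid=False)
        return np.column_stack([ux, uy])


@dataclass
class GroundTruth:
    """Exact deformation map plus the scene's true structural parameters."""

    scale: float
    shear: np.ndarray
    offset_nm: np.ndarray  # translation placing the deformed scene on the post grid
    nonrigid: NonRigidField | None
    true_points: PointSet
    true_spacings_nm: float | None = None
    true_axis_ratio: float | None = None
    true_region_areas_um2: list | None = None

    def residual_nm(self, points_nm: np.ndarray) -> np.ndarray:
        """Residual displacement u(x) in pre-expansion nm."""
        if self.nonrigid is None:
            return np.zeros_like(np.atleast_2d(points_nm), dtype=float)
        return self.nonrigid(points_nm)

    def map_points(self, points_nm: np.ndarray) -> np.ndarray:
        """Full forward map x -> s*M*(x + u(x)) + offset, in post-frame nm."""
        p = np.atleast_2d(np.asarray(points_nm, dtype=float))
        q = p + self.residual_nm(p)
        return self.scale * (q @ self.shear.T) + self.offset_nm


# --------------------------------------------------------------------------
# scene construction
# --------------------------------------------------------------------------

_DEFAULT_FIELD = (51_200.0, 51_200.0)  # 512 px at 100 nm/px


def make_scene(kind: str, params: dict | None = None, seed: int = 0) -> PhantomScene:
    """Build a seeded vector scene of one structure class.

    Recognised ``params`` keys (defaults in parentheses):

    - nuclei: ``n`` (5), ``radius_um`` (4.0), ``radius_sd_um`` (0.6),
      ``ellipticity_max`` (1.25)
    - filaments: ``n`` (20), ``width_nm`` (25), ``step_sd_rad`` (0.25)
    - mitochondria: ``n`` (12), ``with_cristae`` (False),
      ``cristae_spacing_nm`` (85)
    - golgi: ``n_stacks`` (6), ``n_cisternae`` (4), ``spacing_nm`` (64)
    - centriole: ``view`` ("axial"), ``axis_ratio`` (1.0),
      ``diameter_nm`` (250), ``length_nm`` (450), ``width_nm`` (250)

    All kinds accept ``field_size_nm`` (51,200 x 51,200, i.e. a 512 px
    field at 100 nm/px).
    """
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; choose from {SCENE_KINDS}")
    params = dict(params or {})
    fw, fh = params.pop("field_size_nm", _DEFAULT_FIELD)
    rng = substream(seed, f"scene-{kind}")
    builder = {
        "nuclei": _make_nuclei,
        "filaments": _make_filaments,
        "mitochondria": _make_mitochondria,
        "golgi": _make_golgi,
        "centriole": _make_centriole,
    }[kind]
    primitives, structure = builder(params, (fw, fh), rng)
    if params:
        raise ValueError(f"unknown params for kind {kind!r}: {sorted(params)}")
    scene = PhantomScene(kind, primitives, (fw, fh), seed, structure)
    return scene


def _make_nuclei(params, field_size, rng):
    n = int(params.pop("n", 5))
    r_mean = float(params.pop("radius_um", 4.0)) * 1000
    r_sd = float(params.pop("radius_sd_um", 0.6)) * 1000
    ell_max = float(params.pop("ellipticity_max", 1.25))
    fw, fh = field_size
    prims: list = []
    tries = 0
    while len(prims) < n and tries < 2000:
        tries += 1
        r = float(np.clip(rng.normal(r_mean, r_sd), 0.4 * r_mean, 1.8 * r_mean))
        ell = rng.uniform(1.0, ell_max)
        a, b = r * np.sqrt(ell), r / np.sqrt(ell)
        margin = max(a, b) + 500.0
        if 2 * margin >= min(fw, fh):
            raise GeometryError("nucleus radius too large for the field of view")
        c = rng.uniform([margin, margin], [fw - margin, fh - margin])
        ok = all(
            np.linalg.norm(c - p.center_nm) > max(p.semi_axes_nm) + max(a, b) + 800
            for p in prims
        )
        if ok:
            area_um2 = np.pi * a * b / 1e6
            prims.append(Ellipse(c, (a, b), rng.uniform(0, np.pi), 12000.0 * area_um2))
    areas = [p.area_nm2 / 1e6 for p in prims]
    return prims, {"region_areas_um2": areas}


def _make_filaments(params, field_size, rng):
    n = int(params.pop("n", 20))
    width = float(params.pop("width_nm", 25.0))
    step_sd = float(params.pop("step_sd_rad", 0.25))
    fw, fh = field_size
    step = 500.0  # nm per control segment
    prims = []
    for _ in range(n):
        p = rng.uniform([0.05 * fw, 0.05 * fh], [0.95 * fw, 0.95 * fh])
        theta = rng.uniform(0, 2 * np.pi)
        pts = [p.copy()]
        n_steps = int(rng.uniform(0.4, 1.2) * min(fw, fh) / step)
        for _ in range(n_steps):
            theta += rng.normal(0, step_sd)
            p = p + step * np.array([np.cos(theta), np.sin(theta)])
            if not (0 < p[0] < fw and 0 < p[1] < fh):
                break
            pts.append(p.copy())
        if len(pts) >= 4:
            arr = np.array(pts)
            length_um = np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)) / 1000
            prims.append(Curve(arr, 1500.0 * length_um, width))
    return prims, {}


def _make_mitochondria(params, field_size, rng):
    n = int(params.pop("n", 12))
    with_cristae = bool(params.pop("with_cristae", False))
    spacing = float(params.pop("cristae_spacing_nm", 85.0))
    fw, fh = field_size
    prims = []
    for _ in range(n):
        length = rng.uniform(1500, 4000)
        radius = rng.uniform(180, 350)
        if with_cristae and spacing >= length:
            raise GeometryError(
                f"cristae spacing {spacing} nm must be smaller than the "
                f"mitochondrion length {length:.0f} nm"
            )
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        margin = length / 2 + radius + 500
        c = rng.uniform([margin, margin], [fw - margin, fh - margin])
        p0, p1 = c - d * length / 2, c + d * length / 2
        area_um2 = (2 * radius * length + np.pi * radius**2) / 1e6
        prims.append(Capsule(p0, p1, radius, 8000.0 * area_um2))
        if with_cristae:
            normal = np.array([-d[1], d[0]])
            k_max = int((length / 2 - spacing / 2) // spacing)
            segs = []
            for k in range(-k_max, k_max + 1):
                mid = c + d * (k * spacing)
                half = normal * radius * 0.85
                segs.append((mid - half, mid + half))
            seg_len_um = 2 * radius * 0.85 / 1000
            prims.append(StripeSet(segs, spacing, 3000.0 * seg_len_um * len(segs), 30.0))
    structure = {"cristae_spacing_nm": spacing} if with_cristae else {}
    return prims, structure


def _make_golgi(params, field_size, rng):
    n_stacks = int(params.pop("n_stacks", 6))
    n_cist = int(params.pop("n_cisternae", 4))
    spacing = float(params.pop("spacing_nm", 64.0))
    if spacing <= 0:
        raise GeometryError("golgi spacing_nm must be > 0")
    fw, fh = field_size
    prims = []
    for _ in range(n_stacks):
        length = rng.uniform(800, 1600)
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        normal = np.array([-d[1], d[0]])
        stack_depth = (n_cist - 1) * spacing
        margin = length / 2 + stack_depth + 500
        if 2 * margin >= min(fw, fh):
            raise GeometryError("golgi stack does not fit in the field of view")
        c = rng.uniform([margin, margin], [fw - margin, fh - margin])
        segs = []
        for k in range(n_cist):
            off = (k - (n_cist - 1) / 2) * spacing
            mid = c + normal * off
            segs.append((mid - d * length / 2, mid + d * length / 2))
        prims.append(StripeSet(segs, spacing, 3000.0 * (length / 1000) * n_cist, 25.0))
    return prims, {"spacing_nm": spacing}


def _make_centriole(params, field_size, rng):
    view = params.pop("view", "axial")
    fw, fh = field_size
    c = np.array([fw / 2, fh / 2])
    if view == "axial":
        ratio = float(params.pop("axis_ratio", 1.0))
        diameter = float(params.pop("diameter_nm", 250.0))
        if ratio <= 0:
            raise GeometryError("axis_ratio must be > 0")
        r = diameter / 2
        a, b = r * np.sqrt(ratio), r / np.sqrt(ratio)
        prim = Ellipse(c, (a, b), 0.0, 2000.0, ring_fraction=0.35)
        return [prim], {"axis_ratio": ratio}
    if view == "lateral":
        length = float(params.pop("length_nm", 450.0))
        width = float(params.pop("width_nm", 250.0))
        if length <= 0 or width <= 0:
            raise GeometryError("centriole length/width must be > 0")
        d = np.array([1.0, 0.0])
        normal = np.array([0.0, 1.0])
        # barrel: two side walls along the length, two end walls across
        walls = [
            (c - d * length / 2 - normal * width / 2, c + d * length / 2 - normal * width / 2),
            (c - d * length / 2 + normal * width / 2, c + d * length / 2 + normal * width / 2),
            (c - d * length / 2 - normal * width / 2, c - d * length / 2 + normal * width / 2),
            (c + d * length / 2 - normal * width / 2, c + d * length / 2 + normal * width / 2),
        ]
        prims = [Curve(np.array(w), 500.0, 40.0) for w in walls]
        return prims, {"length_nm": length, "width_nm": width,
                       "length_width_ratio": length / width}
    raise GeometryError(f"unknown centriole view {view!r}")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _splat_bilinear(shape: tuple[int, int], pts_px: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Deposit weighted points onto a grid; mass-conserving in the interior."""
    img = np.zeros(shape)
    x, y = pts_px[:, 0], pts_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dy in (0, 1):
        for dx in (0, 1):
            wx = fx if dx else 1 - fx
            wy = fy if dy else 1 - fy
            xi, yi = x0 + dx, y0 + dy
            ok = (xi >= 0) & (xi < shape[1]) & (yi >= 0) & (yi < shape[0])
            np.add.at(img, (yi[ok], xi[ok]), w[ok] * wx[ok] * wy[ok])
    return img


def _apply_noise(img: np.ndarray, imaging: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    if imaging.poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0) * imaging.poisson_scale) / imaging.poisson_scale
    if imaging.gaussian_read_noise_sd > 0:
        img = img + rng.normal(0, imaging.gaussian_read_noise_sd, img.shape)
    return np.maximum(img, 0.0)


def render(scene: PhantomScene, imaging: ImagingParams, seed: int = 0) -> RasterImage:
    """Rasterize a scene through the imaging model.

    Shot noise is applied before read noise; with all noise disabled the
    integrated intensity above background equals the scene's summed
    primitive intensity up to boundary truncation of the PSF tails.
    """
    fw, fh = scene.field_size_nm
    px = imaging.pixel_size_nm
    nx, ny = int(round(fw / px)), int(round(fh / px))
    if nx < 64 or ny < 64:
        raise ValueError(f"field/pixel size yields a {ny}x{nx} image; need >= 64x64")
    if imaging.psf_sigma_nm > max(fw, fh):
        raise ValueError("PSF sigma exceeds the image extent")
    pts, w = scene.sample_points(step_nm=px / 3)
    img = _splat_bilinear((ny, nx), pts / px, w)
    if imaging.psf_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, imaging.psf_sigma_nm / px, mode="constant")
    img = img * imaging.exposure_time_ms + imaging.background_level
    img = _apply_noise(img, imaging, substream(seed, "render-noise"))
    return RasterImage(img, px)


def deform_scene(
    scene: PhantomScene,
    spec: DeformationSpec,
    imaging_post: ImagingParams,
) -> tuple[RasterImage, DeformationField, GroundTruth]:
    """Expand the scene by the forward model and image it on the post grid.

    Returns the post-expansion image, the true residual field sampled on
    the pre grid (units: pre-image pixels at ``imaging_post.pixel_size_nm
    / spec.scale``-independent pre calibration of 100 nm/px is *not*
    assumed — the pre grid is the scene field at the pre pixel size used
    by :func:`render`, conventionally 100 nm/px), and the full ground
    truth.

    The residual field ``u`` lives in pre-expansion coordinates, so the
    distances measured after applying it to pre-frame points are directly
    comparable to pre-expansion structure sizes.
    """
    fw, fh = scene.field_size_nm
    s, M = spec.scale, spec.shear
    nonrigid = None
    if spec.nonrigid_amplitude_nm > 0:
        nonrigid = NonRigidField(
            scene.field_size_nm,
            spec.nonrigid_amplitude_nm,
            spec.nonrigid_correlation_length_nm,
            spec.seed,
        )

    def fwd(points):
        p = np.atleast_2d(points)
        if nonrigid is not None:
            p = p + nonrigid(p)
        return s * (p @ M.T)

    corners = np.array([[0, 0], [fw, 0], [0, fh], [fw, fh]], dtype=float)
    mapped = fwd(corners)
    margin = 3 * s * spec.nonrigid_amplitude_nm + 2 * imaging_post.pixel_size_nm
    lo = mapped.min(axis=0) - margin
    hi = mapped.max(axis=0) + margin
    offset = -lo
    px = imaging_post.pixel_size_nm
    nx, ny = int(np.ceil((hi[0] - lo[0]) / px)), int(np.ceil((hi[1] - lo[1]) / px))
    if nx < 64 or ny < 64:
        raise ValueError(f"post field/pixel size yields a {ny}x{nx} image; need >= 64x64")

    pre_step = px / (3 * s)  # sample finely enough for the post grid
    pts, w = scene.sample_points(step_nm=pre_step)
    post_pts = fwd(pts) + offset
    img = _splat_bilinear((ny, nx), post_pts / px, w)
    if imaging_post.psf_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, imaging_post.psf_sigma_nm / px, mode="constant")
    img = img * imaging_post.exposure_time_ms + imaging_post.background_level
    img = _apply_noise(img, imaging_post, substream(spec.seed, "deform-noise"))
    post = RasterImage(img, px)

    # residual field on the conventional pre grid (100 nm/px of the scene)
    pre_px = 100.0
    gnx, gny = int(round(fw / pre_px)), int(round(fh / pre_px))
    gx, gy = np.meshgrid(np.arange(gnx) * pre_px, np.arange(gny) * pre_px)
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
    if nonrigid is not None:
        u_nm = nonrigid(grid_pts).reshape(gny, gnx, 2)
    else:
        u_nm = np.zeros((gny, gnx, 2))
    field_px = DeformationField(u_nm / pre_px, pixel_size_nm=pre_px)

    mode = "outline" if scene.kind in ("nuclei", "centriole") else "skeleton"
    ref_nm = scene.reference_points_nm(step_nm=pre_px)
    true_points = PointSet(ref_nm / pre_px, provenance="ground_truth",
                           pixel_size_nm=pre_px)
    gt = GroundTruth(
        scale=s,
        shear=M,
        offset_nm=offset,
        nonrigid=nonrigid,
        true_points=true_points,
        true_spacings_nm=scene.structure.get("spacing_nm",
                                             scene.structure.get("cristae_spacing_nm")),
        true_axis_ratio=scene.structure.get("axis_ratio"),
        true_region_areas_um2=scene.structure.get("region_areas_um2"),
    )
    return post, field_px, gt


# --------------------------------------------------------------------------
# ground-truth distortion curves (registration-free loop closure)
# --------------------------------------------------------------------------

def true_residual_curve(
    gt: GroundTruth,
    max_length_um: float,
    bin_width_um: float = 0.5,
    max_pairs: int | None = 2_000_000,
    seed: int = 0,
) -> RmsCurve:
    """Distortion curve of the *imposed* residual field at the true points.

    Feeds the exact residual displacement (no registration involved)
    through the same pair-distance statistic as the measurement
    pipeline; the analytic reference every estimated curve is judged
    against.
    """
    pts = gt.true_points
    p_nm = pts.coords_px * pts.pixel_size_nm
    disp_nm = p_nm + gt.residual_nm(p_nm)
    displaced = PointSet(disp_nm / pts.pixel_size_nm, "ground_truth",
                         pts.pixel_size_nm)
    return rms_vs_length(pts, displaced, max_length_um,
                         bin_width_um=bin_width_um, max_pairs=max_pairs,
                         seed=seed)


def amplitude_for_relative_error(
    scene: PhantomScene,
    target_relative: float,
    at_length_um: float,
    correlation_length_nm: float = 5000.0,
    seed: int = 0,
    max_pairs: int | None = 500_000,
) -> float:
    """RMS amplitude (nm) giving a target relative error at a length.

    The pair-distance error is almost exactly linear in the field
    amplitude for the small distortions of interest, so a probe field of
    unit-scaled amplitude is measured at the requested length and scaled;
    one fixed-point refinement absorbs the residual nonlinearity.
    """
    ref = scene.reference_points_nm(step_nm=100.0)
    pts = PointSet(ref / 100.0, "ground_truth", 100.0)
    amp = 100.0  # probe amplitude, nm
    for _ in range(2):
        fld = NonRigidField(scene.field_size_nm, amp, correlation_length_nm, seed)
        p_nm = pts.coords_px * pts.pixel_size_nm
        displaced = PointSet((p_nm + fld(p_nm)) / 100.0, "ground_truth", 100.0)
        curve = rms_vs_length(pts, displaced, at_length_um + 1.0,
                              bin_width_um=1.0, max_pairs=max_pairs, seed=seed)
        idx = int(np.argmin(np.abs(curve.bin_centers_um - at_length_um)))
        rel = curve.relative_error[idx]
        amp *= target_relative / rel
    return float(amp)
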