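"""Linear and B-spline non-rigid registration of expansion image pairs.

The distortion workflow registers a post-expansion image to its
pre-expansion counterpart in two stages:

1. a global *similarity* (uniform scale, rotation, translation) or
   *affine* (adds shear/anisotropic scale) transform, found
   automatically by log-polar phase correlation followed by direct
   sum-of-squared-differences (SSD) refinement;
2. a cubic B-spline free-form deformation of the similarity/affine-
   registered image, optimized under SSD plus a bending-energy penalty,
   coarse-to-fine over the control lattice. Its dense displacement
   field is the residual expansion inhomogeneity.

Everything is deterministic: no stochastic metric sampling is used.

Transforms map pre-image physical coordinates (nm) to post-image
physical coordinates (nm); the displacement field is expressed in
pre-image pixels on the pre grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import window
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .image import RasterImage


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Knobs of both registration stages.

    ``penalty_weight`` multiplies a normalized bending energy (mean
    squared second difference of the control lattice, per control
    point) against a per-pixel mean squared intensity difference; its
    absolute value is therefore specific to this parameterization.
    """

    penalty_weight: float = 1e-3
    pyramid_levels: int = 3
    grid_spacing_px: float = 16.0
    max_iterations: int = 300
    convergence_tol: float = 1e-9
    linear_blur_px: float = 3.0

    def __post_init__(self) -> None:
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class TransformModel:
    """Linear map y = A x + t from pre-frame nm to post-frame nm."""

    kind: str  # "similarity" | "affine"
    matrix: np.ndarray  # 2x2
    translation_nm: np.ndarray  # (2,)
    final_ssd: float = np.nan
    converged: bool = True

    @property
    def scale(self) -> float:
        """Linear expansion factor: sqrt(|det A|)."""
        return float(np.sqrt(abs(np.linalg.det(self.matrix))))

    @property
    def rotation_rad(self) -> float:
        a = self.matrix / self.scale
        return float(np.arctan2(a[1, 0], a[0, 0]))

    def apply(self, points_nm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_nm, dtype=float))
        return p @ self.matrix.T + self.translation_nm

    def inverse(self) -> "TransformModel":
        inv = np.linalg.inv(self.matrix)
        return TransformModel(self.kind, inv, -inv @ self.translation_nm)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation_nm": self.translation_nm.tolist(),
            "scale": self.scale,
            "rotation_rad": self.rotation_rad,
            "final_ssd": self.final_ssd,
            "converged": self.converged,
        }


@dataclass
class BSplineModel:
    """Cubic B-spline free-form deformation on the pre-image grid."""

    control: np.ndarray  # (2, gy, gx): x- and y-displacement coefficients, px
    grid_spacing_px: float
    image_shape: tuple[int, int]


@dataclass
class DeformationField:
    """Dense residual displacement u(p), pre-image pixels, on the pre grid.

    ``u[..., 0]`` is the x (column) component, ``u[..., 1]`` the y (row)
    component.
    """

    u: np.ndarray  # (H, W, 2)
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError("deformation field must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("deformation field must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.u**2, axis=-1))

    def rms_px(self, mask: np.ndarray | None = None) -> float:
        m2 = np.sum(self.u**2, axis=-1)
        if mask is not None:
            m2 = m2[mask]
        return float(np.sqrt(np.mean(m2)))


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(
    image: RasterImage,
    blur_sigma_px: float = 0.0,
    despeckle: bool = False,
    project: bool = False,
    mask: np.ndarray | None = None,
) -> RasterImage:
    """Maximum-project, despeckle (3x3 median), blur and mask an image.

    The order matches the conventional workflow: projection of the stack
    first, then median despeckling, then Gaussian smoothing; pixels
    outside the mask are zeroed and the mask is carried on the result
    for downstream metrics to ignore.
    """
    data = image.data
    if project:
        if data.ndim != 3:
            raise ValueError("project=True requires a 3D stack")
        data = data.max(axis=0)
    elif data.ndim == 3:
        raise ValueError("got a stack; pass project=True to max-project it")
    if despeckle:
        data = ndimage.median_filter(data, size=3)
    if blur_sigma_px > 0:
        data = ndimage.gaussian_filter(data, blur_sigma_px)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {data.shape}")
        data = np.where(mask, data, 0.0)
    return RasterImage(data, image.pixel_size_nm, channel_label=image.channel_label,
                       mask=mask)


def _normalize(data: np.ndarray) -> np.ndarray:
    """Background-subtract (median) and scale to robust unit amplitude."""
    a = data - np.median(data)
    a = np.maximum(a, 0.0)
    top = np.percentile(a, 99.9)
    if top <= 0:
        raise RegistrationError("image is featureless after background subtraction")
    return a / top


# --------------------------------------------------------------------------
# linear registration
# --------------------------------------------------------------------------

def _logpolar_scale_rotation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Residual (scale, rotation) of b relative to a from FFT magnitudes."""
    shape = a.shape
    wa = a * window("hann", shape)
    wb = b * window("hann", shape)
    fa = np.abs(np.fft.fftshift(np.fft.fft2(wa)))
    fb = np.abs(np.fft.fftshift(np.fft.fft2(wb)))
    radius = min(shape) // 4  # low-frequency half of the spectrum
    pa = warp_polar(fa, radius=radius, scaling="log", order=1)
    pb = warp_polar(fb, radius=radius, scaling="log", order=1)
    pa, pb = pa[: pa.shape[0] // 2], pb[: pb.shape[0] // 2]  # spectrum symmetry
    shifts, _, _ = phase_cross_correlation(pa, pb, upsample_factor=20,
                                           normalization=None)
    angle = np.deg2rad(shifts[0] * 360.0 / fa.shape[0])
    klog = radius / np.log(radius)
    scale = float(np.exp(shifts[1] / klog))
    return 1.0 / scale, -angle  # b -> a convention flip: map pre px -> work px


def _warp_linear(work: np.ndarray, B: np.ndarray, c: np.ndarray,
                 out_shape: tuple[int, int], order: int = 1) -> np.ndarray:
    yy, xx = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    px = B[0, 0] * xx + B[0, 1] * yy + c[0]
    py = B[1, 0] * xx + B[1, 1] * yy + c[1]
    return ndimage.map_coordinates(work, [py, px], order=order, cval=0.0)


def fit_linear(
    pre: RasterImage,
    post: RasterImage,
    kind: str = "similarity",
    config: RegistrationConfig | None = None,
) -> TransformModel:
    """Fit the global linear transform minimizing SSD between the images.

    Initialization is automatic: the physical-extent ratio seeds the
    scale (the two images are assumed to show the same field of view),
    log-polar phase correlation of the magnitude spectra refines scale
    and rotation, translation comes from phase correlation, and a
    Powell search over the transform parameters polishes the SSD,
    coarse-to-fine.
    """
    if kind not in ("similarity", "affine"):
        raise ValueError(f"kind must be 'similarity' or 'affine', got {kind!r}")
    config = config or RegistrationConfig()
    a = _normalize(pre.data)
    b = _normalize(post.data)
    # resample post onto a pre-shaped working grid by a strictly isotropic
    # zoom (otherwise an anisotropic post bounding box would leak shear
    # into the similarity model through the grid geometry)
    z0 = max(post.data.shape[0] / pre.data.shape[0],
             post.data.shape[1] / pre.data.shape[1])
    yy, xx = np.mgrid[0 : a.shape[0], 0 : a.shape[1]]
    work = ndimage.map_coordinates(b, [yy * z0, xx * z0], order=1)

    s0, th0 = _logpolar_scale_rotation(a, work)
    c0 = np.array([(a.shape[1] - 1) / 2, (a.shape[0] - 1) / 2])

    def params_to_Bc(theta):
        if kind == "similarity" or len(theta) == 4:
            ls, ang, tx, ty = theta
            s = np.exp(ls)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            B = s * R
            t = np.array([tx, ty])
        else:
            B = np.array([[theta[0], theta[1]], [theta[2], theta[3]]])
            t = np.array([theta[4], theta[5]])
        c = c0 - B @ c0 + t
        return B, c

    # translation init: undo scale/rotation then phase-correlate
    B_init, c_init = params_to_Bc([np.log(s0), th0, 0.0, 0.0])
    unrot = _warp_linear(work, B_init, c_init, a.shape)
    shift, _, _ = phase_cross_correlation(
        ndimage.gaussian_filter(a, 2), ndimage.gaussian_filter(unrot, 2),
        upsample_factor=10, normalization=None)
    # a(p) ~ unrot(p - shift): work sampled at B(p - shift) + c
    t0 = -(B_init @ np.array([shift[1], shift[0]]))

    if kind == "similarity":
        theta = np.array([np.log(s0), th0, t0[0], t0[1]])
    else:
        B0 = np.exp(np.log(s0)) * np.array(
            [[np.cos(th0), -np.sin(th0)], [np.sin(th0), np.cos(th0)]]
        )
        theta = np.array([B0[0, 0], B0[0, 1], B0[1, 0], B0[1, 1], t0[0], t0[1]])

    # the linear stage runs on moderately smoothed images: the global
    # transform lives at blob scale, and thin structures (2 px filaments)
    # give SSD landscapes with spurious partial-overlap minima when sharp
    if config.linear_blur_px > 0:
        a_s = ndimage.gaussian_filter(a, config.linear_blur_px)
        w_s = ndimage.gaussian_filter(work, config.linear_blur_px)
    else:
        a_s, w_s = a, work

    levels = list(range(config.pyramid_levels - 1, -1, -1))
    # capture range shrinks with refinement; the spectral/phase-correlation
    # initialization is good to a few percent, so even the coarsest level
    # only needs a moderate search radius (wide radii let sparse scenes
    # wander into partial-overlap minima)
    widths = np.geomspace(0.08, 0.02, num=len(levels))
    t_spans = np.geomspace(0.15, 0.02, num=len(levels))

    for i, level in enumerate(levels):
        f = 2**level
        if f > 1:
            # anti-alias before decimation
            a_l = ndimage.zoom(ndimage.gaussian_filter(a_s, f / 2), 1 / f, order=1)
            w_l = ndimage.zoom(ndimage.gaussian_filter(w_s, f / 2), 1 / f, order=1)
        else:
            a_l, w_l = a_s, w_s
        scale_t = 1.0 / f

        def ssd(theta_l, a_l=a_l, w_l=w_l, scale_t=scale_t, f=f):
            th = theta_l.copy()
            if kind == "similarity":
                th_full = np.array([th[0], th[1], th[2] / scale_t, th[3] / scale_t])
            else:
                th_full = np.concatenate([th[:4], th[4:] / scale_t])
            B, c = params_to_Bc(th_full)
            # rescale mapping to level grid: p_full = f * p_level
            warped = _warp_linear(w_l, B, c / f, a_l.shape)
            return float(np.mean((warped - a_l) ** 2))

        if kind == "similarity":
            theta_l = np.array([theta[0], theta[1], theta[2] * scale_t, theta[3] * scale_t])
        else:
            theta_l = np.concatenate([theta[:4], theta[4:] * scale_t])
        w_lin, t_span = widths[i], t_spans[i] * max(a_l.shape)
        if kind == "similarity":
            bounds = [(theta_l[0] - w_lin, theta_l[0] + w_lin),
                      (theta_l[1] - w_lin, theta_l[1] + w_lin),
                      (theta_l[2] - t_span, theta_l[2] + t_span),
                      (theta_l[3] - t_span, theta_l[3] + t_span)]
        else:
            bounds = [(v - w_lin, v + w_lin) for v in theta_l[:4]] + [
                (theta_l[4] - t_span, theta_l[4] + t_span),
                (theta_l[5] - t_span, theta_l[5] + t_span)]
        res = optimize.minimize(
            ssd, theta_l, method="Powell", bounds=bounds,
            options={"maxiter": config.max_iterations, "xtol": 1e-6, "ftol": 1e-10},
        )
        if kind == "similarity":
            theta = np.array([res.x[0], res.x[1], res.x[2] / scale_t, res.x[3] / scale_t])
        else:
            theta = np.concatenate([res.x[:4], res.x[4:] / scale_t])

    B, c = params_to_Bc(theta)
    final = float(np.mean((_warp_linear(work, B, c, a.shape) - a) ** 2))
    # compose physical transform: pre px p -> work px (Bp + c) -> post px -> nm
    ppre, ppost = pre.pixel_size_nm, post.pixel_size_nm
    A_phys = (ppost / ppre) * z0 * B
    t_phys = ppost * z0 * c
    return TransformModel(kind, A_phys, t_phys, final_ssd=final,
                          converged=bool(res.success))


def resample(
    image: RasterImage,
    transform: TransformModel,
    out_shape: tuple[int, int],
    out_pixel_size_nm: float,
    order: int = 1,
) -> RasterImage:
    """Pull ``image`` intensities onto an output grid through ``transform``.

    ``transform`` maps output-frame physical coordinates to ``image``
    physical coordinates (so registering post to pre passes the fitted
    pre->post transform directly). Out-of-domain pixels are filled
    with 0.
    """
    yy, xx = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()]) * out_pixel_size_nm
    src = transform.apply(pts) / image.pixel_size_nm
    out = ndimage.map_coordinates(
        image.data, [src[:, 1].reshape(out_shape), src[:, 0].reshape(out_shape)],
        order=order, cval=0.0,
    )
    return RasterImage(out, out_pixel_size_nm, channel_label=image.channel_label)


# --------------------------------------------------------------------------
# B-spline free-form deformation
# --------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6
    out[m2] = (2 - at[m2]) ** 3 / 6
    return out


def _basis_matrix(n: int, h: float) -> np.ndarray:
    """(n x g) cubic B-spline evaluation matrix for nodes at j*h, j0=-2."""
    j0 = -2
    j1 = int(np.ceil((n - 1) / h)) + 2
    j = np.arange(j0, j1 + 1)
    i = np.arange(n)
    return _bspline3(i[:, None] / h - j[None, :])


def _bending_energy_grad(C: np.ndarray) -> tuple[float, np.ndarray]:
    """Thin-plate-like bending on the control lattice, with gradient."""
    e = 0.0
    g = np.zeros_like(C)
    dxx = C[:, :, 2:] - 2 * C[:, :, 1:-1] + C[:, :, :-2]
    e += np.sum(dxx**2)
    g[:, :, 2:] += 2 * dxx
    g[:, :, 1:-1] += -4 * dxx
    g[:, :, :-2] += 2 * dxx
    dyy = C[:, 2:, :] - 2 * C[:, 1:-1, :] + C[:, :-2, :]
    e += np.sum(dyy**2)
    g[:, 2:, :] += 2 * dyy
    g[:, 1:-1, :] += -4 * dyy
    g[:, :-2, :] += 2 * dyy
    dxy = C[:, 1:, 1:] - C[:, 1:, :-1] - C[:, :-1, 1:] + C[:, :-1, :-1]
    e += 2 * np.sum(dxy**2)
    g[:, 1:, 1:] += 4 * dxy
    g[:, 1:, :-1] += -4 * dxy
    g[:, :-1, 1:] += -4 * dxy
    g[:, :-1, :-1] += 4 * dxy
    n = C[0].size
    return e / n, g / n


def fit_bspline(
    pre: RasterImage,
    post_registered: RasterImage,
    config: RegistrationConfig | None = None,
) -> tuple[BSplineModel, DeformationField]:
    """Non-rigid residual registration of the linearly registered pair.

    Both images must live on the same (pre) grid. The displacement of a
    cubic B-spline control lattice is optimized by L-BFGS-B under

        mean (post(p + u(p)) - pre(p))^2  +  penalty_weight * bending(u)

    coarse-to-fine over lattice spacings (4h, 2h, h). Returns the lattice
    model and the dense field u on the pre grid (pre-image pixels).
    """
    config = config or RegistrationConfig()
    if pre.data.shape != post_registered.data.shape:
        raise ValueError("pre and post_registered must share the same grid")
    a = _normalize(pre.data)
    b = _normalize(post_registered.data)
    H, W = a.shape
    mask = pre.mask if pre.mask is not None else post_registered.mask
    weight = np.ones_like(a) if mask is None else mask.astype(float)
    npx_eff = float(weight.sum())
    if npx_eff == 0:
        raise RegistrationError("empty mask")
    gx_img, gy_img = np.gradient(b, axis=1), np.gradient(b, axis=0)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    spacings = [config.grid_spacing_px * 2**lvl
                for lvl in range(config.pyramid_levels - 1, -1, -1)]
    C = None
    prev_Bx = prev_By = None
    for h in spacings:
        Bx = _basis_matrix(W, h)
        By = _basis_matrix(H, h)
        gxn, gyn = Bx.shape[1], By.shape[1]
        if C is None:
            C = np.zeros((2, gyn, gxn))
        else:
            # initialize from the previous level's dense field by projecting
            # it onto the new basis (normal equations, small and well posed)
            ux = prev_By @ C[0] @ prev_Bx.T
            uy = prev_By @ C[1] @ prev_Bx.T
            C = np.stack([_project_to_basis(ux, By, Bx),
                          _project_to_basis(uy, By, Bx)])

        def objective(theta, Bx=Bx, By=By, gyn=gyn, gxn=gxn):
            Cl = theta.reshape(2, gyn, gxn)
            ux = By @ Cl[0] @ Bx.T
            uy = By @ Cl[1] @ Bx.T
            px, py = xx + ux, yy + uy
            warped = ndimage.map_coordinates(b, [py, px], order=1, cval=0.0)
            r = (warped - a) * weight
            e_data = float(np.sum(r**2)) / npx_eff
            gxs = ndimage.map_coordinates(gx_img, [py, px], order=1, cval=0.0)
            gys = ndimage.map_coordinates(gy_img, [py, px], order=1, cval=0.0)
            dx = 2 * r * gxs / npx_eff
            dy = 2 * r * gys / npx_eff
            gC = np.stack([By.T @ dx @ Bx, By.T @ dy @ Bx])
            e_bend, g_bend = _bending_energy_grad(Cl)
            e = e_data + config.penalty_weight * e_bend
            g = gC + config.penalty_weight * g_bend
            return e, g.ravel()

        # coarse lattices have few parameters; spend most iterations on the
        # finest level
        iters = config.max_iterations if h == spacings[-1] else max(
            config.max_iterations // 3, 20)
        res = optimize.minimize(
            objective, C.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": iters,
                     "ftol": config.convergence_tol, "gtol": 1e-12},
        )
        C = res.x.reshape(2, By.shape[1], Bx.shape[1])
        prev_Bx, prev_By = Bx, By

    ux = prev_By @ C[0] @ prev_Bx.T
    uy = prev_By @ C[1] @ prev_Bx.T
    field = DeformationField(np.stack([ux, uy], axis=-1), pre.pixel_size_nm)
    model = BSplineModel(C, spacings[-1], (H, W))
    return model, field


def _project_to_basis(u: np.ndarray, By: np.ndarray, Bx: np.ndarray) -> np.ndarray:
    """Least-squares B-spline coefficients reproducing a dense field."""
    Gy = By.T @ By + 1e-9 * np.eye(By.shape[1])
    Gx = Bx.T @ Bx + 1e-9 * np.eye(Bx.shape[1])
    return np.linalg.solve(Gy, By.T @ u @ Bx) @ np.linalg.inv(Gx)
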