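"""Registration: preprocessing, linear fits, resampling, B-spline FFD."""

import numpy as np
import pytest
from scipy import ndimage

from exmetric import (
    DeformationSpec,
    ImagingParams,
    RasterImage,
    RegistrationConfig,
    deform_scene,
    fit_bspline,
    fit_linear,
    make_scene,
    preprocess,
    render,
    resample,
)

from conftest import SMALL_FIELD, make_pair


class TestPreprocess:
    def test_constant_image_unchanged_by_blur(self):
        img = RasterImage(np.full((64, 64), 7.0), 100.0)
        out = preprocess(img, blur_sigma_px=3.0)
        np.testing.assert_allclose(out.data, 7.0)

    def test_despeckle_removes_single_pixel_impulse(self):
        data = np.zeros((64, 64))
        data[30, 30] = 100.0
        out = preprocess(RasterImage(data, 100.0), despeckle=True)
        assert out.data.max() < 100.0

    def test_projection_takes_per_pixel_max(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 1, (3, 32, 32))
        out = preprocess(RasterImage(stack, 100.0), project=True)
        np.testing.assert_array_equal(out.data, stack.max(axis=0))

    def test_mask_shape_mismatch_rejected(self):
        img = RasterImage(np.zeros((32, 32)), 100.0)
        with pytest.raises(ValueError, match="mask shape"):
            preprocess(img, mask=np.ones((16, 16), dtype=bool))


@pytest.fixture(scope="module")
def pre_small(nuclei_scene, imaging_clean):
    return render(nuclei_scene, imaging_clean, seed=0)


class TestFitLinear:
    def test_self_registration_is_identity(self, pre_small):
        t = fit_linear(pre_small, pre_small, "similarity")
        assert t.scale == pytest.approx(1.0, abs=0.01)
        assert np.linalg.norm(t.translation_nm) / 100.0 < 0.5  # px

    def test_scale_recovery_across_factors(self, nuclei_scene):
        """Noise-free phantoms: relative scale error < 1% for s in {2, 4, 8}."""
        for s in (2.0, 4.0, 8.0):
            pre, post, _, _ = make_pair(nuclei_scene, scale=s)
            t = fit_linear(pre, post, "similarity")
            assert t.scale == pytest.approx(s, rel=0.01), f"s={s}"

    def test_affine_recovers_shear_similarity_cannot(self, nuclei_scene):
        M = np.diag([1.03, 1 / 1.03])
        pre, post, _, _ = make_pair(nuclei_scene, scale=4.0, shear=M)
        aff = fit_linear(pre, post, "affine")
        rec = aff.matrix / 4.0
        np.testing.assert_allclose(rec, M, atol=0.005 * 1.03)
        sim = fit_linear(pre, post, "similarity")
        anis = sim.matrix / sim.scale
        # similarity stays isotropic: it cannot represent the anisotropy
        assert abs(anis[0, 0] - anis[1, 1]) < 0.005
        assert aff.final_ssd < sim.final_ssd

    def test_translation_equivariance(self, nuclei_scene, imaging_clean):
        """Shifting both images by the same offset leaves scale unchanged."""
        pre, post, _, _ = make_pair(nuclei_scene, scale=2.0)
        t0 = fit_linear(pre, post, "similarity")
        sh_pre = RasterImage(np.roll(pre.data, (9, 9), axis=(0, 1)),
                             pre.pixel_size_nm)
        sh_post = RasterImage(np.roll(post.data, (9, 9), axis=(0, 1)),
                              post.pixel_size_nm)
        t1 = fit_linear(sh_pre, sh_post, "similarity")
        assert t1.scale == pytest.approx(t0.scale, rel=0.005)
        assert t1.rotation_rad == pytest.approx(t0.rotation_rad, abs=0.005)

    def test_featureless_image_rejected(self):
        flat = RasterImage(np.full((128, 128), 3.0), 100.0)
        with pytest.raises(Exception, match="featureless"):
            fit_linear(flat, flat, "similarity")


class TestResample:
    def test_identity_reproduces_input(self, pre_small):
        from exmetric.registration import TransformModel

        ident = TransformModel("similarity", np.eye(2), np.zeros(2))
        out = resample(pre_small, ident, pre_small.data.shape,
                       pre_small.pixel_size_nm, order=1)
        np.testing.assert_allclose(out.data, pre_small.data, atol=1e-9)

    def test_integer_translation_shifts_with_zero_fill(self, pre_small):
        from exmetric.registration import TransformModel

        t = TransformModel("similarity", np.eye(2),
                           np.array([300.0, 0.0]))  # +3 px in x
        out = resample(pre_small, t, pre_small.data.shape,
                       pre_small.pixel_size_nm, order=1)
        np.testing.assert_allclose(out.data[:, :-3], pre_small.data[:, 3:],
                                   atol=1e-9)
        np.testing.assert_allclose(out.data[:, -3:], 0.0)

    def test_round_trip_psnr(self, pre_small):
        from exmetric.registration import TransformModel

        c, s = np.cos(0.1), np.sin(0.1)
        t = TransformModel("similarity",
                           1.1 * np.array([[c, -s], [s, c]]),
                           np.array([500.0, -300.0]))
        once = resample(pre_small, t, pre_small.data.shape,
                        pre_small.pixel_size_nm, order=3)
        back = resample(once, t.inverse(), pre_small.data.shape,
                        pre_small.pixel_size_nm, order=3)
        interior = (slice(40, -40), slice(40, -40))
        err = back.data[interior] - pre_small.data[interior]
        psnr = 10 * np.log10(pre_small.data.max() ** 2 / np.mean(err**2))
        assert psnr > 40.0

    def test_agrees_with_simpleitk_resampler(self, pre_small):
        """Independent cross-check of the coordinate convention."""
        sitk = pytest.importorskip("SimpleITK")
        from exmetric.registration import TransformModel

        c, s = np.cos(0.05), np.sin(0.05)
        A = 1.2 * np.array([[c, -s], [s, c]])
        t_nm = np.array([400.0, -250.0])
        ours = resample(pre_small, TransformModel("similarity", A, t_nm),
                        pre_small.data.shape, pre_small.pixel_size_nm, order=1)
        img = sitk.GetImageFromArray(pre_small.data)
        img.SetSpacing((pre_small.pixel_size_nm,) * 2)
        tr = sitk.AffineTransform(2)
        tr.SetMatrix(A.ravel())
        tr.SetTranslation(t_nm)
        out = sitk.Resample(img, img, tr, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(out)
        # compare only pixels whose source lands strictly inside the image
        # (the two implementations fill out-of-domain pixels differently)
        H, W = pre_small.data.shape
        yy, xx = np.mgrid[0:H, 0:W]
        src = (np.column_stack([xx.ravel(), yy.ravel()])
               * pre_small.pixel_size_nm) @ A.T + t_nm
        src /= pre_small.pixel_size_nm
        inside = ((src[:, 0] > 1) & (src[:, 0] < W - 2)
                  & (src[:, 1] > 1) & (src[:, 1] < H - 2)).reshape(H, W)
        np.testing.assert_allclose(ours.data[inside], theirs[inside],
                                   atol=1e-6 * pre_small.data.max())


class TestFitBspline:
    def test_identical_inputs_give_null_field(self, pre_small):
        _, field = fit_bspline(pre_small, pre_small)
        assert field.rms_px() < 0.1

    def test_recovers_imposed_sinusoidal_field_amplitude(self, imaging_clean):
        # textured support: a filament network carries gradient information
        # everywhere, unlike flat blob interiors
        scene = make_scene("filaments", {"n": 30, "field_size_nm": SMALL_FIELD},
                           seed=4)
        pre = render(scene, imaging_clean, seed=0)
        a = pre.data
        H, W = a.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        amp, wavelength = 3.0, 100.0
        ux = amp * np.sin(2 * np.pi * xx / wavelength)
        uy = amp * np.cos(2 * np.pi * yy / wavelength)
        warped = ndimage.map_coordinates(a, [yy - uy, xx - ux], order=3)
        post = RasterImage(warped, pre.pixel_size_nm)
        cfg = RegistrationConfig(penalty_weight=1e-4)
        _, field = fit_bspline(pre, post, cfg)
        support = a > np.percentile(a, 95)
        true = np.stack([ux, uy], axis=-1)[support]
        rms_true = float(np.sqrt(np.mean(np.sum(true**2, -1))))
        rms_rec = float(np.sqrt(np.mean(np.sum(field.u[support] ** 2, -1))))
        assert rms_rec == pytest.approx(rms_true, rel=0.25)

    def test_field_shrinks_monotonically_with_penalty(self, pre_small):
        a = pre_small.data
        H, W = a.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        ux = 2.0 * np.sin(2 * np.pi * xx / 120.0)
        warped = ndimage.map_coordinates(a, [yy, xx - ux], order=3)
        post = RasterImage(warped, pre_small.pixel_size_nm)
        rms = []
        for pen in (1e-4, 1e-2, 1e0, 1e2):
            cfg = RegistrationConfig(penalty_weight=pen, max_iterations=80)
            _, field = fit_bspline(pre_small, post, cfg)
            rms.append(field.rms_px())
        assert all(a >= b for a, b in zip(rms, rms[1:])), rms
        assert rms[-1] < 0.05  # huge penalty drives the field to zero

    def test_mismatched_grids_rejected(self, pre_small):
        other = RasterImage(np.zeros((16, 16)), 100.0)
        with pytest.raises(ValueError, match="same grid"):
            fit_bspline(pre_small, other)
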