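"""Shared fixtures: small phantom scenes and rendered image pairs.

Everything is generated programmatically and seeded; module-scoped
fixtures keep the expensive renders shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from exmetric import (
    DeformationSpec,
    ImagingParams,
    deform_scene,
    make_scene,
    render,
)

SMALL_FIELD = (25_600.0, 25_600.0)  # 256 px at 100 nm/px


@pytest.fixture(scope="session")
def imaging_clean() -> ImagingParams:
    """Noise-free acquisition (deterministic intensities)."""
    return ImagingParams(poisson_scale=0.0, gaussian_read_noise_sd=0.0,
                         background_level=5.0)


@pytest.fixture(scope="session")
def nuclei_scene():
    return make_scene("nuclei", {"n": 3, "radius_um": 2.5, "radius_sd_um": 0.3,
                                 "field_size_nm": SMALL_FIELD}, seed=11)


@pytest.fixture(scope="session")
def nuclei_pre(nuclei_scene, imaging_clean):
    return render(nuclei_scene, imaging_clean, seed=0)


def make_pair(scene, scale, shear=None, amplitude_nm=0.0,
              correlation_nm=10_000.0, seed=2, noisy=False,
              pre_pixel_nm=100.0):
    """Render a pre/post pair under the standard acquisition model."""
    if noisy:
        pre_imaging = ImagingParams(pixel_size_nm=pre_pixel_nm)
        post_imaging = ImagingParams(pixel_size_nm=pre_pixel_nm * scale,
                                     psf_sigma_nm=120.0 * scale)
    else:
        pre_imaging = ImagingParams(pixel_size_nm=pre_pixel_nm, poisson_scale=0,
                                    gaussian_read_noise_sd=0)
        post_imaging = ImagingParams(pixel_size_nm=pre_pixel_nm * scale,
                                     psf_sigma_nm=120.0 * scale, poisson_scale=0,
                                     gaussian_read_noise_sd=0)
    pre = render(scene, pre_imaging, seed=0)
    spec = DeformationSpec(
        scale=scale,
        shear=np.eye(2) if shear is None else shear,
        nonrigid_amplitude_nm=amplitude_nm,
        nonrigid_correlation_length_nm=correlation_nm,
        seed=seed,
    )
    post, field, gt = deform_scene(scene, spec, post_imaging)
    return pre, post, field, gt
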