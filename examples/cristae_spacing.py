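"""Measure mitochondrial cristae spacing from a post-expansion image.

Renders a single mitochondrion with cristae at a known 85 nm spacing,
expanded 14.3-fold, draws a thick line profile along the organelle axis
and reads consecutive peak-to-peak distances, corrected back to
biological units by the expansion factor.
"""

import numpy as np

from exmetric import (
    DeformationSpec,
    ImagingParams,
    deform_scene,
    make_scene,
    peak_spacing,
    thick_line_profile,
)

factor = 14.3
scene = make_scene("mitochondria",
                   {"n": 1, "with_cristae": True, "cristae_spacing_nm": 85.0,
                    "field_size_nm": (8000.0, 8000.0)}, seed=2)
post, _, gt = deform_scene(
    scene, DeformationSpec(scale=factor, seed=0),
    ImagingParams(pixel_size_nm=120.0, psf_sigma_nm=120.0,
                  poisson_scale=0, gaussian_read_noise_sd=0))

capsule = scene.primitives[0]
p0 = gt.map_points(np.asarray(capsule.p0_nm))[0] / post.pixel_size_nm
p1 = gt.map_points(np.asarray(capsule.p1_nm))[0] / post.pixel_size_nm
profile = thick_line_profile(post, p0, p1, thickness_px=11)
result = peak_spacing(profile, expansion_factor=factor)

s = result.summary
print(f"cristae spacings (expansion-corrected): "
      f"mean {s['mean']:.1f} nm, sd {s['sd']:.1f} nm, "
      f"median {s['median']:.1f} nm, n={s['n']}")
print(f"ground truth: 85.0 nm — the profile reads the imposed ultra-"
      f"structural spacing back out of the rendered image.")
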