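# Methods

This note documents the models, defaults and numerical choices behind
`exmetric`, and what its phantom-based validation does and does not
demonstrate about real data.

## Coordinate and unit conventions

Pixel indices are 0-based with pixel centers at integer coordinates;
`x` is the column (rightward), `y` the row (downward); physical
position = index × `pixel_size_nm`. Transforms map pre-image physical
coordinates (nm) to post-image physical coordinates (nm). Deformation
fields live on the pre-image grid in pre-image pixels. Distortion
curves are expressed on the pre-expansion (biological) length scale, in
µm, so "3% of the measurement length" refers to biological distances.

## Phantom simulator

Scenes are vector geometry, never rasters: ellipses (nuclei, centriole
annuli), polylines with width (filaments, barrel walls), capsules
(mitochondria) and exactly spaced parallel stripe families (cristae,
Golgi cisternae). Rendering samples each primitive into weighted points
(weights summing to the primitive's intensity), splats them bilinearly
onto the grid, convolves with a unit-mass Gaussian PSF, scales by the
exposure time, adds the background offset, then applies Poisson noise
(shot) followed by additive Gaussian noise (read) — in that order,
because photon statistics precede the detector. With noise disabled,
integrated intensity above background equals the scene's summed
intensity up to PSF truncation at the border.

Deformation acts on the continuous coordinates of the primitive
samples, never on pixels:

    x  ↦  s · M · (x + u(x))

with linear factor `s`, unimodular anisotropy matrix `M` (det = 1, so
`s` is identifiable), and a smooth stationary random field `u`
expressed in pre-expansion coordinates so that its RMS magnitude (the
`nonrigid_amplitude_nm` parameter) is directly the residual distortion
a registration pipeline should recover. `u` is synthesized from white
noise on a 128² grid by a hard isotropic spectral cutoff at wavenumber
2π/`correlation_length`, rescaled to the target RMS over the nominal
field, and evaluated continuously through cubic spline interpolation.
Ground truth therefore includes the exact coordinate map, the true
outline/centerline point set, and every structural parameter.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| pre pixel size | 100 nm/px | typical confocal sampling; 512² ≈ 51 µm field |
| post pixel size | `s` × 100 nm/px | both acquisitions frame the same field of view, so the expanded scene fills a same-sized image |
| PSF sigma | 120 nm (pre); `s`·120 nm (post) | ~280 nm FWHM confocal lateral resolution; the post value keeps matched optics relative to the magnified structure |
| background / shot / read | 10 counts; 1 photon per count; sd 2 | moderate-SNR confocal frame |
| non-rigid correlation length | 10 µm | gel swelling gradients and mounting strain vary smoothly at the field-of-view scale; this yields the flat few-percent relative-error curves the method is designed to measure, and is resolvable by the default B-spline lattice (16 px ≪ 100 px) |
| structure intensities | nuclei 12 000/µm², mitochondria 8 000/µm², filaments 1 500/µm, stripes 3 000/µm | peak signals of ~40–150 counts over background, i.e. realistic stain contrast |

The amplitude needed for a target relative error at a given length
(`amplitude_for_relative_error`) exploits that the pair-distance error
is nearly linear in the field amplitude: a probe field is measured at
the target length and scaled, with one fixed-point refinement.

## Registration

**Linear stage.** The global similarity (scale, rotation, translation)
or affine transform is initialized automatically — physical-extent
ratio for the scale seed, log-polar phase correlation of windowed FFT
magnitudes for residual scale/rotation, phase correlation for
translation — and refined by bounded Powell descent on the mean squared
intensity difference, coarse-to-fine (3 levels, anti-aliased
decimation). Two safeguards matter on sparse biological structures:
the refinement runs on moderately smoothed images (σ = 3 px; the
global transform lives at blob scale, and thin filaments otherwise
produce partial-overlap local minima), and the per-level search bounds
shrink from ±8% to ±2% around the initialization (unbounded SSD descent
rewards the degenerate solution that warps the image out of the field,
whose SSD is lower than any imperfect overlap). Both input images
receive the same preprocessing blur: smoothing only one side of the
pair was measured to bias the fitted scale by ~0.5% through apparent
blob-size mismatch.

**Non-rigid stage.** The linearly registered post image is registered
to the pre image with a cubic B-spline free-form deformation: control-
point displacements on a lattice (finest spacing 16 px, three
coarse-to-fine levels at 64/32/16 px, each level initialized by
least-squares projection of the previous dense field), optimized by
L-BFGS-B with analytic gradients under

    mean[(post(p + u(p)) − pre(p))²]  +  λ · bending(u)

where the bending energy is the mean squared second difference
(including the mixed term) of the control lattice. Both terms are
normalized (per pixel, per control point), so λ is dimensionless but
specific to this parameterization; values from other registration
packages do not transfer. Class defaults were calibrated on phantoms
with known imposed fields: λ = 1e-3 for dense-blob (nuclear) images and
1e-4 for filament/mitochondria images, preserving the conventional 10:1
stiffness ratio between the two classes. The linear-ramp residual of a
shear is representable at any stiffness (its bending energy is zero);
the weak filament-class penalty is what permits faithful recovery of
genuinely non-linear fields, at the cost of a slightly higher noise
floor in the shortest distance bins. Registration is fully
deterministic: no stochastic metric sampling anywhere.

Masks (regions of no features, excluded manually in practice) zero the
masked pixels and weight them out of the SSD.

## Distortion curves

Point sets are the 1-px inner boundary of the Otsu-thresholded pre
image (outline mode, nuclear stains) or its morphological skeleton
(filaments, mitochondria). Points are displaced by bilinear
interpolation of the deformation field; for every unordered pair with
original distance d_i ≤ the class range (nuclei 20 µm, mitochondria
10 µm, microtubules 8 µm), the error |d_def − d_i| is binned by d_i
(bin width 0.5 µm, first bin from 1 px). The per-bin aggregator is the
mean of absolute errors (an RMS aggregator is available as a config
option; the two differ by <15% for the error distributions seen here).
Relative error divides by the bin center. When the pair count exceeds
`max_pairs` (default 2×10⁶) a seeded uniform subsample without
replacement is used — an unbiased estimate of the same bin means —
and `n_pairs` records sampled counts. With subsampling off, the
statistic is bit-identical to an exhaustive double loop over all pairs.

## Expansion factors and scaling arithmetic

Area-based: Otsu threshold → fill holes → connected components,
dropping components below 20 µm² (pre-expansion equivalent; rejects
debris) or touching the border (truncated areas bias the mean); the
factor is sqrt(mean post area / mean pre area), with a per-object
dispersion reported alongside. Crop-based: sqrt of the physical area
ratio of landmark-matched rectangles. The registration similarity
scale is a third, independent estimate. `scale_convert` performs the
image↔specimen length conversions and the volumetric (cube) factor.

## Morphometry

Thick line profiles average `thickness_px` parallel bilinear samples
(10 px by convention for cristae/Golgi, 5 px for centrioles; even
values are rounded up to odd for symmetry). Peaks are local maxima with
prominence ≥ 10% of the profile dynamic range and ≥ 3 samples
separation — deliberately conservative, since the manual practice this
replaces is a human reading peaks off a plot. Spacings divide by the
expansion factor, so the correction is exactly linear in 1/factor.
Roundness follows the shape-descriptor convention
4·area/(π·major_axis²) of the moments-equivalent ellipse (1.0 for a
circle, b/a for an ellipse, 3/π ≈ 0.955 for a filled square);
circularity (4π·area/perimeter²) is available by option. Operations
take already-oriented 2D views; aligning off-axis 3D stacks is out of
scope.

## Signal quantification

Total fluorescence is background-corrected before summation (the
background is the mean of a user-selected cell-free region), then
normalized per cell, per ROI area or per mask area, and divided by the
exposure time. Negative pixels after bleedthrough subtraction
(a − f·b) are clipped at zero, since intensities are non-negative by
definition. The cell counter is connected components with an optional
distance-transform watershed split for touching nuclei; it approximates
but does not claim equivalence to manual merge correction. The group
comparison is a classical pooled-variance unpaired two-tailed t-test
(Welch optional), matching the convention of the commercial statistics
software such assays typically cite.

## What the phantom validation shows — and what it does not

Passing tests demonstrate that the estimators are correct and
well-calibrated *under the generative model*: Gaussian PSF, stationary
band-limited distortion fields, matched pre/post staining, no
out-of-focus structure. Real validation data differ in ways the
phantoms deliberately omit: different labels pre vs post expansion
(different antibodies, different backgrounds), 3D structure collapsed
by maximum projection, depth-dependent aberrations, and distortion
fields that need not be stationary (edge effects near gel boundaries).
The registration safeguards (bounded refinement, smoothing) were
designed with those failure modes in mind, but the quantitative
recovery guarantees measured here transfer only to data that broadly
resemble the model. The aperture problem is intrinsic: on smooth
texture-free structures, the displacement component along an edge or
fiber is unobservable locally, and the B-spline fills it in from the
penalty — one reason estimated curves sit a few percent *below* the
imposed truth at short lengths. Registration accuracy also degrades on
fields with very little structure: a scene of a few sub-µm objects
(e.g. isolated Golgi stacks in an otherwise empty 50 µm field) carries
too little intensity information for percent-level scale recovery,
which is why distortion analysis is performed on nuclei, mitochondria
or microtubule channels that fill the field of view.

## Problem sizes

Default validation scenarios use 512² pre images (51 µm field at
100 nm/px), 3–20 structures per field, and ≤ 2×10⁶ point pairs per
curve; a full null/shear/non-rigid acceptance run completes in a few
minutes on one CPU. All randomness flows from a single seed through
named substreams (CRC-keyed `SeedSequence`), so every artifact is
reproducible bit-for-bit.
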