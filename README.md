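# exmetric

Validation metrology for iterative expansion microscopy (ExM).

Expansion microscopy physically magnifies a specimen by embedding it in
a swellable hydrogel; iterative (two-round) protocols reach ~13–21×
linear expansion, turning a confocal microscope into an effective
10–25 nm instrument. Every claim built on such images rests on two
quantitative questions: *how much* did the specimen expand, and *how
uniformly*? `exmetric` implements the standard analysis battery that
answers them — for microscopists validating an expansion protocol, and
for method developers who need a ground-truthed testbed:

- **Expansion factor** — the square root of the post/pre area ratio,
  from segmented nuclear cross-sections or landmark-matched crops.
- **Distortion curves** — register the post-expansion image to the
  pre-expansion image of the same field (similarity or affine, then a
  cubic B-spline free-form deformation), apply the residual deformation
  field to the outline/skeleton coordinates of the pre image, and for
  every point pair compare the original distance *d*ᵢ with the deformed
  distance *d*_def. The curve of mean |*d*_def − *d*ᵢ| (± sd) binned by
  *d*ᵢ — the RMS error versus measurement length — is the field's
  standard distortion readout; dividing by the bin center gives the
  relative error ("x % of the measurement length").
- **Organelle morphometry** — peak-to-peak spacings from thick line
  profiles (mitochondrial cristae, Golgi cisternae), crest-to-crest ER
  tubule diameters, centriole roundness (4·area/(π·major²) of the
  moments-equivalent ellipse) and length-to-width ratios, all corrected
  to biological units by the expansion factor.
- **Fluorescence retention** — background-corrected total signal per
  cell / per ROI / per mask area, exposure-normalized, with channel
  bleedthrough subtraction and an unpaired two-tailed t-test for
  condition comparisons.
- **Phantom simulator** — since validation datasets of this kind are
  rarely deposited, a first-class generator builds vector-geometry
  scenes (nuclei, microtubule filaments, mitochondria with cristae,
  Golgi stacks, centrioles), images them through a Gaussian PSF with
  Poisson–Gaussian noise, and re-images them after a known deformation
  `x ↦ s·M·(x + u(x))` (global scale × unimodular shear × smooth random
  field), with exact ground truth for every quantity the pipeline
  estimates.

## Worked example

`examples/distortion_curve.py` simulates a 15.6× expansion with 3%
handling shear and runs the full metrology pipeline:

```
similarity  fitted scale 15.709   mean relative error 1.76%
affine      fitted scale 15.607   mean relative error 0.04%

 bin_center_um  mean_error_nm     sd_nm  relative_pct  n_pairs
          0.35       6.746763  4.720231      1.927646     1875
          0.85      16.642741  8.864000      1.957970     1916
          1.35      25.987598 13.883193      1.925007     1945
          1.85      34.500521 19.029493      1.864893     2022
```

The similarity transform cannot represent the 3% anisotropy, so the
B-spline stage reports it as ~1.9% relative error at every length; the
affine transform absorbs it and the curve collapses to the noise floor
(0.04%). This similarity-vs-affine contrast is how mechanical handling
distortion is distinguished from genuine expansion inhomogeneity.

The other examples each run one capability end to end and print what
the numbers mean: `expansion_factor.py` (segmentation path recovers the
simulated 15.6×; an exact area ratio of 204.49 gives exactly 14.3),
`cristae_spacing.py` (85 nm ground truth read back as 84.7 ± 2.6 nm),
`retention_assay.py` (normalized-signal ratio 0.997 between fields with
different cell counts and exposures), `scaling_arithmetic.py` (PSF and
decrowding conversions).

A thin CLI mirrors the library for shell pipelines:

```sh
exmetric simulate --kind nuclei --scale 15.6 --seed 1 --out run/
exmetric distortion run/pre.tif run/post.tif --structure nuclei --out run/
exmetric expansion-factor run/pre.tif run/post.tif
```

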