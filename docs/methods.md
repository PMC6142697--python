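# Methods

## Model and scope

The metric treats a structural brain MRI slice as a two-tissue-class
image: a bright class with high edge density (cortical gray matter, the
boundaries between anatomical structures, bright CSF in sulci on T2) and a
dark class (white matter and other interior tissue), on an air background
that is essentially zero. An observed slice is a degraded ideal two-valued
image — blurred by a point-spread function or modulated by a smooth bias
field, plus noise. Under this model the rescaled slice and its local-range
contrast image coincide for an undistorted acquisition, so their first
moments coincide, all four moment-thresholded binary images collapse into
two identical pairs, and the pixel-wise matching scores equal 1.
Degradations separate the two moments and the score falls. This gives a
standardized index in [0, 1] that needs no reference image and no
scanner-specific calibration.

Scoring is slice-wise; volume-level decisions use the mean of the
per-slice totals. The package does not attempt skull stripping,
registration, 3-D features, or region-of-interest scoring, and the
two-class model deliberately ignores the ventricular system.

## Pipeline stages and numerical choices

**Foreground extraction.** The head (not the brain alone) is segmented by
global thresholding of the raw intensities. Because a good-quality slice
has three histogram modes (air ≈ 0, dark tissue, bright structures), the
lower of the two three-class Otsu thresholds is used to separate air from
tissue; two-class Otsu would land in the tissue/bright gap and discard the
dark interior. Images with fewer than three distinct gray levels fall back
to the two-class threshold. One 3×3 binary closing bridges thin breaks,
holes are filled, and the largest connected component is kept. Morphology
runs before component selection so a thin, fragmented bright rim is merged
and filled rather than reduced to its largest fragment. An all-zero or
constant slice raises an "empty slice" error; no stage ever returns NaN
scores.

**Rescaling.** Min-max over the *full* slice (the ≈0 background anchors
the lower end), mapping to [0, 1]. A constant slice raises a
zero-dynamic-range error. Rescaling is idempotent and order-preserving, so
any affine intensity map applied upstream is normalised away.

**Contrast feature.** A sliding range filter (window max − min) with
reflective border padding, so the slice edge does not read as maximal
contrast. Window width is 3, 5 or 7 by the nearest size class of
`max(height, width)` to 250, 350 and 450 px (class boundaries at 300 and
400); an explicit configuration value always overrides the rule. Both
first moments are means over the foreground by default (`moments_over`
switches to full-image means); restricting μ_d to the foreground keeps the
score independent of head size relative to the canvas.

**Binarisation.** Strict inequality (`value > moment`): a pixel exactly at
the threshold stays dark. Background pixels are always dark and excluded
from all counts. Thresholding a {0, 1}-valued feature at any moment in
(0, 1) reproduces the feature, which is what makes the ideal-image
identity exact rather than approximate.

**Matching.** "Edge pixels" are the inner morphological boundary of the
bright regions under 4-connectivity (8-connectivity via configuration):
bright pixels with at least one dark, background or out-of-image
neighbour. The edge-matching scores (q1, q2) count pixels that are edge
pixels in *both* images of the pair and divide by the larger bright-pixel
count, exactly as the defining ratio is written; as a consequence q1 and
q2 stay well below 1 even for identical pairs (perimeter over area). A
configuration flag `edge_denominator` switches the denominator to the
larger edge count, making identical pairs score 1; it is off by default.
If both bright sets are empty the score is 0 with a warning — an image
with no supra-threshold structure has no measurable contrast. The
pixel-wise scores (q3, q4) count foreground agreement (both bright or both
dark) over `n_t`.

**Weights and cut-offs.** Defaults `w = (0.1, 0.1, 0.7, 0.1)`; texture
contrast dominates because it is by far the strongest driver of perceived
quality in complex scenes. Weights must be non-negative and sum to 1
(enforced, overridable). Volume pass/fail compares mean Q with ≥ against
0.40 (T1 and unknown) or 0.45 (T2).

## Degradation models

* **Circular blur**: convolution with a normalized binary pillbox
  (circular averaging) kernel; level = radius in pixels. A spatially
  uniform kernel is swept over the image; the level grid 1–15 covers the
  radii of interest. Radius must be below half the smaller image dimension.
* **Motion blur**: convolution with a normalized rasterised line kernel;
  level = length in pixels, angle in degrees (default 0°, level scales
  length only). Length 1 is the identity.
* **Rician noise**: the slice is placed in the real channel, independent
  N(0, σ²) fields corrupt real and imaginary channels, and the magnitude
  is returned; σ = (level/100) × max intensity. On zero signal this is
  Rayleigh noise with mean σ√(π/2) — the closed form the tests check.
  Pipelines must pass an explicit seed; unseeded use warns.
* **Bias field**: a synthetic stand-in for scanner inhomogeneity — a
  smooth multiplicative field (off-centre Gaussian bump or linear ramp)
  with amplitude 0.06 × level, strictly positive at every level.

All blur kernels sum to 1, so mean intensity is preserved on interior
constant regions; boundaries are reflective throughout.

## The phantom generator

The phantom realises the two-class model directly: an elliptical head
(semi-axes 0.40 h × 0.42 w) on a zero background, outlined by a bright rim
whose outer boundary carries two low-frequency sinusoidal harmonics (head
outline) and whose inner boundary carries higher-frequency harmonics
(gyral folds). Inner-wiggle amplitudes are capped so the band keeps at
least ~60 % of its mean thickness and never pinches apart on the pixel
grid. The interior is dark (default 0.12 of the rim intensity) and
contains thin bright elliptical arcs — sulcal CSF and structure
boundaries, the same bright class as the rim — plus a smooth shading bump
and a smooth stochastic texture field (Gaussian-filtered white noise,
σ = 3 px, 10 % of the intensity span). The texture field matters: tissue
intensities must form a continuous distribution, otherwise both moments
fall into an empty histogram gap and every phantom scores exactly 1, with
knife-edge flips when a uniform interior level crosses a moment.

Defaults were chosen so that a clean default phantom reproduces the
operating point reported for good-quality clinical T2 volumes — total
score around 0.85 with texture ≈ 0.6 and lightness ≈ 0.8 — because the
clean phantom stands in for a good-quality acquisition. The key structural
requirement is that the bright class be *thin*: for a curvilinear bright
structure of width u, the range filter marks a band of width roughly
u + window − 1, so thin structures give the contrast image enough mass to
bring μ_c close to μ_d, as in real anatomy. Wide mid-gray blobs do the
opposite (they inflate μ_d without contributing contrast) and push the
clean phantom out of the ideal regime.

`ideal_spec()` produces the exactly-two-valued variant (rim 1, interior 0,
no arcs, no texture) that realises the undistorted regime. A volume is a
stack of scaled slices (half-sine scale profile, largest mid-volume) that
share the seed-derived geometry, so anatomy varies smoothly through the
stack. The generator returns the analytic head mask and tissue labels as
ground truth; for specs with a positive interior intensity the mask equals
the nonzero support of the image.

What the phantom does *not* emulate: real anatomical geometry, partial
volume effects, three-class tissue composition, k-space artifacts, and
scanner-acquired bias fields. Passing tests on the phantom show that the
metric responds to degradations as designed under the two-class model, not
that its absolute scores transfer to any particular clinical dataset.

## Problem sizes in the test suite

Bound-checking fuzz uses 500 random phantoms at 48–96 px with random
degradations; exhaustive-counting oracles run on 8×8 grids and 64×64
phantoms; degradation-response checks use 256×256 phantoms, 20 seeds and
levels {3, 6, 9, 12, 15}, asserting a non-increasing median for the two
blurs from level 3 up (the known transient rise at levels 1–3 exempts the
lowest levels), a level-15 median strictly below the clean median for all
three degradations, and a clean-beats-degraded win on at least 18 of 20
seeds. The Rayleigh check uses 10⁵ pixels and a 3-standard-error band.

## Known limitations

* The printed edge-matching ratio divides a co-edge count by a bright-area
  count, so q1 and q2 are scale-dependent (thinner structures score
  higher) and do not reach 1 for identical pairs unless
  `edge_denominator` is enabled.
* Foreground extraction degrades gracefully but inevitably under heavy
  noise: at high noise levels the air background rises above the
  air/tissue threshold and `n_t` grows beyond the head.
* Spearman's formula is applied to average ranks when ties occur (integer
  observer scores tie often); this is the standard approximation, not the
  exact tie-corrected coefficient.
* The weights are fixed perceptual constants, not fitted to observer data.
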