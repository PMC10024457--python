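# Methods

This note documents the models, conventions and parameter choices behind
`leafpol`, what the synthetic data do and do not emulate, and the known
limitations of the pipeline.

## Shape-from-focus reconstruction

**Model.** Each pixel of a focus stack is assigned the slice on which its
local intensity gradient magnitude is largest; the stage height of that
slice is the pixel's depth. This assumes (i) a fixed sample holder, so no
slice-to-slice registration is needed; (ii) image texture everywhere depth
is wanted — in textureless regions (deep grooves, saturated wax highlights)
the argmax is noise-driven, which is what the median filter is for.

**Conventions for under-determined details.**

- *Sharpness operator*: L2 magnitude of central differences (one-sided at
  borders), computed on luma for RGB input. The selection is driven by the
  sharpness *contrast* across slices, so the precise operator matters little;
  central differences are the simplest choice consistent with a per-pixel
  gradient.
- *Tie-breaking*: equal sharpness selects the lowest stack index, making the
  reconstruction deterministic.
- *Smoothing target*: the 10×10 median and 15×15 Gaussian pair is applied to
  the depth map (its purpose is to capture the shape of a single cell);
  a `smooth_composite` flag applies the same pair to the composite image.
  Both behaviors are provided because the original protocol is ambiguous
  about the target.
- *Even median window*: a 10×10 window has no central pixel; the origin sits
  at window index (5, 5) — the scipy convention — with nearest-edge padding.
  One consequence, measured on dome-shaped quantized depth, is that each
  median pass translates level-set contours slightly, so the filter is only
  near-idempotent for isolated edges, not for dense contour fields.
- *Gaussian width*: σ = 15/6 = 2.5 px, the standard kernel-size-to-σ rule,
  truncated at the 15×15 support.
- *Pixel scale*: 9.8×10⁻⁵ mm/pixel at 500× (from the calibration slide);
  no 100× calibration is published, so it must be user-supplied.

**Recovery performance.** On a synthetic 30-slice, 0.001 mm-step stack over
a tilted textured plane (128² px), ≥95% of texture-rich pixels (gradient
above the median) recover depth within ±1 stage step. Sub-step accuracy is
impossible by construction: depth is quantized to stage heights before
smoothing.

## Cell morphology

Margin undulation is `A1/A2` with `A1` the shoelace area of the traced
polygon and `A2` its convex-hull area; the value lies in (0, 1] and equals 1
iff the trace is convex, and is invariant to rotation, translation and
uniform scaling. The original procedure counted pixels inside the trace;
both a continuous (shoelace, resolution-independent) and a rasterized
pixel-count area are provided, agreeing within ~2% at realistic cell sizes.

The cap aspect ratio implements the published formula verbatim, including
the factor 2 on the planar peak-to-valley distance (the peak-to-valley run
is treated as half a cell width). A perfectly flat region raises
`FlatCellError` rather than returning infinity, mirroring the exclusion of
unmeasurable cells; the per-sample mean then averages over the remaining
tracings and records the exclusion.

Pubescence coverage is a straight pixel fraction of the traced hair mask.
The count × mean-of-5-hairs approximation is intended for dense (>25%)
coverage with consistent trichome sizes; the switch-over is advisory, not
enforced.

## Polarized spectral features

Preprocessing subtracts the dark reference and divides by the polarizer
transmittance per wavelength (floored at 10⁻⁶ to avoid blow-up on noisy
references). `R_min`/`R_max` are chosen as the whole scans with the
lowest/highest mean reflectance over 500–900 nm rather than the nominal
0°/90° columns, because surface tilt shifts the true extrema by several
polarizer steps; whole-scan selection preserves the spectral shape of the
diffuse spectrum that `DIFF_R` depends on. A per-wavelength envelope mode
exists behind a flag. Ties break toward 0° (minimum) and 90° (maximum).

`R_Qav` is the unweighted mean of `R_Q` over grid points in [500, 900] nm
inclusive. The thin-film interference ripple on the polarizer is *not*
removed — reference correction cannot remove it because its severity varies
between samples — and the band average is the sole mitigation: a ripple with
a whole number of periods in the window cancels to ~10⁻⁶ relative.
`DIFF_R = R_min(765)/R_min(680)` (NIR over red, so > 1 for green leaves;
linear interpolation off-grid, no extrapolation). The ~55° Brewster
geometry (arctan 1.45) is recorded as metadata only; no computation uses it.

## Phenotype classifier and evaluation harness

QDA with equal priors: per-class sample means and unbiased (n−1)
covariances, a ridge of 10⁻⁸·trace/2 added only when the condition number
exceeds 10¹², and prediction by maximum Gaussian log-density (priors being
equal). No feature scaling is applied — QDA is equivariant to it — so
`R_Qav` stays on its native 10⁻⁴ scale. Ties resolve in the fixed order
glossy < glaucous < hairy < glabrous.

The Monte-Carlo harness draws unstratified uniform 150/199 splits (the
published example split is close to, but not exactly, proportional),
redrawing a split that leaves a class absent from training. Each run has an
independently spawned seed substream, so any single run is reproducible from
the master seed. A run whose fit fails (a class with <3 training samples or
a singular covariance) is skipped; more than 1% skips aborts the
evaluation.

Two statistical subtleties are worth recording:

- The published headline (72.9% mean rate over 10,000 runs) requires the
  measured features of the 349 real leaves, which are not available; the
  classifier is therefore validated by properties — equivalence to a linear
  discriminant under pooled covariance, to the nearest-mean rule under
  identity covariances, chance-level behavior under label shuffling,
  parameter recovery on generator output, and bitwise determinism.
- A *single* shuffled-label dataset has its own, slightly learnable chance
  level (observed spread ~±0.02 across datasets at n = 200), and repeated
  splits of one dataset are correlated. The chance-level check therefore
  averages over independent shuffled datasets and takes its standard error
  across those replicates, not across runs.

## Synthetic data: what it emulates and what it does not

**Surfaces.** Periodic cell domes (cosine-squared profile, default 30 µm
pitch, 5 µm amplitude) with sinusoidally wavy margins, jittered centers,
optional trichomes, and wax: `glossy_fill` raises grooves to 75% of the
dome amplitude and smooths (strictly reducing height variance, the
groove-filling behavior of glossy wax), `glaucous_scatter` adds fine
correlated roughness. Default patches are sampled at 1 µm/pixel so a 128 px
field holds a few dozen cells at desk scale; the real 500× calibration
(0.098 µm/pixel) is used when reading microscope data. Trichomes are
stamped (disks for vertical hairs, thick segments for horizontal ones)
until the requested area fraction is met, so ground-truth coverage tracks
the configured density to within one stamp.

**Focus stacks.** Defocus is modeled as a Gaussian blur with σ =
`blur_coefficient`·|Δz| (default 3000 px/mm, capped at 12 px), composited
from a 12-level blur bank. The real microscope's defocus kernel is unknown;
a Gaussian is the standard desk-scale surrogate and only the monotone
blur-vs-offset relationship matters for selection tests.

**Scan sets.** `R(θ, λ) = D(λ) + S(λ)·sin²(θ − θ₀) + ripple + noise`, with
D a parametric green-leaf curve (base 0.03, green bump 0.04 at 550 nm, NIR
plateau 0.42 behind a logistic red edge at 710 nm) and S spectrally flat
(specular light does not enter the leaf, so it is "white"). The sin²
modulation follows from specular light being polarized perpendicular to the
incidence plane at the Brewster geometry; the thin-film ripple is a
zero-mean sinusoid applied to the specular term only. With no tilt and no
noise the decomposition is exact: `R_Q = S/2` and `R_min = D`. This is not
a physical BRDF: no wavelength-dependent refractive index, no
multiple-scattering canopy effects, no PROSPECT-style leaf interior.

**Feature clouds.** Truncated bivariate Gaussians per phenotype, calibrated
once to the published constraints: glabrous `R_Qav` confined to
[0.48, 4.32]×10⁻⁴, all classes within [0.30, 19.63]×10⁻⁴, the region above
8×10⁻⁴ reachable only by glossy samples, hairy predominantly below 2×10⁻⁴.
Per-class `DIFF_R` distributions are only loosely constrained by published
exemplars (a handful of values between 4.77 and 13.17 and the qualitative
statement that very hairy leaves resemble glaucous ones); the defaults are
therefore approximate, and the resulting Monte-Carlo rates (~70% mean on
the study-sized composition) should be read as behavior of the synthetic
geometry, not a reproduction of the measured result. Truncation biases
moments by construction, so parameter-recovery tests use untruncated specs.

## Problem sizes

Default test and acceptance runs use 128² px surfaces, 30-slice stacks,
261-point wavelength grids (400–1700 nm at 5 nm), 500–2000 Monte-Carlo runs
and 10⁴-sample recovery datasets; these sizes make the full suite run in
seconds while leaving every statistical check well-powered. The full
10,000-run protocol is a parameter change (`n_runs=10000`, a few seconds of
numpy time at study size).

## Known limitations

- No slice registration: stacks from instruments without a fixed holder
  will smear the depth map.
- Depth is quantized to stage heights; cap aspect ratios of shallow cells
  (height ≲ 2 stage steps) are dominated by quantization.
- Automatic segmentation is out of scope: cell traces and hair masks are
  inputs, not outputs.
- The low-chlorophyll (pink/yellow/white leaf) variant of `DIFF_R` at
  shorter wavelengths is not implemented; `DIFF_R` assumes a green-leaf red
  edge.
- Wax loading and trichome geometry are classified, not quantified.
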