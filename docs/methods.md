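# Methods

This note documents the models, defaults and numerical choices behind
`fieldbridge`, and what results on its synthetic cohorts do and do not say
about real paired 1.5T/3T data.

## Synthetic subjects

A subject's high-field reference is a stack of 2-D slices built from nested
smooth-boundary regions with fixed intensity tiers (background 0, ventricular
CSF 0.22, peripheral CSF 0.35, gray matter 0.60, white matter 0.85, on a
[0, 1] scale).  Region outlines are per-subject random ellipses perturbed by
low-order Fourier modes of the boundary radius, the in-plane radius follows
a spherical-cap profile through the stack, and roughly ten random smooth
blobs modulate the white-matter interior.  The blobs and boundary wobble are
deliberately strong enough that slices are far from rotationally symmetric:
in-plane rotation must be identifiable from image content for the
registration stage to be well-posed, just as cortical folding patterns make
it identifiable in real scans.  The phantom is *not* an anatomical model —
the analysis needs tissue-tiered intensities and spatial structure, not
anatomy.

The low-field member of a pair applies, in order:

1. **contrast scaling** toward the per-slice mean, factor `contrast_scale`
   (default 0.75) — gray–white contrast loss;
2. **Gaussian blur**, FWHM `blur_fwhm_px` (default 1.2 px) — lower effective
   resolution;
3. a **multiplicative bias field**: a random low-order 2-D polynomial
   normalized to mean 1 with peak deviation `bias_amplitude` (default 0.08);
4. **magnitude noise**: `|signal + N(0, noise_sigma)|` with `noise_sigma`
   default 0.03 of the intensity range.  The folding keeps intensities
   non-negative (as magnitude MR images are) while leaving the expected
   absolute perturbation at `sigma * sqrt(2/pi)` on tissue and background
   alike; a Rician option would behave nearly identically at these SNRs;
5. a **vendor gain** (A 1.00, B 1.08, C 0.92) — global intensity scale
   differences between manufacturers' reconstructions;
6. a small **rigid in-plane misalignment** (cohort default: translations
   uniform in ±3 px, rotation ±4°), resampled bilinearly.

With every parameter neutral the degradation is the identity, exactly.
Repeat scans share all structured components (the bias field and
misalignment derive from the scan's own seed) and differ only in the noise
stream, so averaging k repeats converges to the shared noiseless image at
the usual 1/sqrt(k) rate — this is what makes the repeat-scan IDP a clean
measurement-error floor.

Cohort defaults are three vendor strata with per-subject log-normal jitter
(25%) around the degradation defaults, 16 slices of 64×64 per subject.
These sizes are the package's desk-scale study conditions; slice count and
resolution are configurable.

## Registration

Same-subject, same-modality pairs justify a mean-squared-error similarity
after median intensity scaling (no mutual information needed).  Three
numerical choices matter, all adopted after the plain coarse-to-fine MSE
search proved fragile on rotation:

* both sides of the objective are smoothed (Gaussian, σ = 1 px) so
  resampling-induced high-frequency mismatch cannot out-compete a weak
  rotation signal;
* the multi-resolution pyramid (block averaging ×4, ×2) estimates
  **translation only** — block averaging suppresses exactly the texture
  that identifies rotation, biasing coarse rotation estimates toward zero;
* rotation is estimated at full resolution, seeded from a 2°-step grid
  sweep (the rotation landscape can carry noise-induced local minima) and
  polished by a Powell search over all three parameters.

An automated surrogate replaces visual inspection: normalized
cross-correlation of reference-foreground pixels must reach a threshold
(default 0.95) on every slice; on failure the search restarts from
perturbed initializations (default up to 3 restarts) and the best result is
kept.  On noiseless phantoms with |t| ≤ 5 px, |θ| ≤ 10°, recovery is within
0.5 px / 0.5° in ≥ 95% of trials (the acceptance suite runs 100).  One
transform is shared per stack by default (matching the generative model);
per-slice estimation is available.

## Super-resolution methods

Classical: separable cubic convolution (Keys kernel, free parameter
a = −1/2, i.e. Catmull-Rom — the interpolating member, which reproduces
linear signals exactly) and Lanczos-a (default a = 3).  Pixel centers sit at
integer coordinates, output grids align by center, borders replicate, and
kernel weights are renormalized to sum to 1 at every output position, so
constant images are exactly preserved.  Scale 1 returns the input bit-exactly.

Learned: ESPCN (conv stack in LR space + sub-pixel shuffle, MSE loss),
SRGAN (residual-block generator with batch norm and leaky-ReLU, pixel-shuffle
upsampling, global conv discriminator), and TCGAN (a patch-embedding
self-attention generator in series with a CNN U-Net generator, judged by a
PatchGAN discriminator that emits a grid of patch logits).  GANs train on a
weighted sum of adversarial (non-saturating BCE), L1 pixel, and perceptual
feature losses with default weights 1e-3 / 1 / 6e-3; the loss composition
for the transformer GAN is an interpretation — the combination is not
uniquely fixed by precedent — and the weights are configuration.

The perceptual feature space is the package's own frozen random three-stage
conv backbone (fixed seed), shared with the perceptual metric.  Random
shallow convolutional features are a standard training-free texture
embedding; absolute distances in this space are not comparable to published
learned-perceptual-metric values, and the package only ever uses orderings.

All networks run on an in-repo numpy reverse-mode autodiff engine in
float64 on a single thread, which makes training bit-reproducible for a
fixed seed and data order.  Desk-scale defaults (base 16–32 channels, 2–4
residual blocks, transformer depth 1–2, heads 2, patch 8) train in seconds
to minutes on one CPU.  Scale-1 operation is supported throughout because
field-strength harmonization on matched grids is a restoration problem as
much as an upsampling one; the pipeline default instead downsamples the
aligned low-field image by the configured factor (2) and maps it back to
the reference grid.

## Metrics

All metrics consume 8-bit quantized pairs (`round-half-up(255·clip(x,0,1))`).
Quantization is part of the IDP definition — the 0% threshold counts
"at least one gray level" differences, and under any continuous noise model
an unquantized version would saturate at 1 identically.

* **PSNR**: canonical `10·log10(255²/MSE)`; an `as_printed` variant
  `20·log10(255/MSE)` — a formula that appears verbatim in parts of the
  literature — is implemented too, because the two coincide only at
  MSE = 1 and the discrepancy should stay visible rather than be silently
  corrected.  Identical images return `inf` (the pipeline caps it at a
  large finite value for averaging).
* **SSIM**: 11×11 Gaussian windows (σ = 1.5) fully inside the image,
  stabilizers C1 = (0.01·255)², C2 = (0.03·255)², C3 = C2/2, exponents
  α = β = γ = 1 by default.  At unit exponents the component product is
  evaluated in its algebraically collapsed form, which keeps
  SSIM(x, x) = 1 to the last bit; general exponents use sign-preserving
  powers.
* **Perceptual distance**: mean squared distance between channel-unit-
  normalized feature maps across the backbone's three taps; zero iff
  inputs identical, symmetric.
* **IDP**: strict `>` on the relative difference, exactly as defined; the
  default sweep is {0, 10, 20, 25, 50, 75}% (the 25% point is part of the
  definition's formula even where prose lists five thresholds).  The
  reference-zero policy defaults to: empty-on-empty agrees (Q = 0), signal
  on empty background qualifies at every ψ — this keeps identical-image IDP
  at zero and flags hallucinated signal; a `mask_background` policy that
  excludes reference-zero pixels from N is selectable.  The normalizer N is
  all pixels (no brain mask) by default.

A property worth knowing: near saturation (IDP(0) ≈ 1) the metric is not
monotone under *added* distortion — extra noise can dither pixels back into
the reference's quantization bin and lower IDP(0) slightly.  This is a real
property of thresholded quantized differences, not an implementation
artifact; evaluation-level conclusions should therefore rest on the anchors
and paired statistics, not on tiny IDP(0) differences between nearly
saturated comparisons.

## Evaluation

Averaging is hierarchical and unweighted: slice values → subject mean →
cohort mean (overall and per vendor).  Pairwise method differences use
either a paired t-test on subject-level values (default) or an
intercept-only least-squares fit on slice-level differences with
subject-clustered sandwich standard errors and a t reference on
(clusters − 1) degrees of freedom.  Both are labeled as what they are;
no equivalence to any particular mixed-effect or GEE specification is
claimed.  Raw p-values are reported alongside Holm-adjusted ones.  The
significance level for anchor verdicts defaults to 0.001.

The two clinical-significance anchors: (1) a method passes only if it is
statistically significantly *better* than the original low-vs-high baseline
(direction-aware per metric); (2) each method's cohort IDP is reported as a
signed gap to the repeat-scan IDP floor (default 9 repeat-scan subjects) —
positive and small is the expected regime, and a method below the floor is
flagged rather than celebrated, since no stochastic method should beat the
measurement-error floor except by construction.

Degenerate inputs are handled explicitly: zero-variance paired differences
give p = 1 (zero mean) or p = 0 with a collapsed CI (nonzero mean); exact
ranking ties are broken alphabetically and flagged.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the metrics implement their definitions, the
registration recovers known transforms, the statistics are calibrated
(type-I error and CI coverage verified by simulation), the anchors behave
correctly on constructed method orderings, and trained models genuinely
improve over nearest-neighbor upsampling.  They do not certify performance
on real paired scans: the phantoms have no anatomy, no through-plane
effects, no k-space artifacts, Gaussian rather than Rician noise, and their
noise levels place the ψ = 0 IDP baseline near saturation (~99%), far above
values attainable on carefully preprocessed clinical data where most
background is exactly zero on both sides.  Cohort sizes (8–12 subjects,
4–16 slices) are desk-scale study conditions chosen for single-CPU runtimes;
the learned models' training lengths in `scripts/acceptance.py` (ESPCN 40,
GANs 20 epochs) are the shortest at which the GAN outputs are past the
degenerate early regime in which a generator scores well at ψ = 0 merely by
zeroing the background.  Cross-vendor harmonization, 3T→1.5T mapping and
radiomic feature validation are out of scope.
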