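# fieldbridge

Paired low-field/high-field MRI harmonization, end to end and fully
synthetic.  Clinical archives mix 1.5T and 3T T1-weighted brain scans, and
the field-strength gap (SNR, contrast, inhomogeneity) confounds pooled and
longitudinal analyses.  One harmonization strategy is computational: map
each 1.5T scan toward 3T quality with a super-resolution (SR) model, then ask
— with full-reference image quality metrics against the subject's own 3T
scan — whether the mapped image is measurably closer to the 3T reference
than the original 1.5T scan was.

`fieldbridge` implements that paired-design evaluation as a tested pipeline
on synthetic subjects:

* **phantom** — paired high/low-field brain-like slice stacks per subject
  (tissue-tiered concentric regions; the low-field member adds contrast
  loss, blur, a multiplicative bias field, magnitude noise, a vendor gain
  and a small in-plane rigid misalignment), plus same-subject repeat scans
  and three vendor strata.
* **registration** — rigid in-plane realignment of each low-field stack to
  its high-field pair (multi-resolution Powell search on a smoothed MSE
  objective, with an automated correlation check and restart loop).
* **super-resolution** — five methods behind one sklearn-style estimator
  interface (`fit(X_low, y_high)` / `transform`): bicubic (Catmull-Rom
  cubic convolution) and Lanczos-a interpolation, and ESPCN, SRGAN and TCGAN
  trained with the package's own numpy autodiff engine (no GPU, no
  downloads).
* **metrics** — PSNR (canonical and literal-formula variants), SSIM with
  configurable component exponents, a deterministic perceptual feature
  distance, and **IDP** (Intensity Differences in Pixels).
* **evaluation** — slice → subject → cohort averaging, per-vendor
  stratification, paired t / cluster-robust comparisons with 95% CIs and
  Holm adjustment, method ranking, and the two clinical-significance
  anchors: (1) a method must beat the original 1.5T-vs-3T baseline with
  statistical significance, (2) its IDP is compared against the repeat-scan
  measurement-error floor.

## The IDP metric

After quantizing both images to 8-bit gray levels, a pixel *qualifies* at
threshold ψ when its relative intensity difference from the reference
strictly exceeds ψ:

    Q(i,j) = 1   if |P_ref(i,j) − P_syn(i,j)| / P_ref(i,j) > ψ
    IDP(ψ) = Σ Q(i,j) / N,      ψ ∈ {0, 10, 20, 25, 50, 75}%

At ψ = 0 this is the fraction of pixels that differ by at least one gray
level.  Reference-zero pixels (undefined ratio) follow a documented policy:
empty-on-empty agrees; signal hallucinated on empty background qualifies at
every ψ.  IDP is exactly non-increasing in ψ.

## Worked example

```python
import numpy as np
from fieldbridge import (DegradationParams, degrade_to_low_field,
                         make_high_field_subject, register_rigid,
                         make_pair, idp_sweep, psnr, ssim)

high = make_high_field_subject("sub-01", n_slices=4, size_px=64,
                               vendor="A", seed=7)
low = degrade_to_low_field(high, DegradationParams(
    noise_sigma=0.02, blur_fwhm_px=1.0, contrast_scale=0.8, seed=3))
aligned = register_rigid(low, high).aligned

pair = make_pair(high.slices[2], aligned.slices[2])
print(f"PSNR {psnr(pair):.2f} dB  SSIM {ssim(pair):.3f}")
for r in idp_sweep(pair):
    print(f"  IDP(psi={r.psi:.2f}) = {100 * r.idp:5.1f}%  "
          f"({r.n_qualifying}/{r.n_pixels} px)")
```

prints

```
PSNR 23.15 dB  SSIM 0.668
  IDP(psi=0.00) =  99.5%  (4077/4096 px)
  IDP(psi=0.10) =  84.5%  (3460/4096 px)
  IDP(psi=0.20) =  60.5%  (2477/4096 px)
  IDP(psi=0.25) =  58.8%  (2407/4096 px)
  IDP(psi=0.50) =  57.4%  (2353/4096 px)
  IDP(psi=0.75) =  57.1%  (2340/4096 px)
```

At ψ = 0 almost every pixel of a noisy, contrast-reduced scan differs by at
least one gray level from its reference; the sweep shows the difference mass
decaying as the tolerance loosens.  The plateau at high ψ is the zero-policy
at work: contrast scaling toward the slice mean lifts the empty background
off zero, and signal on reference-empty background counts at every
threshold (the `mask_background` policy excludes those pixels instead).  A
good SR method pushes the whole curve down toward — but not below — the
repeat-scan floor.

The full pipeline is one call (or `fieldbridge run` from a shell):

```python
from fieldbridge import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7))
print(report.to_json())
```

CLI stages: `fieldbridge generate | register | superresolve | metrics |
evaluate | run`, each seeded and reproducible; volumes travel as NIfTI-1
with JSON sidecars.

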