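"""Synthetic paired high-field / low-field brain-like phantoms.

The generator replaces a download of real paired 1.5T/3T scans with phantoms
that reproduce the statistical structure the downstream analysis relies on:

* a high-field reference stack per subject built from nested smooth tissue
  regions (background 0, CSF, gray and white matter tiers, dark ventricles)
  whose outlines vary smoothly across slices and randomly across subjects;
* a low-field counterpart obtained by contrast loss, smoothing, a smooth
  multiplicative bias field, additive magnitude noise, a vendor gain, and a
  small in-plane rigid misalignment;
* same-subject repeat low-field scans that share every structured component
  and differ only in the noise realization — the basis of the repeat-scan
  measurement-error anchor;
* a vendor label with a vendor-specific intensity gain, so cohorts can be
  stratified by manufacturer; pairs are always same-vendor.

Everything is a pure function of its seed(s).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import (
    FIELD_HIGH,
    FIELD_LOW,
    VENDORS,
    DegradationParams,
    RigidTransform2D,
    SliceStack,
)

# Tissue intensity tiers (fraction of full range): CSF rim, gray matter,
# white matter, ventricular CSF.
_TIERS = {"csf": 0.35, "gray": 0.60, "white": 0.85, "ventricle": 0.22}

# Default gain per vendor: global intensity scale differences between
# manufacturers' reconstruction pipelines.
VENDOR_GAINS = {"A": 1.0, "B": 1.08, "C": 0.92}


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _region_mask(
    rr: np.ndarray,
    tt: np.ndarray,
    radius: float,
    wobble: np.ndarray,
    softness: float,
) -> np.ndarray:
    """Soft indicator of a star-convex region r < radius * (1 + wobble(theta)).

    ``wobble`` holds low-order Fourier coefficients (a_k, b_k) perturbing the
    boundary radius with angle; ``softness`` is the edge half-width in the
    same normalized radial units.
    """
    pert = np.zeros_like(tt)
    n_modes = wobble.shape[0]
    for k in range(n_modes):
        pert += wobble[k, 0] * np.cos((k + 2) * tt) + wobble[k, 1] * np.sin(
            (k + 2) * tt
        )
    boundary = radius * (1.0 + pert)
    return _smoothstep((boundary - rr) / max(softness, 1e-9) + 0.5)


def make_high_field_subject(
    subject_id: str,
    n_slices: int,
    size_px: int,
    vendor: str = "A",
    seed: int = 0,
    pixel_spacing_mm: Tuple[float, float] = (1.0, 1.0),
) -> SliceStack:
    """Generate a high-field reference stack for one subject.

    The phantom is a set of concentric smooth-boundary regions (not an
    anatomical atlas): an outer head/CSF ellipse, a gray-matter ring, a
    white-matter core with a few random smooth internal blobs for texture,
    and dark ventricles.  Region outlines carry per-subject random ellipse
    and low-order Fourier perturbations, so slices are not rotationally
    symmetric; the overall radius follows a smooth through-slice profile.
    Background outside the outer region is exactly 0.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    if vendor not in VENDORS:
        raise ValueError(f"unknown vendor {vendor!r}")

    rng = np.random.default_rng(seed)
    h = w = size_px

    # Per-subject geometry.
    aspect = rng.uniform(0.78, 0.95)
    orient = rng.uniform(0.0, np.pi)
    center = (np.array([h, w]) - 1) / 2.0 + rng.uniform(-1.5, 1.5, size=2)
    wobble_outer = rng.normal(0.0, 0.02, size=(3, 2))
    wobble_gray = rng.normal(0.0, 0.04, size=(3, 2))
    wobble_white = rng.normal(0.0, 0.06, size=(3, 2))
    wobble_vent = rng.normal(0.0, 0.05, size=(2, 2))
    vent_offset = rng.uniform(-0.08, 0.08, size=2)

    # Internal texture blobs inside white matter.
    n_blobs = 10
    blob_pos = rng.uniform(-0.38, 0.38, size=(n_blobs, 2))
    blob_amp = rng.uniform(-0.16, 0.16, size=n_blobs)
    blob_sig = rng.uniform(0.04, 0.12, size=n_blobs)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy = (yy - center[0]) / (0.5 * h)
    dx = (xx - center[1]) / (0.5 * w)
    # Rotate into the subject's ellipse frame and scale the minor axis.
    cy = np.cos(orient) * dy + np.sin(orient) * dx
    cx = -np.sin(orient) * dy + np.cos(orient) * dx
    cx = cx / aspect
    rr = np.hypot(cy, cx)
    tt = np.arctan2(cx, cy)

    soft = 2.5 / size_px  # ~2.5 px anti-aliased edge
    slices = np.zeros((n_slices, h, w))
    for z in range(n_slices):
        # Smooth through-slice radius profile (spherical cap).
        u = 0.0 if n_slices == 1 else (z / (n_slices - 1)) * 1.4 - 0.7
        zscale = float(np.sqrt(max(1.0 - u * u, 0.15)))

        outer = _region_mask(rr, tt, 0.80 * zscale, wobble_outer, soft)
        gray = _region_mask(rr, tt, 0.68 * zscale, wobble_gray, soft)
        white = _region_mask(rr, tt, 0.50 * zscale, wobble_white, soft)
        rv = np.hypot(cy - vent_offset[0], cx - vent_offset[1])
        vent = _region_mask(rv, tt, 0.16 * zscale, wobble_vent, soft)

        img = (
            _TIERS["csf"] * outer
            + (_TIERS["gray"] - _TIERS["csf"]) * gray
            + (_TIERS["white"] - _TIERS["gray"]) * white
            + (_TIERS["ventricle"] - _TIERS["white"]) * vent
        )
        # Texture blobs, confined to the white-matter region.
        tex = np.zeros_like(img)
        for b in range(n_blobs):
            d2 = (cy - blob_pos[b, 0]) ** 2 + (cx - blob_pos[b, 1]) ** 2
            tex += blob_amp[b] * np.exp(-d2 / (2 * blob_sig[b] ** 2))
        img = img + tex * white
        slices[z] = np.clip(img, 0.0, 1.0)
        # Exact-zero background outside the outer region.
        slices[z][outer <= 0.0] = 0.0

    return SliceStack(
        subject_id=subject_id,
        slices=slices,
        pixel_spacing_mm=pixel_spacing_mm,
        field_strength=FIELD_HIGH,
        vendor=vendor,
        repeat_index=0,
    )


def _bias_field(shape: Tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: low-order 2-D polynomial, mean 1, with
    peak deviation ``amplitude``."""
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    coeffs = rng.normal(size=(3, 3))
    coeffs[0, 0] = 0.0
    p = np.zeros(shape)
    for i in range(3):
        for j in range(3):
            if i == j == 0:
                continue
            p += coeffs[i, j] * (y**i) * (x**j)
    peak = np.max(np.abs(p))
    if peak > 0:
        p = p / peak * amplitude
    field = 1.0 + p
    return field / field.mean()


def _degrade(
    high: SliceStack, params: DegradationParams, noise_seed: Optional[int] = None
) -> SliceStack:
    """Shared implementation for first scans and repeats.

    Structured components (bias field) always derive from ``params.seed`` so
    repeats of a subject share them; only the additive noise stream switches
    to ``noise_seed``.
    """
    struct_rng = np.random.default_rng((int(params.seed), 1))
    noise_rng = np.random.default_rng(
        (int(params.seed) if noise_seed is None else int(noise_seed), 2)
    )

    out = high.slices.copy()

    # 1. Contrast scaling toward the per-slice mean.
    if params.contrast_scale != 1.0:
        means = out.mean(axis=(1, 2), keepdims=True)
        out = means + params.contrast_scale * (out - means)

    # 2. Gaussian blur of the stated FWHM (in-plane).
    if params.blur_fwhm_px > 0:
        sigma = params.blur_fwhm_px / 2.3548200450309493
        for z in range(out.shape[0]):
            out[z] = ndimage.gaussian_filter(out[z], sigma, mode="nearest")

    # 3. Smooth multiplicative bias field (one field per subject/scan).
    if params.bias_amplitude > 0:
        field = _bias_field(high.shape, params.bias_amplitude, struct_rng)
        out = out * field[None, :, :]

    # 4. Additive Gaussian noise on the magnitude image: |signal + n| keeps
    # intensities non-negative and leaves E|difference| = sigma * sqrt(2/pi)
    # both on tissue and on empty background.
    if params.noise_sigma > 0:
        out = np.abs(out + noise_rng.normal(0.0, params.noise_sigma, out.shape))

    # 5. Vendor gain.
    if params.vendor_gain != 1.0:
        out = out * params.vendor_gain

    # 6. Rigid in-plane misalignment.
    if not params.misalign.is_identity:
        out = np.stack([params.misalign.apply(s) for s in out])
        out = np.maximum(out, 0.0)

    return SliceStack(
        subject_id=high.subject_id,
        slices=out,
        pixel_spacing_mm=high.pixel_spacing_mm,
        field_strength=FIELD_LOW,
        vendor=high.vendor,
        repeat_index=0,
        provenance=high,
    )


def degrade_to_low_field(high: SliceStack, params: DegradationParams) -> SliceStack:
    """Produce the low-field member of a subject pair.

    Applies, in order: contrast scaling toward the mean, Gaussian blur,
    multiplicative bias field, additive magnitude noise, vendor gain, and
    rigid misalignment resampling.  Neutral parameters return the input
    pixel-identically (apart from the field tag).
    """
    if high.field_strength != FIELD_HIGH:
        raise ValueError("degrade_to_low_field expects a high-field stack")
    low = _degrade(high, params)
    low.degradation = params  # type: ignore[attr-defined]
    return low


def make_repeat_scan(
    low: SliceStack, params: DegradationParams, repeat_seed: int
) -> SliceStack:
    """Same-subject repeat low-field scan: identical structured degradation,
    independent noise realization."""
    if low.field_strength != FIELD_LOW:
        raise ValueError("make_repeat_scan expects a low-field stack")
    if low.provenance is None:
        raise ValueError("low-field stack carries no provenance high-field stack")
    if int(repeat_seed) == int(params.seed):
        raise ValueError("repeat_seed must differ from the original scan seed")
    rep = _degrade(low.provenance, params, noise_seed=repeat_seed)
    rep.repeat_index = low.repeat_index + 1
    rep.degradation = params  # type: ignore[attr-defined]
    return rep


def make_cohort(
    n_subjects_per_vendor: Dict[str, int],
    config: Optional[DegradationParams] = None,
    seed: int = 0,
    n_slices: int = 16,
    size_px: int = 64,
    jitter: float = 0.25,
    misalign_tx: float = 3.0,
    misalign_theta: float = 4.0,
) -> List[Tuple[SliceStack, SliceStack]]:
    """Generate a cohort of same-vendor (high, low) subject pairs.

    Per-subject degradation parameters are drawn around ``config`` (relative
    jitter on noise/blur/bias/contrast; misalignment uniform within
    ``±misalign_tx`` px and ``±misalign_theta`` deg); the vendor gain comes
    from :data:`VENDOR_GAINS`.  Cross-manufacturer pairs are never generated.
    """
    if not n_subjects_per_vendor or all(
        v < 1 for v in n_subjects_per_vendor.values()
    ):
        raise ValueError("need at least one vendor with count >= 1")
    for v in n_subjects_per_vendor:
        if v not in VENDORS:
            raise ValueError(f"unknown vendor {v!r}")
    config = config or DegradationParams()

    root = np.random.SeedSequence(seed)
    pairs: List[Tuple[SliceStack, SliceStack]] = []
    idx = 0
    for vendor, count in n_subjects_per_vendor.items():
        for _ in range(count):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            sid = f"sub-{idx:03d}"
            subj_seed = int(rng.integers(0, 2**31 - 1))
            high = make_high_field_subject(
                sid, n_slices, size_px, vendor=vendor, seed=subj_seed
            )

            def _jit(v: float) -> float:
                return float(v * np.exp(rng.normal(0.0, jitter))) if v > 0 else 0.0

            params = DegradationParams(
                noise_sigma=_jit(config.noise_sigma),
                blur_fwhm_px=_jit(config.blur_fwhm_px),
                bias_amplitude=_jit(config.bias_amplitude),
                contrast_scale=float(
                    np.clip(config.contrast_scale * np.exp(rng.normal(0, jitter / 4)), 0.05, 1.0)
                ),
                misalign=RigidTransform2D(
                    float(rng.uniform(-misalign_tx, misalign_tx)),
                    float(rng.uniform(-misalign_tx, misalign_tx)),
                    float(rng.uniform(-misalign_theta, misalign_theta)),
                ),
                vendor_gain=VENDOR_GAINS[vendor],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            low = degrade_to_low_field(high, params)
            pairs.append((high, low))
            idx += 1
    return pairs
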