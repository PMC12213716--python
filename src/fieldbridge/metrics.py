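"""Full-reference image quality metrics.

All metrics operate on 8-bit quantized image pairs (:class:`QuantizedPair`):
intensities in [0, 1] are mapped to integer gray levels 0–255 first, because
the thresholded pixel-difference metric counts *gray-level* differences — at
its 0% threshold a pixel qualifies exactly when the two quantized values
differ by at least one gray level.  Under any continuous noise model a
float-valued version of that count would saturate at 1, so quantization is
part of the metric's definition, not a storage detail.

Implemented metrics:

* ``psnr`` — peak signal-to-noise ratio, in the canonical form
  ``10·log10(Max²/MSE)`` and in an ``as_printed`` variant
  ``20·log10(Max/MSE)`` that some reports use verbatim; the two coincide only
  at MSE = 1.  Identical images return ``inf``.
* ``ssim`` — structural similarity, the product of Gaussian-windowed
  luminance, contrast and structure components raised to configurable
  exponents α, β, γ (all 1 by default).
* ``perceptual_distance`` — mean squared distance between unit-normalized
  deep feature maps from the package's fixed-seed conv backbone; lower is
  more similar; only orderings are meaningful.
* ``idp`` / ``idp_sweep`` — Intensity Differences in Pixels: the fraction of
  pixels whose relative intensity difference from the reference *strictly*
  exceeds a threshold ψ, swept over ψ ∈ {0, 10, 20, 25, 50, 75}%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .features import FeatureBackbone, default_backbone
from .features import feature_distance as _feature_distance
from .nn import Tensor

MAX_F = 255
DEFAULT_PSI = (0.0, 0.10, 0.20, 0.25, 0.50, 0.75)

ZERO_POLICIES = ("flag_nonzero", "mask_background")


@dataclass(frozen=True)
class QuantizedPair:
    """A reference/candidate pair of equal-size 8-bit gray-level grids."""

    reference: np.ndarray
    candidate: np.ndarray
    max_f: int = MAX_F

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference)
        cand = np.asarray(self.candidate)
        if ref.shape != cand.shape or ref.ndim != 2:
            raise ValueError("reference and candidate must be equal-shape 2-D grids")
        for name, arr in (("reference", ref), ("candidate", cand)):
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{name} must be an integer grid (quantize first)")
            if arr.min() < 0 or arr.max() > self.max_f:
                raise ValueError(f"{name} values outside [0, {self.max_f}]")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "candidate", cand)


@dataclass(frozen=True)
class IDPResult:
    """One point of the IDP threshold sweep."""

    psi: float
    idp: float
    n_pixels: int
    n_qualifying: int


def quantize(img: np.ndarray) -> np.ndarray:
    """Map a float image in [0, 1] to integer gray levels 0–255.

    Values are clipped to [0, 1] and rounded half-away-from-zero (0.5 of a
    gray level rounds up), so 0.5 → 128.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    scaled = MAX_F * np.clip(img, 0.0, 1.0)
    return np.floor(scaled + 0.5).astype(np.int64)


def make_pair(reference: np.ndarray, candidate: np.ndarray) -> QuantizedPair:
    """Quantize two float images in [0, 1] into a metric-ready pair."""
    return QuantizedPair(quantize(reference), quantize(candidate))


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

def psnr(pair: QuantizedPair, variant: str = "standard") -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    ``standard`` is ``10·log10(Max_f² / MSE)``; ``as_printed`` evaluates
    ``20·log10(Max_f / MSE)`` literally.  The variants agree only when
    MSE = 1; both are exposed so the discrepancy stays visible.
    """
    if variant not in ("standard", "as_printed"):
        raise ValueError(f"unknown PSNR variant {variant!r}")
    diff = pair.reference.astype(float) - pair.candidate.astype(float)
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return math.inf
    if variant == "standard":
        return 10.0 * math.log10(pair.max_f**2 / mse)
    return 20.0 * math.log10(pair.max_f / mse)


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    r = np.arange(window) - (window - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _signed_pow(x: np.ndarray, p: float) -> np.ndarray:
    if p == 1.0:
        return x
    return np.sign(x) * np.abs(x) ** p


def ssim(
    pair: QuantizedPair,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    window: int = 11,
    window_sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Structural similarity: mean of ``l^α · c^β · s^γ`` over Gaussian
    windows that fit fully inside the image.

    Stabilizers ``C1=(k1·L)²``, ``C2=(k2·L)²``, ``C3=C2/2`` with ``L = max_f``
    keep flat regions well-defined; with α=β=γ=1 the measure is symmetric in
    its two arguments and equals 1 exactly for identical images.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > min(pair.reference.shape):
        raise ValueError("window larger than image")
    x = pair.reference.astype(float)
    y = pair.candidate.astype(float)
    kern = _gaussian_kernel(window, window_sigma)

    def win(img):
        return fftconvolve(img, kern, mode="valid")

    mu_x = win(x)
    mu_y = win(y)
    sxx = win(x * x) - mu_x**2
    syy = win(y * y) - mu_y**2
    sxy = win(x * y) - mu_x * mu_y

    L = float(pair.max_f)
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    c3 = c2 / 2.0
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    if alpha == beta == gamma == 1.0:
        # c·s with c3 = c2/2 collapses algebraically to (2σxy+C2)/(σx²+σy²+C2);
        # using it directly keeps SSIM(x, x) = 1 to the last bit
        ssim_map = lum * (2 * sxy + c2) / (sxx + syy + c2)
    else:
        # round-off can push exact-zero variances slightly negative; the
        # general path takes square roots, so clamp here only
        sxx = np.maximum(sxx, 0.0)
        syy = np.maximum(syy, 0.0)
        con = (2 * np.sqrt(sxx) * np.sqrt(syy) + c2) / (sxx + syy + c2)
        struct = (sxy + c3) / (np.sqrt(sxx) * np.sqrt(syy) + c3)
        ssim_map = _signed_pow(lum, alpha) * _signed_pow(con, beta) * _signed_pow(
            struct, gamma
        )
    return float(ssim_map.mean())


# ---------------------------------------------------------------------------
# perceptual distance
# ---------------------------------------------------------------------------

def perceptual_distance(
    pair: QuantizedPair, backbone: Optional[FeatureBackbone] = None
) -> float:
    """Deep-feature patch distance: ≥ 0, 0 for identical inputs, symmetric."""
    backbone = backbone or default_backbone()
    a = Tensor(pair.reference[None, None].astype(float) / pair.max_f)
    b = Tensor(pair.candidate[None, None].astype(float) / pair.max_f)
    return float(_feature_distance(a, b, backbone).data)


# ---------------------------------------------------------------------------
# IDP
# ---------------------------------------------------------------------------

def _qualifying(
    pair: QuantizedPair, psi: float, zero_policy: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean qualifying map Q and the validity mask defining N."""
    ref = pair.reference.astype(float)
    cand = pair.candidate.astype(float)
    nonzero = pair.reference != 0
    valid = np.ones_like(nonzero) if zero_policy == "flag_nonzero" else nonzero

    q = np.zeros(ref.shape, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(ref - cand) / ref
    q[nonzero] = rel[nonzero] > psi
    if zero_policy == "flag_nonzero":
        # ratio undefined at reference 0: empty-on-empty agrees (Q=0),
        # signal hallucinated on empty background qualifies at every psi
        q[~nonzero] = pair.candidate[~nonzero] != 0
    return q & valid, valid


def idp(pair: QuantizedPair, psi: float, zero_policy: str = "flag_nonzero") -> IDPResult:
    """Fraction of pixels whose relative gray-level difference from the
    reference strictly exceeds ψ (a pixel at exactly ψ does not qualify)."""
    if psi < 0:
        raise ValueError("psi must be >= 0")
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    q, valid = _qualifying(pair, psi, zero_policy)
    n = int(valid.sum())
    nq = int(q.sum())
    return IDPResult(psi=float(psi), idp=nq / n if n else 0.0,
                     n_pixels=n, n_qualifying=nq)


def idp_sweep(
    pair: QuantizedPair,
    thresholds: Sequence[float] = DEFAULT_PSI,
    zero_policy: str = "flag_nonzero",
) -> List[IDPResult]:
    """IDP at each threshold of an ascending ψ sweep; values are
    non-increasing in ψ because the qualifying pixel sets are nested."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [idp(pair, t, zero_policy) for t in thresholds]
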