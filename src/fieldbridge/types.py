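"""Core domain objects shared across the harmonization pipeline.

A *subject* is represented by one or more :class:`SliceStack` objects: an
ordered stack of 2-D axial slices with pixel spacing and acquisition tags
(field strength, vendor, repeat index).  High-field (3T-like) stacks serve as
references; low-field (1.5T-like) stacks are degraded counterparts produced by
:mod:`fieldbridge.phantom`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

FIELD_HIGH = "high"
FIELD_LOW = "low"
VENDORS = ("A", "B", "C")


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: translation (pixels) plus rotation about the
    slice center (degrees, counter-clockwise).

    ``tx_px`` shifts along the first array axis (rows), ``ty_px`` along the
    second (columns).  ``apply`` resamples with bilinear interpolation and
    edge replication, the convention used throughout the registration stage.
    """

    tx_px: float = 0.0
    ty_px: float = 0.0
    theta_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.tx_px == 0.0 and self.ty_px == 0.0 and self.theta_deg == 0.0

    def _matrix(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        return np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )

    def inverse(self) -> "RigidTransform2D":
        r_inv = self._matrix().T
        t = np.array([self.tx_px, self.ty_px])
        t_inv = -r_inv @ t
        return RigidTransform2D(float(t_inv[0]), float(t_inv[1]), -self.theta_deg)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        r = self._matrix()
        t = r @ np.array([other.tx_px, other.ty_px]) + np.array(
            [self.tx_px, self.ty_px]
        )
        return RigidTransform2D(
            float(t[0]), float(t[1]), self.theta_deg + other.theta_deg
        )

    def apply(self, img: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``img`` so its content moves by (tx, ty) and rotates by
        theta about the image center."""
        img = np.asarray(img, dtype=float)
        if self.is_identity:
            return img.copy()
        center = (np.array(img.shape) - 1) / 2.0
        # Output coord o maps to input coord R^-1 (o - c - t) + c.
        r_inv = self._matrix().T
        offset = center + np.array([self.tx_px, self.ty_px])
        return ndimage.affine_transform(
            img,
            r_inv,
            offset=-r_inv @ offset + center,
            order=order,
            mode="nearest",
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.tx_px, self.ty_px, self.theta_deg])


IDENTITY_TRANSFORM = RigidTransform2D()


@dataclass(frozen=True)
class DegradationParams:
    """Generative parameters mapping a high-field phantom to its low-field
    pair.

    Intensities live in [0, 1]; ``noise_sigma`` is the Gaussian noise scale as
    a fraction of that range, ``blur_fwhm_px`` the in-plane smoothing kernel
    FWHM, ``bias_amplitude`` the peak deviation of the multiplicative bias
    field from 1, ``contrast_scale`` in (0, 1] shrinks intensities toward the
    slice mean (gray-white contrast loss), ``vendor_gain`` a global intensity
    scale.  With every parameter at its neutral value the degradation is the
    identity.
    """

    noise_sigma: float = 0.03
    blur_fwhm_px: float = 1.2
    bias_amplitude: float = 0.08
    contrast_scale: float = 0.75
    misalign: RigidTransform2D = field(default_factory=RigidTransform2D)
    vendor_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.blur_fwhm_px < 0:
            raise ValueError("blur_fwhm_px must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if not (0 < self.contrast_scale <= 1):
            raise ValueError("contrast_scale must be in (0, 1]")
        if self.vendor_gain <= 0:
            raise ValueError("vendor_gain must be > 0")

    @classmethod
    def neutral(cls, seed: int = 0) -> "DegradationParams":
        return cls(
            noise_sigma=0.0,
            blur_fwhm_px=0.0,
            bias_amplitude=0.0,
            contrast_scale=1.0,
            misalign=RigidTransform2D(),
            vendor_gain=1.0,
            seed=seed,
        )

    def replace(self, **kw) -> "DegradationParams":
        return replace(self, **kw)


@dataclass
class SliceStack:
    """One subject's image as an ordered stack of 2-D slices.

    ``slices`` has shape (n_slices, H, W) with finite, non-negative float
    intensities.  ``provenance`` optionally points back at the stack this one
    was derived from (used by repeat-scan generation); it is never serialized.
    """

    subject_id: str
    slices: np.ndarray
    pixel_spacing_mm: Tuple[float, float] = (1.0, 1.0)
    field_strength: str = FIELD_HIGH
    vendor: str = "A"
    repeat_index: int = 0
    provenance: Optional["SliceStack"] = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3-D array (n_slices, H, W)")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("slice intensities must be finite")
        if np.any(self.slices < 0):
            raise ValueError("slice intensities must be non-negative")
        if self.field_strength not in (FIELD_HIGH, FIELD_LOW):
            raise ValueError(f"unknown field strength {self.field_strength!r}")
        if self.vendor not in VENDORS:
            raise ValueError(f"unknown vendor {self.vendor!r}")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if self.repeat_index < 0:
            raise ValueError("repeat_index must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.slices.shape[1:]

    def copy_with(self, **kw) -> "SliceStack":
        out = dict(
            subject_id=self.subject_id,
            slices=self.slices.copy(),
            pixel_spacing_mm=self.pixel_spacing_mm,
            field_strength=self.field_strength,
            vendor=self.vendor,
            repeat_index=self.repeat_index,
            provenance=self.provenance,
        )
        out.update(kw)
        return SliceStack(**out)
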