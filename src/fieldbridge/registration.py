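"""Rigid intra-subject realignment of low-field stacks to their high-field
pairs.

Same-subject, same-modality pairs are related (up to degradation) by a small
in-plane rigid motion, so a mean-squared-error objective after median
intensity scaling is an adequate similarity measure; no mutual-information
machinery is needed.  The optimizer is a coarse-to-fine search: translation
is estimated on block-averaged pyramid levels, rotation at full resolution
only (block averaging suppresses the texture that identifies it) seeded from
a grid sweep, with Powell refinement of all three parameters at the end.
Both sides of the objective are lightly smoothed so resampling artifacts do
not out-compete weak rotation signals.  If the result fails an automated
alignment check
(normalized cross-correlation of foreground pixels on every slice), the
search restarts from randomized perturbed initializations up to
``max_restarts`` times and the best result is kept — an automated version of
"inspect, and re-run realignment for pairs that failed".

By default one shared in-plane transform is estimated per stack (the
misalignment model the phantoms use); per-slice estimation is available via
``mode="per_slice"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage, optimize

from .types import RigidTransform2D, SliceStack

FOREGROUND_QUANTILE = 0.05  # of the reference max, defines foreground
DEFAULT_NCC_THRESHOLD = 0.95


@dataclass
class RegistrationResult:
    transforms: List[RigidTransform2D]
    aligned: SliceStack
    objective_trace: List[float]
    converged: bool
    n_restarts: int

    @property
    def transform(self) -> RigidTransform2D:
        return self.transforms[0]


def _block_downsample(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    h, w = img.shape
    h2, w2 = h - h % f, w - w % f
    return img[:h2, :w2].reshape(h2 // f, f, w2 // f, f).mean(axis=(1, 3))


def _median_scale(moving: np.ndarray, reference: np.ndarray) -> float:
    fg_ref = reference[reference > FOREGROUND_QUANTILE * reference.max()]
    fg_mov = moving[moving > FOREGROUND_QUANTILE * moving.max()]
    if fg_mov.size == 0 or fg_ref.size == 0:
        return 1.0
    med = np.median(fg_mov)
    return float(np.median(fg_ref) / med) if med > 0 else 1.0


OBJECTIVE_SMOOTH_SIGMA = 1.0  # px; pre-filter inside the similarity measure


def _smooth(img: np.ndarray, sigma: float = OBJECTIVE_SMOOTH_SIGMA) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma)


def _mse(params: np.ndarray, moving: np.ndarray, reference_smoothed: np.ndarray,
         scale_factor: float) -> float:
    """MSE between the smoothed warped moving image and the (pre-smoothed)
    reference.  Smoothing both sides suppresses resampling-induced
    high-frequency mismatch that can otherwise out-compete a weak rotation
    signal."""
    t = RigidTransform2D(params[0], params[1], params[2])
    warped = _smooth(t.apply(moving)) * scale_factor
    return float(np.mean((warped - reference_smoothed) ** 2))


def _optimize_slice(
    moving: np.ndarray,
    reference: np.ndarray,
    init: np.ndarray,
    tol: float,
    trace: List[float],
) -> np.ndarray:
    """Coarse-to-fine Powell minimization of intensity MSE."""
    sf = _median_scale(moving, reference)
    ref_s = _smooth(reference)
    est = np.asarray(init, dtype=float)
    size = min(moving.shape)

    # Coarse levels: translation only.  Rotation is deliberately left out of
    # the pyramid — block averaging suppresses the fine texture that carries
    # the rotation signal, biasing coarse estimates toward zero rotation.
    for f in [f for f in (4, 2) if size // f >= 16]:
        mov = _block_downsample(moving, f)
        ref_f = _block_downsample(ref_s, f)
        res = optimize.minimize(
            lambda p: _mse(np.array([p[0], p[1], est[2]]), mov, ref_f, sf),
            est[:2] / f,
            method="Powell",
            options={"xtol": tol, "ftol": tol, "maxiter": 100},
        )
        est[:2] = res.x * f
        obj = _mse(est, moving, ref_s, sf)
        if not trace or obj <= trace[-1]:
            trace.append(obj)

    # Full resolution: seed rotation from a grid sweep (the MSE landscape in
    # theta can carry noise-induced local minima), then refine all three.
    thetas = est[2] + np.arange(-10.0, 10.5, 2.0)
    objs = [_mse(np.array([est[0], est[1], th]), moving, ref_s, sf)
            for th in thetas]
    est[2] = thetas[int(np.argmin(objs))]
    res = optimize.minimize(
        _mse,
        est,
        args=(moving, ref_s, sf),
        method="Powell",
        options={"xtol": tol, "ftol": tol, "maxiter": 200},
    )
    est = res.x.copy()
    obj = _mse(est, moving, ref_s, sf)
    if not trace or obj <= trace[-1]:
        trace.append(obj)
    return est


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 1.0 if np.allclose(av, bv) else 0.0
    return float((av * bv).sum() / denom)


def alignment_check(
    aligned: SliceStack | np.ndarray,
    reference: SliceStack | np.ndarray,
    threshold: float = DEFAULT_NCC_THRESHOLD,
) -> bool:
    """True iff every slice correlates with its reference at ≥ ``threshold``
    (normalized cross-correlation over reference-foreground pixels).

    Scale- and offset-invariant, so intensity gain differences between field
    strengths do not fail the check.
    """
    a = aligned.slices if isinstance(aligned, SliceStack) else np.asarray(aligned, float)
    r = reference.slices if isinstance(reference, SliceStack) else np.asarray(reference, float)
    if a.ndim == 2:
        a, r = a[None], r[None]
    if a.shape != r.shape:
        raise ValueError("shape mismatch between aligned and reference")
    for az, rz in zip(a, r):
        mask = rz > FOREGROUND_QUANTILE * rz.max()
        if mask.sum() < 16:
            mask = np.ones_like(rz, dtype=bool)
        if _ncc(az, rz, mask) < threshold:
            return False
    return True


def register_rigid(
    moving: SliceStack,
    reference: SliceStack,
    max_restarts: int = 3,
    tol: float = 1e-4,
    mode: str = "global",
    ncc_threshold: float = DEFAULT_NCC_THRESHOLD,
    seed: int = 0,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    ``mode="global"`` fits one in-plane transform shared by all slices (the
    objective sums over slices); ``mode="per_slice"`` fits each slice
    independently.  Returns the best transform found, the resampled stack,
    the accepted-objective trace, whether the alignment check passed, and the
    number of restarts consumed.
    """
    if moving.slices.shape != reference.slices.shape:
        raise ValueError("moving and reference must have identical dimensions")
    if not (np.all(np.isfinite(moving.slices)) and np.all(np.isfinite(reference.slices))):
        raise ValueError("non-finite intensities")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if mode not in ("global", "per_slice"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    n = moving.n_slices
    trace: List[float] = []

    def solve(init: np.ndarray) -> List[np.ndarray]:
        if mode == "per_slice":
            return [
                _optimize_slice(moving.slices[z], reference.slices[z], init, tol, trace)
                for z in range(n)
            ]
        # global: optimize on the mean objective across slices via a stacked
        # representative slice set (use middle slice for coarse, all for fine)
        sf = _median_scale(moving.slices, reference.slices)
        refs_s = [_smooth(reference.slices[z]) for z in range(n)]

        def objective(p):
            total = 0.0
            for z in range(n):
                total += _mse(p, moving.slices[z], refs_s[z], sf)
            return total / n

        # coarse-to-fine on the middle slice first, then polish globally
        mid = n // 2
        est = _optimize_slice(
            moving.slices[mid], reference.slices[mid], init, tol, trace
        )
        res = optimize.minimize(
            objective, est, method="Powell",
            options={"xtol": tol, "ftol": tol, "maxiter": 200},
        )
        obj = float(res.fun)
        if not trace or obj <= trace[-1]:
            trace.append(obj)
        return [res.x] * n

    best_params: Optional[List[np.ndarray]] = None
    best_obj = np.inf
    converged = False
    restarts_used = 0
    init = np.zeros(3)

    # identity short-circuit
    if np.array_equal(moving.slices, reference.slices):
        aligned = moving.copy_with()
        return RegistrationResult(
            [RigidTransform2D()] * n, aligned, [0.0], True, 0
        )

    for attempt in range(max_restarts + 1):
        params = solve(init)
        aligned_slices = np.stack(
            [
                RigidTransform2D(*params[z]).apply(moving.slices[z])
                for z in range(n)
            ]
        )
        sf = _median_scale(moving.slices, reference.slices)
        obj = float(np.mean((aligned_slices * sf - reference.slices) ** 2))
        if obj < best_obj:
            best_obj = obj
            best_params = params
        check = alignment_check(
            moving.copy_with(slices=np.maximum(aligned_slices, 0.0)),
            reference,
            ncc_threshold,
        )
        if check:
            converged = True
            best_params = params
            break
        restarts_used = attempt + 1
        if attempt < max_restarts:
            init = np.array(
                [rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(-6, 6)]
            )

    assert best_params is not None
    transforms = [RigidTransform2D(*p) for p in best_params]
    aligned_slices = np.stack(
        [transforms[z].apply(moving.slices[z]) for z in range(n)]
    )
    aligned = moving.copy_with(slices=np.maximum(aligned_slices, 0.0))
    return RegistrationResult(
        transforms=transforms,
        aligned=aligned,
        objective_trace=trace,
        converged=converged,
        n_restarts=min(restarts_used, max_restarts),
    )
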