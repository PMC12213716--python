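"""Independent brute-force reference implementations used only by tests.

Each oracle is written as directly as possible from the mathematical
definition (explicit per-pixel loops, no shared code with the package), so
agreement with the package is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def cubic_w(t: float, a: float = -0.5) -> float:
    t = abs(t)
    if t <= 1:
        return (a + 2) * t**3 - (a + 3) * t**2 + 1
    if t < 2:
        return a * t**3 - 5 * a * t**2 + 8 * a * t - 4 * a
    return 0.0


def lanczos_w(t: float, a: int) -> float:
    if abs(t) >= a:
        return 0.0
    if t == 0:
        return 1.0
    return (
        math.sin(math.pi * t) / (math.pi * t)
        * math.sin(math.pi * t / a) / (math.pi * t / a)
    )


def naive_separable_resample(img, scale, kernel, support):
    """Double-loop separable resampling: center-aligned coordinates, clipped
    (edge-replicated) indices, per-position weight normalization."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    ho, wo = round(h * scale), round(w * scale)

    def axis_weights(n_in, n_out):
        rows = []
        for k in range(n_out):
            x = (k + 0.5) / (n_out / n_in) - 0.5
            base = math.floor(x)
            taps = []
            for off in range(-support + 1, support + 1):
                i = base + off
                taps.append((min(max(i, 0), n_in - 1), kernel(x - i)))
            total = sum(wt for _, wt in taps)
            rows.append([(i, wt / total) for i, wt in taps])
        return rows

    wr = axis_weights(h, ho)
    wc = axis_weights(w, wo)
    tmp = np.zeros((ho, w))
    for r in range(ho):
        for c in range(w):
            tmp[r, c] = sum(wt * img[i, c] for i, wt in wr[r])
    out = np.zeros((ho, wo))
    for r in range(ho):
        for c in range(wo):
            out[r, c] = sum(wt * tmp[r, i] for i, wt in wc[c])
    return out


def naive_bicubic(img, scale):
    return naive_separable_resample(img, scale, cubic_w, 2)


def naive_lanczos(img, scale, a=3):
    return naive_separable_resample(img, scale, lambda t: lanczos_w(t, a), a)


def naive_ssim(ref, cand, window=11, sigma=1.5, k1=0.01, k2=0.03, L=255):
    """Sliding-window SSIM from the definition, one window at a time."""
    x = np.asarray(ref, dtype=float)
    y = np.asarray(cand, dtype=float)
    r = np.arange(window) - (window - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    h, w = x.shape
    vals = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            wx = x[i : i + window, j : j + window]
            wy = y[i : i + window, j : j + window]
            mx = (kern * wx).sum()
            my = (kern * wy).sum()
            vx = (kern * wx * wx).sum() - mx * mx
            vy = (kern * wy * wy).sum() - my * my
            vxy = (kern * wx * wy).sum() - mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * vxy + c2))
                / ((mx * mx + my * my + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def naive_idp(ref, cand, psi):
    """Pixel-by-pixel count from the thresholded relative-difference rule."""
    ref = np.asarray(ref)
    cand = np.asarray(cand)
    n = 0
    q = 0
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            n += 1
            p0, p1 = int(ref[i, j]), int(cand[i, j])
            if p0 == 0:
                if p1 != 0:
                    q += 1
            elif abs(p0 - p1) / p0 > psi:
                q += 1
    return q / n, q, n


def brute_force_shift(a, b, max_shift=6):
    """Integer shift (dy, dx) to apply to b so it best correlates with a."""
    best = None
    best_val = -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            bs = np.roll(np.roll(b, dy, axis=0), dx, axis=1)
            v = float((a * bs).sum())
            if v > best_val:
                best_val = v
                best = (dy, dx)
    return best


def repeat_scan_idp_oracle(noiseless, sigma, n_draws, rng):
    """Monte-Carlo estimate of P(quantized repeat scans differ) per pixel,
    averaged over the image: simulate pairs of magnitude-noise scans of the
    same noiseless image and count quantized disagreements."""
    total = 0.0
    for _ in range(n_draws):
        s1 = np.abs(noiseless + rng.normal(0, sigma, noiseless.shape))
        s2 = np.abs(noiseless + rng.normal(0, sigma, noiseless.shape))
        q1 = np.floor(255 * np.clip(s1, 0, 1) + 0.5)
        q2 = np.floor(255 * np.clip(s2, 0, 1) + 0.5)
        total += np.mean(q1 != q2)
    return total / n_draws
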