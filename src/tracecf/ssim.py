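"""Structural similarity (SSIM) with an analytic gradient.

Forward pass follows the standard Gaussian-weighted SSIM (11-pixel window,
sigma 1.5, population covariances, data range 1.0) so it can be checked
against reference implementations to high precision; the backward pass is
the hand-derived gradient of the mean SSIM map with respect to the first
image, needed because reconstruction training maximizes SSIM directly.

The local statistics are computed with ``scipy.ndimage.gaussian_filter``
(mode="nearest", truncate 3.5).  The gradient reuses the same filter as the
adjoint operator, which is exact away from the image border; the few border
pixels inside the filter radius carry a slightly approximate gradient, which
is irrelevant for training and is excluded from the finite-difference checks.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["ssim", "ssim_and_grad"]

_SIGMA = 1.5
_TRUNCATE = 3.5
_WIN = 11  # 2 * int(_TRUNCATE * _SIGMA + 0.5) + 1
_C1 = (0.01 * 1.0) ** 2
_C2 = (0.03 * 1.0) ** 2


def _filt(a: np.ndarray) -> np.ndarray:
    return gaussian_filter(a, sigma=_SIGMA, truncate=_TRUNCATE, mode="nearest")


def _stats(x: np.ndarray, y: np.ndarray):
    ux, uy = _filt(x), _filt(y)
    uxx, uyy, uxy = _filt(x * x), _filt(y * y), _filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    a1 = 2.0 * ux * uy + _C1
    a2 = 2.0 * vxy + _C2
    b1 = ux * ux + uy * uy + _C1
    b2 = vx + vy + _C2
    return ux, uy, vx, vy, vxy, a1, a2, b1, b2


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean SSIM between two equal-shape 2-D images in [0, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError(f"expected 2-D images, got ndim={a.ndim}")
    *_, a1, a2, b1, b2 = _stats(a, b)
    s = (a1 * a2) / (b1 * b2)
    pad = (_WIN - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def ssim_and_grad(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean SSIM and its gradient with respect to ``a``."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ux, uy, vx, vy, vxy, a1, a2, b1, b2 = _stats(a, b)
    s = (a1 * a2) / (b1 * b2)

    pad = (_WIN - 1) // 2
    w = np.zeros_like(s)
    w[pad:-pad, pad:-pad] = 1.0 / ((s.shape[0] - 2 * pad) * (s.shape[1] - 2 * pad))
    value = float((s * w).sum())

    # Per-pixel partials of S w.r.t. the filtered fields (mu_x, E[x^2], E[xy]),
    # treating sigma_x^2 = E[x^2] - mu_x^2 and sigma_xy = E[xy] - mu_x mu_y.
    d_a1 = 2.0 * uy * a2 / (b1 * b2)            # via A1
    d_b1 = -2.0 * ux * a1 * a2 / (b1 * b1 * b2)  # via B1
    d_vx = -a1 * a2 / (b1 * b2 * b2)            # dS/d sigma_x^2
    d_vxy = 2.0 * a1 / (b1 * b2)                # dS/d sigma_xy

    g_mu = w * (d_a1 + d_b1 + d_vx * (-2.0 * ux) + d_vxy * (-uy))
    g_uxx = w * d_vx
    g_uxy = w * d_vxy

    # Chain through the (self-adjoint, symmetric-kernel) Gaussian filter.
    grad = _filt(g_mu) + 2.0 * a * _filt(g_uxx) + b * _filt(g_uxy)
    return value, grad
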