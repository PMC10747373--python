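"""Non-local means denoising.

Each output pixel is a convex combination of the pixels in a search
window around it, weighted by patch similarity:

    NL(i) = sum_j w(i,j) I(j),
    w(i,j) = exp(-d(i,j) / (2 h^2)) / Z(i),   Z(i) = sum_j exp(-d(i,j)/(2 h^2)),

where d(i,j) is the mean squared difference between the square patches
centred on i and j, and h (the "sigma" of the smoothing sweep) sets how
tolerant the similarity weighting is.  Weights are non-negative and sum
to one for every pixel, so the output at each pixel lies within the
range of its search window.

Intensities are normalized to [0, 1] before weighting — by the image's
declared native ``value_range`` when present, else by its own min/max —
and restored afterwards, so h is expressed on a fixed scale (the sweep
grid 1e-3..1e-1 assumes this) and transfers between images from the
same detector.

Two evaluation paths are provided with an identical contract:
:func:`nlm_denoise` is the vectorized production path (one pass per
window offset, patch distances via a uniform filter);
:func:`nlm_denoise_reference` enumerates every (i, j) pair and exists as
the independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .core import RasterImage, as_image

__all__ = ["NLMParams", "nlm_denoise", "nlm_denoise_reference"]


@dataclass(frozen=True)
class NLMParams:
    """Smoothing factor and geometry of the NLM kernels.

    Defaults (patch_radius=1, window_radius=2, i.e. 3x3 patches compared
    inside 5x5 search windows) are the centred odd-sized equivalents of
    the nominal 2x2 patch/window sizes, which cannot be centred.
    """

    h: float
    patch_radius: int = 1
    window_radius: int = 2

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("h must be > 0")
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


def _normalize(img: RasterImage) -> tuple[np.ndarray, float, float]:
    """Map pixels to [0, 1]; returns (normalized, lo, scale)."""
    if img.value_range is not None:
        lo, hi = img.value_range
    else:
        lo, hi = float(img.pixels.min()), float(img.pixels.max())
    scale = hi - lo
    if scale <= 0:
        return np.zeros_like(img.pixels), lo, 1.0
    return (img.pixels - lo) / scale, lo, scale


def nlm_denoise(img: RasterImage | np.ndarray, params: NLMParams) -> RasterImage:
    """Vectorized NLM: one shifted-difference pass per window offset.

    Patch distances are computed on a reflect-padded copy of the image,
    so windows never shrink at the borders and the weights sum to one
    everywhere.  Bit-compatible with :func:`nlm_denoise_reference` (to
    floating-point summation order).
    """
    img = as_image(img)
    x, lo, scale = _normalize(img)
    p, w = params.patch_radius, params.window_radius
    inv = 1.0 / (2.0 * params.h**2)
    R = p + w
    pad = np.pad(x, R, mode="reflect")
    H, W = x.shape
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    size = 2 * p + 1
    for di in range(-w, w + 1):
        for dj in range(-w, w + 1):
            # squared differences over a patch-radius-expanded core so the
            # uniform filter sees no boundary of its own
            a = pad[R - p : R + p + H, R - p : R + p + W]
            b = pad[R - p + di : R + p + H + di, R - p + dj : R + p + W + dj]
            sq = (a - b) ** 2
            d = uniform_filter(sq, size=size)[p : p + H, p : p + W] if p > 0 else sq
            wt = np.exp(-d * inv)
            num += wt * pad[R + di : R + di + H, R + dj : R + dj + W]
            den += wt
    out = num / den
    return img.with_pixels(out * scale + lo)


def nlm_denoise_reference(
    img: RasterImage | np.ndarray, params: NLMParams
) -> RasterImage:
    """Brute-force NLM enumerating every (pixel, neighbour) pair.

    O(N * window^2 * patch^2); exists solely as the test oracle for the
    vectorized path.  Asserts the weight-normalization identity
    sum_j w(i,j) = 1 at every pixel.
    """
    img = as_image(img)
    x, lo, scale = _normalize(img)
    p, w = params.patch_radius, params.window_radius
    inv = 1.0 / (2.0 * params.h**2)
    R = p + w
    pad = np.pad(x, R, mode="reflect")
    H, W = x.shape
    out = np.empty_like(x)
    n_patch = (2 * p + 1) ** 2
    for i in range(H):
        for j in range(W):
            ci, cj = i + R, j + R
            weights = []
            values = []
            for di in range(-w, w + 1):
                for dj in range(-w, w + 1):
                    d = 0.0
                    for u in range(-p, p + 1):
                        for v in range(-p, p + 1):
                            diff = pad[ci + u, cj + v] - pad[ci + di + u, cj + dj + v]
                            d += diff * diff
                    d /= n_patch
                    weights.append(np.exp(-d * inv))
                    values.append(pad[ci + di, cj + dj])
            z = float(np.sum(weights))
            wts = np.asarray(weights) / z
            assert abs(wts.sum() - 1.0) < 1e-12, "weights must sum to 1"
            assert np.all(wts >= 0) and np.all(wts <= 1)
            out[i, j] = float(np.dot(wts, values))
    return img.with_pixels(out * scale + lo)
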