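"""Normalized noise power spectrum (NNPS) of a flat-field stack.

The 2-D NNPS is estimated from repeated flat-field ("white") exposures:
the ensemble-average frame S is subtracted from each frame, the
difference is tiled into overlapping square ROIs, and the periodograms
|DFT|^2 of all ROIs are averaged, scaled by the periodogram
normalization (dx*dy)/(Nx*Ny) and divided by the squared grand mean of
S.  The result has units of mm^2 and, for white noise of per-pixel
variance s^2 on a mean level mu, a flat value of s^2 * dx*dy / mu^2
(up to the 1 - 1/M variance absorbed by the ensemble-mean subtraction).

1-D curves are reduced from the 2-D surface the standard way: axial
curves average a band of lines flanking — and excluding — the
zero-frequency axes; the radial curve bins by radial frequency with a
bin width equal to the frequency sampling interval.  The DC bin and the
zero-frequency axes are excluded from every 1-D average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RasterImage

__all__ = ["FlatFieldStack", "NNPSResult", "nnps_2d", "nnps_1d", "nnps_radial"]


@dataclass
class FlatFieldStack:
    """Ordered collection of same-shape flat-field frames."""

    frames: np.ndarray  # (n_frames, H, W)
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        if isinstance(self.frames, (list, tuple)):
            pitches = {
                f.pixel_pitch_mm for f in self.frames if isinstance(f, RasterImage)
            }
            if len(pitches) > 1:
                raise ValueError("frames have inconsistent pixel pitch")
            self.frames = np.stack(
                [f.pixels if isinstance(f, RasterImage) else np.asarray(f, float)
                 for f in self.frames]
            )
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack needs >= 2 same-shape frames")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if not self.frames.mean() > 0:
            raise ValueError("ensemble-average signal must be positive")

    @classmethod
    def from_images(cls, frames, pixel_pitch_mm: float | None = None) -> "FlatFieldStack":
        if pixel_pitch_mm is None:
            first = frames[0]
            if isinstance(first, RasterImage) and first.pixel_pitch_mm:
                pixel_pitch_mm = first.pixel_pitch_mm
            else:
                raise ValueError("pixel_pitch_mm is required")
        return cls(frames, pixel_pitch_mm)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class NNPSResult:
    """2-D NNPS surface plus 1-D reductions.

    ``nnps2d`` is fftshifted so DC sits at index ``roi_size // 2`` on
    both axes; ``f_u``/``f_v`` are the matching shifted frequency axes
    (lp/mm; u = columns, v = rows).  All NNPS values are in mm^2.
    """

    nnps2d: np.ndarray
    f_u: np.ndarray
    f_v: np.ndarray
    pixel_pitch_mm: float
    roi_size: int
    n_rois: int
    freq_axis_1d: np.ndarray | None = None
    axial_u: np.ndarray | None = None
    axial_v: np.ndarray | None = None
    radial: np.ndarray | None = None
    band_halfwidth: int | None = None

    @property
    def nyquist_lpmm(self) -> float:
        return 1.0 / (2.0 * self.pixel_pitch_mm)

    @property
    def freq_step(self) -> float:
        return 1.0 / (self.roi_size * self.pixel_pitch_mm)


def _roi_starts(extent: int, roi: int, step: int) -> list[int]:
    starts = list(range(0, extent - roi + 1, step))
    return starts


def nnps_2d(
    stack: FlatFieldStack | list,
    roi_size: int = 128,
    overlap: float = 0.5,
    pixel_pitch_mm: float | None = None,
) -> NNPSResult:
    """2-D NNPS from a flat-field stack with overlapping-ROI averaging.

    Parameters
    ----------
    stack
        FlatFieldStack (or a list of RasterImage carrying their pitch).
    roi_size
        ROI side length in pixels; must be a power of two no larger
        than the smaller image dimension.
    overlap
        Fractional ROI overlap in [0, 1); 0.5 steps ROIs by half their
        size.
    """
    if not isinstance(stack, FlatFieldStack):
        stack = FlatFieldStack.from_images(stack, pixel_pitch_mm)
    frames = stack.frames
    n, H, W = frames.shape
    if roi_size < 2 or (roi_size & (roi_size - 1)) != 0:
        raise ValueError("roi_size must be a power of two >= 2")
    if roi_size > min(H, W):
        raise ValueError(f"roi_size {roi_size} exceeds image extent {min(H, W)}")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    S = frames.mean(axis=0)
    mu = float(S.mean())
    if mu <= 0:
        raise ValueError("zero or negative grand mean; NNPS undefined")
    step = max(1, int(round(roi_size * (1.0 - overlap))))
    rows = _roi_starts(H, roi_size, step)
    cols = _roi_starts(W, roi_size, step)
    n_rois = n * len(rows) * len(cols)
    if n_rois < 4:
        raise ValueError(
            f"only {n_rois} ROIs available; need >= 4 for a stable estimate"
        )
    acc = np.zeros((roi_size, roi_size))
    for k in range(n):
        diff = frames[k] - S
        for r0 in rows:
            for c0 in cols:
                roi = diff[r0 : r0 + roi_size, c0 : c0 + roi_size]
                acc += np.abs(np.fft.fft2(roi)) ** 2
    pitch = stack.pixel_pitch_mm
    scale = (pitch * pitch) / (roi_size * roi_size)
    nnps = np.fft.fftshift(acc / n_rois * scale / (mu * mu))
    f = np.fft.fftshift(np.fft.fftfreq(roi_size, d=pitch))
    return NNPSResult(
        nnps2d=nnps,
        f_u=f.copy(),
        f_v=f.copy(),
        pixel_pitch_mm=pitch,
        roi_size=roi_size,
        n_rois=n_rois,
    )


def nnps_1d(result: NNPSResult, band_halfwidth: int = 7) -> NNPSResult:
    """Fill the 1-D axial and radial curves of an NNPSResult (in place).

    ``axial_u`` averages the ``band_halfwidth`` rows on each side of the
    f_v = 0 axis (the axis itself excluded) as a function of f_u, folded
    over +/- f_u; ``axial_v`` is the transpose; ``radial`` bins all
    off-axis, non-DC values by sqrt(f_u^2 + f_v^2) with bin width equal
    to the frequency sampling interval.  Curves run from one frequency
    step up to Nyquist.
    """
    if result.nnps2d is None:
        raise ValueError("2-D NNPS missing")
    N = result.roi_size
    iz = N // 2  # DC index after fftshift
    if band_halfwidth < 1 or iz - band_halfwidth < 0:
        raise ValueError(f"band_halfwidth {band_halfwidth} exceeds the grid")
    df = result.freq_step
    half = N // 2  # bins at k*df, k = 1..half (half*df = Nyquist)
    freqs = df * np.arange(1, half + 1)

    def axial(mat: np.ndarray) -> np.ndarray:
        # mat rows = f_v, cols = f_u; average band rows around f_v=0
        band = np.concatenate(
            [
                mat[iz - band_halfwidth : iz, :],
                mat[iz + 1 : iz + 1 + band_halfwidth, :],
            ]
        ).mean(axis=0)
        out = np.empty(half)
        for k in range(1, half + 1):
            if k < half:
                out[k - 1] = 0.5 * (band[iz + k] + band[iz - k])
            else:  # Nyquist present only on the negative side (index 0)
                out[k - 1] = band[iz - k]
        return out

    result.axial_u = axial(result.nnps2d)
    result.axial_v = axial(result.nnps2d.T)

    fu = result.f_u[None, :]
    fv = result.f_v[:, None]
    rho = np.hypot(fu, fv)
    mask = (result.f_u[None, :] != 0) & (result.f_v[:, None] != 0)
    bins = np.rint(rho / df).astype(int)
    radial = np.full(half, np.nan)
    flat_bins = bins[mask]
    flat_vals = result.nnps2d[mask]
    for k in range(1, half + 1):
        sel = flat_bins == k
        if np.any(sel):
            radial[k - 1] = flat_vals[sel].mean()
    result.radial = radial
    result.freq_axis_1d = freqs
    result.band_halfwidth = band_halfwidth
    return result


def nnps_radial(
    stack: FlatFieldStack | list,
    roi_size: int = 128,
    overlap: float = 0.5,
    band_halfwidth: int = 7,
    pixel_pitch_mm: float | None = None,
) -> NNPSResult:
    """Convenience: 2-D estimate plus 1-D reductions in one call."""
    return nnps_1d(
        nnps_2d(stack, roi_size, overlap, pixel_pitch_mm), band_halfwidth
    )
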