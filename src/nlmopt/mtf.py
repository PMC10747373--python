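"""Presampled MTF by the slanted-edge method.

A nearly vertical edge, tilted a few degrees to stagger its sub-pixel
phase across rows, is projected onto the edge normal to build an
oversampled edge-spread function (ESF).  Central differencing gives the
line-spread function (LSF); a Hann window centred on the LSF peak
suppresses noise in the tails; |FFT| normalized at DC is the MTF.  Two
known instrument signatures of the estimator itself are divided out:
the boxcar aperture of the ESF binning and the transfer function of the
central-difference derivative (both sinc-shaped).  The summary scalar
is f10, the lowest frequency at which the MTF falls to 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RasterImage, RectROI, as_image

__all__ = ["MTFResult", "estimate_edge_angle", "compute_mtf"]


@dataclass
class MTFResult:
    """Presampled MTF curve and its 10%-MTF frequency.

    ``freq`` ascends from 0 to the presampled Nyquist (lp/mm); ``mtf``
    is normalized to exactly 1 at zero frequency.  ``f10_at_nyquist``
    flags the degenerate case where the curve never falls below 0.10
    before Nyquist (f10 is then reported as Nyquist).
    """

    freq: np.ndarray
    mtf: np.ndarray
    f10: float
    edge_angle_deg: float
    esf_oversample: int
    f10_at_nyquist: bool = False


def _row_edge_positions(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row edge position as the centroid of |row derivative|.

    Rows without a clear transition (derivative max not above 5x the row
    noise MAD) are dropped.  Returns (row indices, positions in columns,
    both for usable rows only).
    """
    rows = []
    pos = []
    half_window = 10  # centroid support around the derivative peak, px
    for r in range(sub.shape[0]):
        d = np.diff(sub[r].astype(np.float64))
        a = np.abs(d)
        mad = float(np.median(np.abs(d - np.median(d))))
        if not a.max() > 5.0 * mad:
            continue
        # the raw centroid of |d| is dragged toward the row centre by the
        # noise floor; localize around the peak and subtract the floor
        k0 = int(np.argmax(np.convolve(a, np.ones(3) / 3.0, mode="same")))
        lo = max(0, k0 - half_window)
        hi = min(len(a), k0 + half_window + 1)
        seg = np.clip(a[lo:hi] - 2.0 * mad, 0.0, None)
        total = seg.sum()
        if total <= 0:
            continue
        # derivative sample k sits between columns k and k+1
        centroid = float(np.dot(seg, np.arange(lo, hi) + 0.5) / total)
        rows.append(r)
        pos.append(centroid)
    return np.asarray(rows, dtype=float), np.asarray(pos, dtype=float)


def estimate_edge_angle(
    img: RasterImage | np.ndarray, roi: RectROI
) -> float:
    """Tilt of a roughly vertical edge, degrees from vertical.

    Least-squares line through the per-row edge centroids.  Raises when
    fewer than 10 rows show a detectable transition.
    """
    angle, _ = _fit_edge(as_image(img), roi)
    return angle


def _fit_edge(img: RasterImage, roi: RectROI) -> tuple[float, np.poly1d]:
    sub = roi.extract(img.pixels)
    rows, pos = _row_edge_positions(sub)
    if len(rows) < 10:
        raise ValueError(
            f"only {len(rows)} rows show a detectable edge transition; "
            "need >= 10 (is there an edge in the ROI?)"
        )
    slope, intercept = np.polyfit(rows, pos, 1)
    angle = float(np.degrees(np.arctan(slope)))
    return angle, np.poly1d([slope, intercept])


def _hann_centered(n: int, peak: int) -> np.ndarray:
    k = np.arange(n)
    w = np.cos(np.pi * (k - peak) / n) ** 2
    w[np.abs(k - peak) > n / 2] = 0.0
    return w


def compute_mtf(
    img: RasterImage | np.ndarray,
    roi: RectROI,
    oversample: int = 4,
    pixel_pitch_mm: float | None = None,
) -> MTFResult:
    """Presampled MTF from a tilted-edge image.

    Parameters
    ----------
    oversample
        Sub-pixel ESF binning factor (4 or 8): bin width is
        pitch / oversample.
    """
    image = as_image(img, pixel_pitch_mm)
    if image.pixel_pitch_mm is None:
        raise ValueError("pixel pitch is required for MTF in physical units")
    if oversample not in (4, 8):
        raise ValueError("oversample must be 4 or 8")
    pitch = image.pixel_pitch_mm
    angle, line = _fit_edge(image, roi)
    theta = np.radians(angle)
    sub = roi.extract(image.pixels)
    h, w = sub.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # signed distance of each pixel centre from the edge, along the normal
    dist_px = ((cc + 0.5) - line(rr + 0.5)) * np.cos(theta)
    binw = 1.0 / oversample  # in pixel units
    idx = np.floor(dist_px / binw).astype(int)
    lo = int(idx.min())
    idx -= lo
    nbins = int(idx.max()) + 1
    sums = np.bincount(idx.ravel(), weights=sub.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    filled = counts > 0
    if (~filled).mean() > 0.10:
        raise ValueError(
            f"{(~filled).sum()} of {nbins} ESF bins are empty (> 10%); "
            "the edge tilt is too small for this oversampling factor"
        )
    esf = np.full(nbins, np.nan)
    esf[filled] = sums[filled] / counts[filled]
    if not filled.all():
        x = np.arange(nbins)
        esf[~filled] = np.interp(x[~filled], x[filled], esf[filled])
    # trim a symmetric span around the edge so the LSF is centred-ish
    edge_bin = -lo  # bin holding normal distance 0
    margin = min(edge_bin, nbins - 1 - edge_bin)
    esf = esf[edge_bin - margin : edge_bin + margin + 1]
    n = len(esf)
    if n < 16:
        raise ValueError("edge span too short for MTF estimation")
    lsf = np.zeros(n)
    lsf[1:-1] = (esf[2:] - esf[:-2]) / 2.0
    lsf[0] = esf[1] - esf[0]
    lsf[-1] = esf[-1] - esf[-2]
    peak = int(np.argmax(np.abs(lsf)))
    lsf_w = lsf * _hann_centered(n, peak)
    spec = np.abs(np.fft.rfft(lsf_w))
    if spec[0] == 0:
        raise ValueError("zero DC response; no edge contrast in the ROI")
    binw_mm = binw * pitch
    freq = np.fft.rfftfreq(n, d=binw_mm)
    mtf = spec / spec[0]
    # divide out estimator signatures: ESF binning aperture and the
    # central-difference derivative response (both exactly sinc)
    corr = np.sinc(freq * binw_mm) * np.sinc(2.0 * freq * binw_mm)
    corr = np.where(np.abs(corr) < 1e-6, 1.0, corr)
    mtf = mtf / np.abs(corr)
    nyq = 1.0 / (2.0 * pitch)
    keep = freq <= nyq + 1e-12
    freq, mtf = freq[keep], mtf[keep]
    mtf = np.clip(mtf, 0.0, None)
    mtf[0] = 1.0
    below = np.nonzero(mtf < 0.10)[0]
    below = below[below > 0]
    if len(below):
        i = below[0]
        f0, f1 = freq[i - 1], freq[i]
        m0, m1 = mtf[i - 1], mtf[i]
        f10 = float(f0 + (f1 - f0) * (m0 - 0.10) / (m0 - m1))
        at_nyq = False
    else:
        f10 = float(nyq)
        at_nyq = True
    return MTFResult(
        freq=freq,
        mtf=mtf,
        f10=f10,
        edge_angle_deg=angle,
        esf_oversample=oversample,
        f10_at_nyquist=at_nyq,
    )
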