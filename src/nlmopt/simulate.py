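"""Synthetic scintillator + sensor image chain.

The simulator emulates an indirect X-ray detector (Gd2O2S:Tb screen on a
CMOS sensor, 48 um pitch) as a parameterized blur/noise chain:

    ideal scene -> Gaussian scintillator PSF -> gain -> Poisson sampling
               -> additive Gaussian read noise -> quantize/clip

Scintillator thickness is represented operationally, not physically: a
thicker screen converts more light (higher gain, cleaner image) but
spreads it further (wider PSF, blurrier image).  Two named presets,
``"thin"`` and ``"thick"``, encode the two operating points the
optimization framework assumes — thin = sharper + noisier, thick =
blurrier + cleaner.

Scenes are rendered noiselessly first (:func:`render_scene`) and pushed
through the detector chain with :func:`expose`; flat-field ensembles for
noise-power analysis come from :func:`make_flat_stack`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import RasterImage, RectROI

__all__ = [
    "DetectorConfig",
    "SceneSpec",
    "detector_preset",
    "render_scene",
    "expose",
    "make_flat_stack",
    "simulate_edge_pair",
    "SimulatedPair",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Operating point of the simulated scintillator + sensor chain.

    Parameters
    ----------
    psf_sigma_mm
        Standard deviation of the Gaussian scintillator blur, mm.
    gain
        Expected detected quanta per unit incident fluence (> 0).
    read_noise
        Additive zero-mean Gaussian noise, detector counts.
    pixel_pitch_mm
        Sampling pitch, mm (48 um default).
    bit_depth
        Output quantization depth in bits.
    seed
        Base RNG seed; all randomness derives from it.
    """

    psf_sigma_mm: float
    gain: float
    read_noise: float
    pixel_pitch_mm: float = 0.048
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def max_count(self) -> float:
        return float(2**self.bit_depth - 1)


# Preset operating points.  They reproduce the qualitative thin-vs-thick
# ordering (thin sharper but noisier) with both operating points usable
# by the measurement stack: at the default fluence of 750 the thin
# detector's total noise is ~0.5% of full scale, which places the NLM
# weight transition inside the standard h grid [1e-3, 1e-1], and both
# PSFs are wide enough that the 10%-MTF frequency falls strictly below
# Nyquist.  Package defaults, not measurements of any physical screen.
_PRESETS = {
    "thin": dict(psf_sigma_mm=0.050, gain=40.0, read_noise=280.0),
    "thick": dict(psf_sigma_mm=0.100, gain=80.0, read_noise=60.0),
}


def detector_preset(name: str, seed: int = 0) -> DetectorConfig:
    """Return the named detector preset (``"thin"`` or ``"thick"``)."""
    try:
        kwargs = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown detector preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return DetectorConfig(seed=seed, **kwargs)


@dataclass(frozen=True)
class SceneSpec:
    """Description of a noiseless test scene.

    kind
        ``"flat"`` (uniform field), ``"line_pairs"`` (bands of square-wave
        bar groups), or ``"edge"`` (tilted two-level step).
    fluence
        Mean incident intensity, arbitrary units > 0.
    line_groups
        For ``line_pairs``: list of ``(frequency lp/mm, contrast in (0,1])``.
    edge_angle_deg
        For ``edge``: tilt of the edge from vertical, degrees (0..10).
    edge_contrast
        For ``edge``: 1 gives a dark side of zero; ``c`` gives
        ``fluence*(1-c)``.
    """

    kind: str
    fluence: float = 750.0
    line_groups: tuple[tuple[float, float], ...] = ()
    edge_angle_deg: float = 3.0
    edge_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"flat", "line_pairs", "edge"}:
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if not self.fluence > 0:
            raise ValueError("fluence must be > 0")
        if self.kind == "edge":
            if not (0.0 <= self.edge_angle_deg <= 10.0):
                raise ValueError("edge_angle_deg must be in [0, 10] degrees")
            if not (0.0 < self.edge_contrast <= 1.0):
                raise ValueError("edge_contrast must be in (0, 1]")
        if self.kind == "line_pairs":
            if not self.line_groups:
                raise ValueError("line_pairs scene needs at least one group")
            for f, c in self.line_groups:
                if not f > 0 or not (0.0 < c <= 1.0):
                    raise ValueError(f"invalid line group ({f}, {c})")
        object.__setattr__(self, "line_groups", tuple(tuple(g) for g in self.line_groups))


def _clipped_linear_integral(a: float, t: float, y0: float, y1: float) -> float:
    """Integral of clip(a - t*y, 0, 1) over [y0, y1], exactly.

    The integrand is piecewise linear; trapezoid rule between the clip
    breakpoints is exact.
    """
    pts = [y0, y1]
    if t != 0.0:
        for target in (0.0, 1.0):
            y = (a - target) / t
            if y0 < y < y1:
                pts.append(y)
    pts.sort()
    g = lambda y: min(1.0, max(0.0, a - t * y))
    total = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        total += 0.5 * (g(lo) + g(hi)) * (hi - lo)
    return total


def edge_bright_fraction(row: int, col: int, x0: float, tan_theta: float) -> float:
    """Exact area fraction of pixel (row, col) on the bright side of the
    edge line ``x = x0 + tan_theta * y`` (bright side is x > line).

    Pixel (row, col) covers x in [col, col+1), y in [row, row+1).
    """
    # length of the bright strip at height y: clip(col+1 - x0 - t*y, 0, 1)
    return _clipped_linear_integral(col + 1.0 - x0, tan_theta, float(row), float(row) + 1.0)


def _render_edge(spec: SceneSpec, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    t = math.tan(math.radians(spec.edge_angle_deg))
    # edge passes through the image centre at mid-height
    x0 = w / 2.0 - t * h / 2.0
    bright = spec.fluence
    dark = spec.fluence * (1.0 - spec.edge_contrast)
    out = np.empty(shape, dtype=np.float64)
    cols = np.arange(w)
    for r in range(h):
        xe_top = x0 + t * r
        xe_bot = x0 + t * (r + 1)
        lo, hi = min(xe_top, xe_bot), max(xe_top, xe_bot)
        frac = np.where(cols >= hi, 1.0, 0.0)
        # boundary columns need the exact sub-pixel area
        for c in range(max(0, int(math.floor(lo)) - 1), min(w, int(math.ceil(hi)) + 1)):
            frac[c] = edge_bright_fraction(r, c, x0, t)
        out[r] = dark + (bright - dark) * frac
    return out


def _render_line_pairs(
    spec: SceneSpec, shape: tuple[int, int], pitch_mm: float
) -> np.ndarray:
    h, w = shape
    nyq = 1.0 / (2.0 * pitch_mm)
    for f, _ in spec.line_groups:
        if f >= nyq:
            raise ValueError(
                f"line group at {f} lp/mm is at or above the Nyquist "
                f"frequency {nyq:.3f} lp/mm for pitch {pitch_mm} mm"
            )
    out = np.empty(shape, dtype=np.float64)
    n_groups = len(spec.line_groups)
    band = h / n_groups
    x_mm = (np.arange(w) + 0.5) * pitch_mm
    for k, (f, c) in enumerate(spec.line_groups):
        phase = (x_mm * f) % 1.0
        row_vals = np.where(phase < 0.5, spec.fluence, spec.fluence * (1.0 - c))
        r0, r1 = int(round(k * band)), int(round((k + 1) * band))
        out[r0:r1] = row_vals
    return out


def render_scene(
    spec: SceneSpec, shape: tuple[int, int], pitch_mm: float
) -> RasterImage:
    """Render the noiseless ideal scene at the given shape and pitch.

    Edge scenes use exact per-pixel area fractions on boundary pixels,
    which makes the rendered edge an analytic reference for the
    slanted-edge MTF (pure pixel-aperture response).
    """
    h, w = (int(shape[0]), int(shape[1]))
    if h < 2 or w < 2:
        raise ValueError("scene shape must be at least 2x2")
    if spec.kind == "flat":
        arr = np.full((h, w), float(spec.fluence))
    elif spec.kind == "edge":
        arr = _render_edge(spec, (h, w))
    else:
        arr = _render_line_pairs(spec, (h, w), pitch_mm)
    return RasterImage(arr, pixel_pitch_mm=pitch_mm)


def expose(scene: RasterImage, det: DetectorConfig) -> RasterImage:
    """Push a noiseless scene through the detector chain.

    The fixed pipeline order is: Gaussian PSF blur (reflective
    boundaries), gain scaling, per-pixel Poisson sampling, additive
    Gaussian read noise, clip to the quantizer range and round to
    integer counts.  Same seed + same inputs -> bit-identical output.
    """
    arr = scene.pixels
    if np.any(arr < 0):
        raise ValueError("scene must be non-negative")
    sigma_px = det.psf_sigma_mm / det.pixel_pitch_mm
    blurred = gaussian_filter(arr, sigma=sigma_px, mode="reflect") if sigma_px > 0 else arr
    expected = blurred * det.gain
    rng = np.random.default_rng(det.seed)
    counts = rng.poisson(expected).astype(np.float64)
    if det.read_noise > 0:
        counts = counts + rng.normal(0.0, det.read_noise, size=counts.shape)
    counts = np.clip(np.rint(counts), 0.0, det.max_count)
    return RasterImage(
        counts,
        pixel_pitch_mm=det.pixel_pitch_mm,
        value_range=(0.0, det.max_count),
    )


def make_flat_stack(
    det: DetectorConfig,
    n_frames: int,
    fluence: float,
    shape: tuple[int, int] = (512, 1024),
) -> list[RasterImage]:
    """Repeated flat-field ("white") exposures of the same scene.

    Frames differ only by their noise realization; the per-frame seed is
    ``det.seed + frame_index`` so the whole stack is a pure function of
    the config.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (ensemble averaging needs >= 2)")
    scene = render_scene(
        SceneSpec(kind="flat", fluence=fluence), shape, det.pixel_pitch_mm
    )
    return [expose(scene, replace(det, seed=det.seed + i)) for i in range(n_frames)]


@dataclass(frozen=True)
class SimulatedPair:
    """A matched thin/thick acquisition of the same edge scene, with the
    ROI layout the sweep needs (edge-bearing EPI ROI, homogeneous SNR
    ROI on the bright side, and an MTF ROI spanning the edge)."""

    thin: RasterImage
    thick: RasterImage
    scene: RasterImage
    epi_roi: RectROI
    snr_roi: RectROI
    mtf_roi: RectROI
    thin_det: DetectorConfig
    thick_det: DetectorConfig


def simulate_edge_pair(
    shape: tuple[int, int] = (256, 256),
    seed: int = 1,
    fluence: float = 750.0,
    edge_angle_deg: float = 2.8,
    edge_contrast: float = 0.75,
) -> SimulatedPair:
    """Standard simulated study: one tilted-edge scene imaged by both
    detector presets, with ROIs for the EPI/SNR sweep and the MTF.

    The two exposures use distinct seeds derived from ``seed`` so the
    noise realizations are independent.
    """
    thin_det = detector_preset("thin", seed=int(seed))
    thick_det = detector_preset("thick", seed=int(seed) + 10_000)
    spec = SceneSpec(
        kind="edge",
        fluence=fluence,
        edge_angle_deg=edge_angle_deg,
        edge_contrast=edge_contrast,
    )
    scene = render_scene(spec, shape, thin_det.pixel_pitch_mm)
    thin = expose(scene, thin_det)
    thick = expose(scene, thick_det)
    h, w = shape
    # edge runs through the centre column; EPI ROI straddles it
    epi_roi = RectROI(h // 4, w // 2 - w // 8, h // 2, w // 4)
    # SNR ROI sits well inside the bright (right) side, clear of the edge
    snr_roi = RectROI(h // 4, w - w // 4 - 4, h // 2, w // 8)
    mtf_roi = RectROI(h // 4, w // 2 - w // 8, h // 2, w // 4)
    return SimulatedPair(
        thin=thin,
        thick=thick,
        scene=scene,
        epi_roi=epi_roi,
        snr_roi=snr_roi,
        mtf_roi=mtf_roi,
        thin_det=thin_det,
        thick_det=thick_det,
    )
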