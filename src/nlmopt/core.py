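"""Core containers shared by every stage of the pipeline.

Conventions used throughout the package (enforced here, once):

* images are 2-D, row-major, 0-based;
* rectangular ROIs are half-open: rows ``[row0, row0 + height)``,
  columns ``[col0, col0 + width)``;
* spatial frequencies are in lp/mm and pixel pitch in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RasterImage",
    "RectROI",
    "CapabilityError",
    "HomogeneousROIError",
    "NoCrossingError",
    "as_image",
]


class CapabilityError(RuntimeError):
    """An optional capability (extra dependency group) is not installed."""


class HomogeneousROIError(ValueError):
    """An ROI is constant where a spread statistic is required."""


class NoCrossingError(RuntimeError):
    """A sweep produced no EPI/SNR crossing, so no optimal h exists."""


@dataclass(frozen=True)
class RectROI:
    """Rectangular region selector, half-open in both axes."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        for name in ("row0", "col0", "height", "width"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"RectROI.{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("RectROI corner must be non-negative")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("RectROI extent must be positive")
        if self.height * self.width < 4:
            raise ValueError("RectROI must cover at least 4 pixels")

    @classmethod
    def parse(cls, text: str) -> "RectROI":
        """Parse the CLI form ``"row0,col0,height,width"``."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError(f"ROI must be 'row0,col0,height,width', got {text!r}")
        return cls(*(int(p) for p in parts))

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0] or self.col0 + self.width > shape[1]:
            raise ValueError(
                f"ROI {self} exceeds image of shape {shape[0]}x{shape[1]}"
            )

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        self.validate_for(pixels.shape)
        return pixels[self.slices]

    def overlaps(self, other: "RectROI") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )


@dataclass
class RasterImage:
    """2-D grayscale intensity grid with physical pixel pitch.

    Parameters
    ----------
    pixels
        2-D array of finite real intensities (stored as float64).
    pixel_pitch_mm
        Sampling pitch in mm.  May be ``None`` for images without a
        physical scale; stages that need physical units reject that.
    value_range
        ``(lo, hi)`` of the native intensity scale, e.g. ``(0, 65535)``
        for a 16-bit detector.  Used by the denoiser so its smoothing
        factor is expressed on a fixed normalized scale; when absent the
        image's own min/max are used instead.
    """

    pixels: np.ndarray
    pixel_pitch_mm: float | None = None
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"image must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite pixels")
        self.pixels = arr
        if self.pixel_pitch_mm is not None:
            if not (float(self.pixel_pitch_mm) > 0):
                raise ValueError("pixel_pitch_mm must be > 0")
            self.pixel_pitch_mm = float(self.pixel_pitch_mm)
        if self.value_range is not None:
            lo, hi = (float(v) for v in self.value_range)
            if not hi > lo:
                raise ValueError("value_range must satisfy hi > lo")
            self.value_range = (lo, hi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def nyquist_lpmm(self) -> float:
        if self.pixel_pitch_mm is None:
            raise ValueError("image has no pixel pitch; pass pixel_pitch_mm")
        return 1.0 / (2.0 * self.pixel_pitch_mm)

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        """New image with the same pitch/value-range metadata."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


def as_image(obj, pixel_pitch_mm: float | None = None) -> RasterImage:
    """Coerce an array or RasterImage to a RasterImage."""
    if isinstance(obj, RasterImage):
        return obj
    return RasterImage(np.asarray(obj), pixel_pitch_mm=pixel_pitch_mm)
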