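"""Image and result I/O.

Images travel as 16-bit grayscale TIFF (primary), PNG, or headerless
raw; values are never rescaled on read.  Curve results go to CSV
(UTF-8, header row, '.' decimal separator, 17 significant digits, so a
round trip reproduces the floats exactly); scalars and settings go to
JSON sidecars.  Every CLI run writes a sidecar capturing its effective
parameters and the package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import RasterImage
from .mtf import MTFResult
from .nnps import NNPSResult
from .sweep import SweepResult, SweepResults

__all__ = [
    "read_image",
    "read_stack",
    "write_image",
    "write_results",
    "read_curve_csv",
    "sidecar_path",
    "write_sidecar",
]

_INT_RANGES = {
    np.dtype(np.uint8): (0.0, 255.0),
    np.dtype(np.uint16): (0.0, 65535.0),
    np.dtype(np.int16): (0.0, 32767.0),
}


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_sidecar(path: str | Path, params: dict) -> Path:
    """JSON sidecar with all effective parameters (reproducibility contract)."""
    side = sidecar_path(path)
    payload = dict(params)
    payload.setdefault("package_version", __version__)
    side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return side


def _attach_meta(arr: np.ndarray, pitch: float | None) -> RasterImage:
    vr = _INT_RANGES.get(arr.dtype)
    return RasterImage(arr, pixel_pitch_mm=pitch, value_range=vr)


def _pitch_from_sidecar(path: Path) -> float | None:
    side = sidecar_path(path)
    if side.exists():
        try:
            return json.loads(side.read_text()).get("pixel_pitch_mm")
        except (json.JSONDecodeError, OSError):
            return None
    return None


def read_image(
    path: str | Path,
    pixel_pitch_mm: float | None = None,
    *,
    shape: tuple[int, int] | None = None,
    dtype: str | None = None,
):
    """Read a grayscale image (or multi-page stack) from disk.

    Returns a :class:`RasterImage`, or a list of them for multi-page
    TIFFs (page order preserved).  RGB inputs are rejected: convert to
    single-channel grayscale first (e.g. with ImageMagick or
    ``skimage.color.rgb2gray``).  The explicit ``pixel_pitch_mm``
    argument wins over a sidecar value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pitch = pixel_pitch_mm if pixel_pitch_mm is not None else _pitch_from_sidecar(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    elif suffix in {".raw", ".bin"}:
        if shape is None or dtype is None:
            raise ValueError("raw input needs explicit shape= and dtype=")
        arr = np.fromfile(path, dtype=np.dtype(dtype)).reshape(shape)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            "RGB(A) input is not supported: convert to single-channel "
            "grayscale before reading"
        )
    if arr.ndim == 3:  # multi-page stack
        return [_attach_meta(page, pitch) for page in arr]
    return _attach_meta(arr, pitch)


def read_stack(path: str | Path, pixel_pitch_mm: float | None = None) -> list[RasterImage]:
    """Read a multi-page TIFF as an ordered frame list."""
    frames = read_image(path, pixel_pitch_mm)
    if isinstance(frames, RasterImage):
        frames = [frames]
    return frames


def write_image(
    img: RasterImage | list[RasterImage],
    path: str | Path,
    *,
    sidecar: dict | None = None,
) -> Path:
    """Write a RasterImage (or frame list, as multi-page TIFF) to disk.

    Values are rounded and clipped to the image's declared value_range
    (16-bit full scale when none is declared).
    """
    path = Path(path)
    frames = img if isinstance(img, list) else [img]
    first = frames[0]
    lo, hi = first.value_range or (0.0, 65535.0)
    dtype = np.uint8 if hi <= 255 else np.uint16
    pages = [
        np.clip(np.rint(f.pixels), lo, hi).astype(dtype) for f in frames
    ]
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(
            path,
            pages[0] if len(pages) == 1 else np.stack(pages),
            photometric="minisblack",
        )
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if len(pages) > 1:
            raise ValueError("PNG cannot hold a multi-frame stack; use TIFF")
        iio.imwrite(path, pages[0])
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")
    meta = dict(sidecar or {})
    if first.pixel_pitch_mm is not None:
        meta.setdefault("pixel_pitch_mm", first.pixel_pitch_mm)
    write_sidecar(path, meta)
    return path


_FLOAT_FMT = "%.17g"


def _write_curves(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def write_results(result, path: str | Path, *, settings: dict | None = None) -> Path:
    """Write a result object: CSV for its curves, JSON sidecar for scalars.

    Accepts SweepResult(s), NNPSResult, MTFResult, or a plain dict of
    scalars (JSON only).
    """
    path = Path(path)
    meta = dict(settings or {})
    if isinstance(result, SweepResults):
        result = result.raw
    if isinstance(result, SweepResult):
        df = pd.DataFrame(
            {"h": result.h_grid, "epi": result.epi_curve,
             "snr_norm": result.snr_norm_curve}
        )
        _write_curves(df, path)
        meta.update(
            status=result.status,
            optimal_h=result.optimal_h,
            crossing_index=result.crossing_index,
            grid_spacing=result.grid_spacing,
        )
    elif isinstance(result, NNPSResult):
        if result.freq_axis_1d is None:
            raise ValueError("run nnps_1d before writing NNPS results")
        df = pd.DataFrame(
            {
                "frequency_lpmm": result.freq_axis_1d,
                "axial_u": result.axial_u,
                "axial_v": result.axial_v,
                "radial": result.radial,
            }
        )
        _write_curves(df, path)
        meta.update(
            n_rois=result.n_rois,
            roi_size=result.roi_size,
            pixel_pitch_mm=result.pixel_pitch_mm,
            band_halfwidth=result.band_halfwidth,
        )
    elif isinstance(result, MTFResult):
        df = pd.DataFrame({"frequency_lpmm": result.freq, "mtf": result.mtf})
        _write_curves(df, path)
        meta.update(
            f10_lpmm=result.f10,
            edge_angle_deg=result.edge_angle_deg,
            esf_oversample=result.esf_oversample,
            f10_at_nyquist=result.f10_at_nyquist,
        )
    elif isinstance(result, dict):
        path.write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        if settings:
            write_sidecar(path, meta)
        return path
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    write_sidecar(path, meta)
    return path


def read_curve_csv(path: str | Path) -> pd.DataFrame:
    """Read back a curve CSV written by :func:`write_results`."""
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
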