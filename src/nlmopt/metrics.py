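"""Scalar image-quality measures.

* :func:`epi` — edge preservation index: normalized cross-correlation of
  mean-subtracted Laplacian responses of a reference and a measured
  image over an ROI.  1 means sharpness fully preserved, -1 means the
  edge field is inverted.
* :func:`roi_snr` — ROI mean divided by ROI (population) standard
  deviation on a nominally uniform region.
* :func:`no_reference_score` — adapter hook for a no-reference
  perceptual score (BRISQUE); delegates to an installed backend and is
  otherwise a capability error.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .core import CapabilityError, HomogeneousROIError, RasterImage, RectROI, as_image

__all__ = ["epi", "roi_snr", "no_reference_score", "LAPLACIAN_KERNEL"]

# 4-neighbour discrete Laplacian; applied to the full image before ROI
# extraction so the ROI sees no filter-boundary artefacts.
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _laplacian(pixels: np.ndarray) -> np.ndarray:
    return convolve(pixels, LAPLACIAN_KERNEL, mode="reflect")


def epi(
    reference: RasterImage | np.ndarray,
    measured: RasterImage | np.ndarray,
    roi: RectROI,
) -> float:
    """Edge preservation index of ``measured`` against ``reference``.

    Both images are Laplacian-filtered over their full extent; the
    responses are restricted to ``roi``, mean-subtracted and correlated:

        EPI = G(a, b) / sqrt(G(a, a) * G(b, b)),   G(a, b) = sum a*b.

    Symmetric in its arguments and invariant to positive affine
    rescaling of either image.
    """
    ref = as_image(reference)
    mea = as_image(measured)
    if ref.shape != mea.shape:
        raise ValueError(
            f"shape mismatch: reference {ref.shape} vs measured {mea.shape}"
        )
    roi.validate_for(ref.shape)
    a = _laplacian(ref.pixels)[roi.slices]
    b = _laplacian(mea.pixels)[roi.slices]
    a = a - a.mean()
    b = b - b.mean()
    gaa = float(np.sum(a * a))
    gbb = float(np.sum(b * b))
    if gaa == 0.0 or gbb == 0.0:
        raise HomogeneousROIError(
            "Laplacian response is constant within the ROI; EPI is undefined"
        )
    return float(np.sum(a * b) / np.sqrt(gaa * gbb))


def roi_snr(img: RasterImage | np.ndarray, roi: RectROI) -> float:
    """Mean / population standard deviation over the ROI."""
    arr = roi.extract(as_image(img).pixels)
    std = float(arr.std())  # population (divisor N)
    if std == 0.0:
        raise HomogeneousROIError("homogeneous ROI: standard deviation is zero")
    return float(arr.mean()) / std


def no_reference_score(img: RasterImage | np.ndarray, backend=None) -> float:
    """No-reference perceptual quality score (lower = more natural).

    Delegates to a BRISQUE implementation: either an explicit callable
    ``backend`` mapping a 2-D float array to a scalar, or an installed
    OpenCV-contrib quality module.  The score's internals are
    deliberately out of scope here; this function only adapts.
    """
    image = as_image(img)
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise ValueError("no-reference scoring needs an image of at least 64x64")
    if backend is not None:
        return float(backend(image.pixels))
    try:  # pragma: no cover - exercised only when opencv-contrib exists
        import cv2  # type: ignore

        scorer = cv2.quality.QualityBRISQUE_create(  # noqa: attr-defined
            "brisque_model_live.yml", "brisque_range_live.yml"
        )
    except Exception as exc:
        raise CapabilityError(
            "no BRISQUE backend installed; install the optional dependency "
            "group 'nlmopt[brisque]' or pass backend=..."
        ) from exc
    arr = image.pixels
    lo, hi = image.value_range or (arr.min(), arr.max())
    arr8 = np.clip((arr - lo) / max(hi - lo, 1e-12) * 255.0, 0, 255).astype(np.uint8)
    return float(scorer.compute(arr8)[0])  # pragma: no cover
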