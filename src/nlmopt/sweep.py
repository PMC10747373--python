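"""Smoothing-parameter selection by the EPI / normalized-SNR crossing.

The thin-detector image is denoised at every h on a fixed grid
(100 log-spaced steps over [1e-3, 1e-1] by default).  Two curves are
traced against h:

* EPI of the denoised image against the thin input itself (sharpness
  retained; starts near 1 and falls as smoothing grows);
* ROI SNR of the denoised image divided by the ROI SNR of the
  thick-detector image (noise removed, on the same 0..~1 scale as EPI;
  rises with smoothing).

The first h where the curves cross is the selected smoothing factor:
the denoised thin image then matches the thick detector's noise level
while giving up as little sharpness as possible.

The sweep is exposed statsmodels-style: build an :class:`NLMSweep`
model from the image pair, call :meth:`NLMSweep.fit`, and read the
selection off the returned :class:`SweepResults` (``summary()``,
``plot()``, ``apply()``).  The plain-function surface
(:func:`run_sweep`, :func:`select_optimal_h`, :func:`apply_optimal`)
wraps the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import HomogeneousROIError, NoCrossingError, RasterImage, RectROI, as_image
from .metrics import epi, roi_snr
from .nlm import NLMParams, nlm_denoise

__all__ = [
    "SweepConfig",
    "SweepResult",
    "NLMSweep",
    "SweepResults",
    "run_sweep",
    "select_optimal_h",
    "apply_optimal",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid and ROI layout of a smoothing sweep."""

    epi_roi: RectROI
    snr_roi: RectROI
    h_min: float = 1e-3
    h_max: float = 1e-1
    n_steps: int = 100
    grid_spacing: str = "log"
    nlm: NLMParams = field(default_factory=lambda: NLMParams(h=1e-2))

    def __post_init__(self) -> None:
        if not (0 < self.h_min < self.h_max):
            raise ValueError("need 0 < h_min < h_max")
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        if self.grid_spacing not in {"log", "linear"}:
            raise ValueError("grid_spacing must be 'log' or 'linear'")
        if self.epi_roi.overlaps(self.snr_roi):
            raise ValueError("epi_roi and snr_roi must be disjoint")

    def grid(self) -> np.ndarray:
        if self.grid_spacing == "log":
            return np.logspace(
                np.log10(self.h_min), np.log10(self.h_max), self.n_steps
            )
        return np.linspace(self.h_min, self.h_max, self.n_steps)


@dataclass
class SweepResult:
    """Raw sweep outcome: the h grid, both curves, and the crossing."""

    h_grid: np.ndarray
    epi_curve: np.ndarray
    snr_norm_curve: np.ndarray
    grid_spacing: str = "log"
    crossing_index: int | None = None
    optimal_h: float | None = None
    status: str = "no_crossing"


def select_optimal_h(result: SweepResult) -> float | None:
    """Locate the first EPI / normalized-SNR crossing on the grid.

    An exact tie at a grid point selects that point; otherwise the first
    sign change of d = EPI - SNR_norm is interpolated linearly to d = 0
    — in log10(h) on a log grid, in h on a linear grid.  Fills
    ``crossing_index``, ``optimal_h`` and ``status`` on ``result`` and
    returns the optimal h (``None`` when the curves never cross).
    """
    h = np.asarray(result.h_grid, dtype=float)
    d = np.asarray(result.epi_curve, float) - np.asarray(result.snr_norm_curve, float)
    if len(h) != len(d) or len(h) < 2:
        raise ValueError("curves must be populated and match the grid")
    ties = np.nonzero(d == 0.0)[0]
    if len(ties):
        i = int(ties[0])
        result.crossing_index = i
        result.optimal_h = float(h[i])
        result.status = "crossed"
        return result.optimal_h
    sign_change = np.nonzero(d[:-1] * d[1:] < 0.0)[0]
    if not len(sign_change):
        result.crossing_index = None
        result.optimal_h = None
        result.status = "no_crossing"
        return None
    i = int(sign_change[0])
    frac = d[i] / (d[i] - d[i + 1])
    if result.grid_spacing == "log":
        x0, x1 = np.log10(h[i]), np.log10(h[i + 1])
        h_star = float(10.0 ** (x0 + (x1 - x0) * frac))
    else:
        h_star = float(h[i] + (h[i + 1] - h[i]) * frac)
    result.crossing_index = i
    result.optimal_h = h_star
    result.status = "crossed"
    return h_star


def run_sweep(
    thin: RasterImage, thick: RasterImage, cfg: SweepConfig
) -> SweepResult:
    """Trace EPI and normalized SNR over the h grid and pick the crossing."""
    thin = as_image(thin)
    thick = as_image(thick)
    if thin.shape != thick.shape:
        raise ValueError(f"thin {thin.shape} and thick {thick.shape} shapes differ")
    cfg.epi_roi.validate_for(thin.shape)
    cfg.snr_roi.validate_for(thin.shape)
    snr_thick = roi_snr(thick, cfg.snr_roi)
    if snr_thick == 0:
        raise ValueError("thick-image SNR is zero; normalization undefined")
    grid = cfg.grid()
    epi_curve = np.empty_like(grid)
    snr_curve = np.empty_like(grid)
    for i, h in enumerate(grid):
        try:
            denoised = nlm_denoise(thin, replace(cfg.nlm, h=float(h)))
            epi_curve[i] = epi(thin, denoised, cfg.epi_roi)
            snr_curve[i] = roi_snr(denoised, cfg.snr_roi) / snr_thick
        except (ValueError, HomogeneousROIError) as exc:
            raise type(exc)(f"sweep step {i} (h={h:.6g}): {exc}") from exc
    result = SweepResult(
        h_grid=grid,
        epi_curve=epi_curve,
        snr_norm_curve=snr_curve,
        grid_spacing=cfg.grid_spacing,
    )
    select_optimal_h(result)
    return result


def apply_optimal(
    thin: RasterImage, result: SweepResult, nlm_params: NLMParams
) -> RasterImage:
    """Denoise ``thin`` at the selected h (bit-identical to calling the
    denoiser directly)."""
    if result.status != "crossed" or result.optimal_h is None:
        raise NoCrossingError(
            "sweep found no EPI/SNR crossing; no optimal h to apply"
        )
    return nlm_denoise(thin, replace(nlm_params, h=float(result.optimal_h)))


class NLMSweep:
    """Smoothing-parameter selection model for a thin/thick image pair.

    Parameters
    ----------
    thin, thick
        Same-shape images of the same scene from the sharp/noisy and
        blurry/clean detectors.
    epi_roi
        Edge-bearing region where sharpness retention is scored.
    snr_roi
        Homogeneous region where noise is scored; must be disjoint from
        ``epi_roi``.
    h_min, h_max, n_steps, grid_spacing
        The h grid (defaults: 100 log-spaced steps over [1e-3, 1e-1]).
    nlm_params
        Patch/window geometry; ``h`` is overridden per step.

    Examples
    --------
    >>> model = NLMSweep(thin, thick, epi_roi=er, snr_roi=sr)   # doctest: +SKIP
    >>> res = model.fit()                                       # doctest: +SKIP
    >>> res.optimal_h, res.status                               # doctest: +SKIP
    """

    def __init__(
        self,
        thin: RasterImage,
        thick: RasterImage,
        *,
        epi_roi: RectROI,
        snr_roi: RectROI,
        h_min: float = 1e-3,
        h_max: float = 1e-1,
        n_steps: int = 100,
        grid_spacing: str = "log",
        nlm_params: NLMParams | None = None,
    ) -> None:
        self.thin = as_image(thin)
        self.thick = as_image(thick)
        self.config = SweepConfig(
            epi_roi=epi_roi,
            snr_roi=snr_roi,
            h_min=h_min,
            h_max=h_max,
            n_steps=n_steps,
            grid_spacing=grid_spacing,
            nlm=nlm_params if nlm_params is not None else NLMParams(h=1e-2),
        )

    def fit(self) -> "SweepResults":
        """Run the sweep and return the results object."""
        return SweepResults(self, run_sweep(self.thin, self.thick, self.config))


class SweepResults:
    """Fitted sweep: curves, selection, and convenience views."""

    def __init__(self, model: NLMSweep, result: SweepResult) -> None:
        self.model = model
        self._result = result

    # -- raw sweep fields -------------------------------------------------
    @property
    def h_grid(self) -> np.ndarray:
        return self._result.h_grid

    @property
    def epi_curve(self) -> np.ndarray:
        return self._result.epi_curve

    @property
    def snr_norm_curve(self) -> np.ndarray:
        return self._result.snr_norm_curve

    @property
    def crossing_index(self) -> int | None:
        return self._result.crossing_index

    @property
    def optimal_h(self) -> float | None:
        return self._result.optimal_h

    @property
    def status(self) -> str:
        return self._result.status

    @property
    def raw(self) -> SweepResult:
        return self._result

    # -- actions ----------------------------------------------------------
    def apply(self, image: RasterImage | None = None) -> RasterImage:
        """Denoise an image (default: the model's thin input) at the
        selected h."""
        target = self.model.thin if image is None else as_image(image)
        return apply_optimal(target, self._result, self.model.config.nlm)

    def to_frame(self):
        """Sweep curves as a pandas DataFrame (h, epi, snr_norm)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "h": self.h_grid,
                "epi": self.epi_curve,
                "snr_norm": self.snr_norm_curve,
            }
        )

    def plot(self, ax=None):
        """EPI and normalized-SNR curves vs h, crossing marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.h_grid, self.epi_curve, label="EPI")
        ax.plot(self.h_grid, self.snr_norm_curve, label="SNR / SNR(thick)")
        if self.model.config.grid_spacing == "log":
            ax.set_xscale("log")
        if self.status == "crossed":
            ax.axvline(self.optimal_h, color="k", ls="--", lw=0.8)
        ax.set_xlabel("smoothing factor h")
        ax.set_ylabel("index value")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the sweep."""
        cfg = self.model.config
        lines = [
            "NLM smoothing-parameter sweep",
            "=============================",
            f"grid            : {cfg.n_steps} steps, {cfg.grid_spacing}-spaced, "
            f"[{cfg.h_min:g}, {cfg.h_max:g}]",
            f"patch / window  : {2 * cfg.nlm.patch_radius + 1}x"
            f"{2 * cfg.nlm.patch_radius + 1} / "
            f"{2 * cfg.nlm.window_radius + 1}x{2 * cfg.nlm.window_radius + 1}",
            f"epi_roi         : {cfg.epi_roi}",
            f"snr_roi         : {cfg.snr_roi}",
            f"status          : {self.status}",
        ]
        if self.status == "crossed":
            i = self.crossing_index
            lines += [
                f"optimal h       : {self.optimal_h:.6g} "
                f"(grid interval {i}..{i + 1})",
                f"EPI at bracket  : {self.epi_curve[i]:.4f} -> "
                f"{self.epi_curve[min(i + 1, len(self.h_grid) - 1)]:.4f}",
                f"SNRn at bracket : {self.snr_norm_curve[i]:.4f} -> "
                f"{self.snr_norm_curve[min(i + 1, len(self.h_grid) - 1)]:.4f}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SweepResults status={self.status!r} optimal_h={self.optimal_h}>"
        )
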