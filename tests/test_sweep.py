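"""Smoothing-parameter sweep: crossing arithmetic, the model/results
API, and the end-to-end behaviour on the simulated detector pair."""

import numpy as np
import pytest

from nlmopt import (
    HomogeneousROIError,
    NLMParams,
    NLMSweep,
    NoCrossingError,
    RectROI,
    SweepConfig,
    SweepResult,
    apply_optimal,
    epi,
    nlm_denoise,
    roi_snr,
    run_sweep,
    select_optimal_h,
)


def _result(epi_curve, snr_curve, grid, spacing="linear"):
    return SweepResult(
        h_grid=np.asarray(grid, float),
        epi_curve=np.asarray(epi_curve, float),
        snr_norm_curve=np.asarray(snr_curve, float),
        grid_spacing=spacing,
    )


class TestSelectOptimalH:
    def test_exact_tie_at_grid_point(self):
        res = _result(
            [1.0, 0.75, 0.5, 0.25, 0.0],
            [0.0, 0.25, 0.5, 0.75, 1.0],
            [0.001, 0.0255, 0.05, 0.0745, 0.1],
        )
        assert select_optimal_h(res) == 0.05
        assert res.status == "crossed"
        assert res.crossing_index == 2

    def test_linear_interpolation_between_grid_points(self):
        res = _result([0.8, 0.6], [0.5, 0.7], [0.01, 0.02])
        # d = [0.3, -0.1] -> h* = 0.01 + 0.01 * 0.3/0.4 = 0.0175
        assert select_optimal_h(res) == pytest.approx(0.0175, abs=1e-15)

    def test_log_grid_interpolates_in_log10_h(self):
        res = _result([0.8, 0.6], [0.5, 0.7], [0.01, 0.1], spacing="log")
        expected = 10.0 ** (-2 + 1 * 0.75)
        assert select_optimal_h(res) == pytest.approx(expected, rel=1e-12)

    def test_no_sign_change_reports_no_crossing_without_raising(self):
        res = _result([0.9, 0.8, 0.7], [0.1, 0.2, 0.3], [0.01, 0.02, 0.03])
        assert select_optimal_h(res) is None
        assert res.status == "no_crossing"
        assert res.optimal_h is None

    def test_first_of_multiple_crossings_selected(self):
        res = _result(
            [0.9, 0.4, 0.9, 0.4], [0.5, 0.5, 0.5, 0.5], [0.01, 0.02, 0.03, 0.04]
        )
        assert res is not None
        select_optimal_h(res)
        assert res.crossing_index == 0
        assert 0.01 <= res.optimal_h <= 0.02

    def test_bracketing_invariant(self):
        res = _result([0.8, 0.6, 0.2], [0.3, 0.5, 0.9], [0.01, 0.02, 0.03])
        h = select_optimal_h(res)
        i = res.crossing_index
        assert res.h_grid[i] <= h <= res.h_grid[i + 1]


class TestSweepConfig:
    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SweepConfig(epi_roi=RectROI(0, 0, 8, 8), snr_roi=RectROI(4, 4, 8, 8))

    def test_bad_grid_rejected(self):
        rois = dict(epi_roi=RectROI(0, 0, 8, 8), snr_roi=RectROI(0, 16, 8, 8))
        with pytest.raises(ValueError):
            SweepConfig(h_min=0.1, h_max=0.01, **rois)
        with pytest.raises(ValueError):
            SweepConfig(n_steps=2, **rois)

    def test_log_grid_endpoints(self):
        cfg = SweepConfig(
            epi_roi=RectROI(0, 0, 8, 8), snr_roi=RectROI(0, 16, 8, 8), n_steps=100
        )
        g = cfg.grid()
        assert g[0] == pytest.approx(1e-3)
        assert g[-1] == pytest.approx(1e-1)
        assert len(g) == 100


class TestRunSweep:
    def test_noiseless_input_raises_homogeneous_roi_error(self, sim_pair):
        """A noiseless flat SNR ROI has zero std: the framework needs
        noisy input, and says so with the step index attached."""
        cfg = SweepConfig(
            epi_roi=sim_pair.epi_roi, snr_roi=sim_pair.snr_roi, n_steps=3
        )
        clean = sim_pair.scene  # noiseless composite
        with pytest.raises(HomogeneousROIError, match="homogeneous"):
            run_sweep(clean, clean, cfg)

    def test_end_to_end_crossing_and_monotone_curves(self, sweep_fit):
        assert sweep_fit.status == "crossed"
        assert 1e-3 < sweep_fit.optimal_h < 1e-1
        assert np.all(np.diff(sweep_fit.epi_curve) <= 1e-9)
        assert np.all(np.diff(sweep_fit.snr_norm_curve) >= -1e-9)
        assert np.all((sweep_fit.epi_curve >= -1) & (sweep_fit.epi_curve <= 1))
        assert np.all(sweep_fit.snr_norm_curve >= 0)

    def test_determinism(self, sim_pair, sweep_fit):
        again = NLMSweep(
            sim_pair.thin,
            sim_pair.thick,
            epi_roi=sim_pair.epi_roi,
            snr_roi=sim_pair.snr_roi,
            n_steps=25,
        ).fit()
        assert np.array_equal(again.epi_curve, sweep_fit.epi_curve)
        assert np.array_equal(again.snr_norm_curve, sweep_fit.snr_norm_curve)
        assert again.optimal_h == sweep_fit.optimal_h

    def test_grid_refinement_stability(self, sim_pair, sweep_fit):
        """Doubling the step count moves h* by less than one coarse
        grid interval."""
        fine = NLMSweep(
            sim_pair.thin,
            sim_pair.thick,
            epi_roi=sim_pair.epi_roi,
            snr_roi=sim_pair.snr_roi,
            n_steps=50,
        ).fit()
        i = sweep_fit.crossing_index
        coarse_gap = sweep_fit.h_grid[i + 1] - sweep_fit.h_grid[i]
        assert abs(fine.optimal_h - sweep_fit.optimal_h) < coarse_gap

    def test_crossing_bracketing_at_interpolated_h(self, sim_pair, sweep_fit):
        """Re-evaluating both curves exactly at h* lands within the
        larger of the two adjacent grid-point gaps."""
        h = sweep_fit.optimal_h
        den = nlm_denoise(sim_pair.thin, NLMParams(h=h))
        e = epi(sim_pair.thin, den, sim_pair.epi_roi)
        s = roi_snr(den, sim_pair.snr_roi) / roi_snr(sim_pair.thick, sim_pair.snr_roi)
        i = sweep_fit.crossing_index
        gap_e = abs(sweep_fit.epi_curve[i + 1] - sweep_fit.epi_curve[i])
        gap_s = abs(sweep_fit.snr_norm_curve[i + 1] - sweep_fit.snr_norm_curve[i])
        assert abs(e - s) < max(gap_e, gap_s)


class TestApplyOptimal:
    def test_delegation_is_bit_identical_to_direct_denoise(self, sim_pair, sweep_fit):
        out = sweep_fit.apply()
        direct = nlm_denoise(sim_pair.thin, NLMParams(h=sweep_fit.optimal_h))
        assert np.array_equal(out.pixels, direct.pixels)

    def test_no_crossing_rejected(self, sim_pair):
        res = _result([0.9, 0.8], [0.1, 0.2], [0.01, 0.02])
        select_optimal_h(res)
        with pytest.raises(NoCrossingError):
            apply_optimal(sim_pair.thin, res, NLMParams(h=0.01))

    def test_restored_image_beats_input_snr_and_hmax_epi(self, sim_pair, sweep_fit):
        out = sweep_fit.apply()
        assert roi_snr(out, sim_pair.snr_roi) > roi_snr(sim_pair.thin, sim_pair.snr_roi)
        at_hmax = nlm_denoise(sim_pair.thin, NLMParams(h=0.1))
        assert epi(sim_pair.thin, out, sim_pair.epi_roi) > epi(
            sim_pair.thin, at_hmax, sim_pair.epi_roi
        )


class TestResultsAPI:
    def test_summary_mentions_selection(self, sweep_fit):
        text = sweep_fit.summary()
        assert "crossed" in text
        assert f"{sweep_fit.optimal_h:.6g}" in text

    def test_to_frame_round_trip(self, sweep_fit):
        df = sweep_fit.to_frame()
        assert list(df.columns) == ["h", "epi", "snr_norm"]
        assert len(df) == 25

    def test_plot_smoke(self, sweep_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = sweep_fit.plot()
        assert len(ax.lines) >= 2
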