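"""Synthetic detector chain: scene rendering, exposure statistics,
flat-field stacks, and the thin/thick preset contract."""

import numpy as np
import pytest
from dataclasses import replace

from nlmopt import (
    DetectorConfig,
    RectROI,
    detector_preset,
    expose,
    make_flat_stack,
    render_scene,
    roi_snr,
)
from nlmopt.simulate import SceneSpec, edge_bright_fraction

PITCH = 0.048


class TestRenderScene:
    def test_flat_is_exactly_constant(self):
        img = render_scene(SceneSpec(kind="flat", fluence=100.0), (8, 8), PITCH)
        assert np.all(img.pixels == 100.0)

    def test_aligned_edge_is_a_clean_step(self):
        spec = SceneSpec(kind="edge", fluence=100.0, edge_angle_deg=0.0, edge_contrast=1.0)
        img = render_scene(spec, (8, 8), PITCH)
        assert np.all(img.pixels[:, :4] == 0.0)
        assert np.all(img.pixels[:, 4:] == 100.0)

    def test_tilted_edge_matches_polygon_clipping_oracle(self):
        """Boundary-pixel values equal the exact bright-area fraction,
        cross-checked against shapely polygon clipping."""
        from shapely.geometry import Polygon, box

        angle = np.degrees(np.arctan(1 / 20))  # 2.862...
        spec = SceneSpec(kind="edge", fluence=100.0, edge_angle_deg=angle, edge_contrast=1.0)
        img = render_scene(spec, (64, 64), PITCH)
        t = 1 / 20
        x0 = 32.0 - t * 32.0
        big = 1e4
        # bright half-plane x > x0 + t*y as a huge polygon
        bright = Polygon(
            [
                (x0 + t * -big, -big),
                (x0 + t * big, big),
                (x0 + t * big + big, big),
                (x0 + t * -big + big, -big),
            ]
        )
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 64, size=10)
        for r in rows:
            c = int(np.floor(x0 + t * (r + 0.5)))  # a boundary column
            frac_oracle = bright.intersection(box(c, r, c + 1, r + 1)).area
            assert img.pixels[r, c] == pytest.approx(100.0 * frac_oracle, abs=1e-9)
            assert edge_bright_fraction(r, c, x0, t) == pytest.approx(frac_oracle, abs=1e-12)

    def test_line_pairs_above_nyquist_rejected_with_offender_named(self):
        spec = SceneSpec(kind="line_pairs", fluence=100.0, line_groups=((2.0, 1.0), (12.0, 0.5)))
        with pytest.raises(ValueError, match="12"):
            render_scene(spec, (64, 64), PITCH)

    def test_line_pairs_are_two_level_square_waves(self):
        spec = SceneSpec(kind="line_pairs", fluence=100.0, line_groups=((1.0, 0.5),))
        img = render_scene(spec, (16, 64), PITCH)
        assert set(np.unique(img.pixels)) == {50.0, 100.0}


class TestExpose:
    def test_high_count_limit_is_nearly_noiseless(self):
        det = DetectorConfig(psf_sigma_mm=0.0, gain=1e6, read_noise=0.0,
                             bit_depth=24, seed=0)
        scene = render_scene(SceneSpec(kind="flat", fluence=1.0), (32, 32), PITCH)
        out = expose(scene, det)
        assert np.all(np.abs(out.pixels - 1e6) / 1e6 < 0.01)

    def test_poisson_variance_matches_mean(self):
        det = DetectorConfig(psf_sigma_mm=0.0, gain=3.0, read_noise=0.0, seed=2)
        scene = render_scene(SceneSpec(kind="flat", fluence=100.0), (512, 512), PITCH)
        out = expose(scene, det)
        assert out.pixels.var() == pytest.approx(out.pixels.mean(), rel=0.05)

    def test_thin_preset_is_noisier_than_thick_on_the_same_flat(self):
        scene = render_scene(SceneSpec(kind="flat", fluence=750.0), (128, 128), PITCH)
        roi = RectROI(16, 16, 96, 96)
        snr_thin = roi_snr(expose(scene, detector_preset("thin", seed=3)), roi)
        snr_thick = roi_snr(expose(scene, detector_preset("thick", seed=3)), roi)
        assert snr_thin < snr_thick

    def test_determinism_same_seed_bit_identical(self):
        det = detector_preset("thin", seed=9)
        scene = render_scene(SceneSpec(kind="flat", fluence=750.0), (32, 32), PITCH)
        assert np.array_equal(expose(scene, det).pixels, expose(scene, det).pixels)

    def test_negative_scene_rejected(self):
        det = detector_preset("thin")
        with pytest.raises(ValueError, match="non-negative"):
            expose(render_scene(SceneSpec(kind="flat", fluence=1.0), (8, 8), PITCH).with_pixels(
                np.full((8, 8), -1.0)), det)


class TestFlatStack:
    def test_needs_at_least_two_frames(self):
        with pytest.raises(ValueError, match=">= 2"):
            make_flat_stack(detector_preset("thin"), 1, 750.0, shape=(32, 32))

    def test_same_seed_gives_identical_stacks(self):
        det = detector_preset("thin", seed=4)
        a = make_flat_stack(det, 3, 750.0, shape=(32, 32))
        b = make_flat_stack(det, 3, 750.0, shape=(32, 32))
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.pixels, fb.pixels)

    def test_frames_are_independent_noise_realizations(self):
        det = detector_preset("thin", seed=4)
        frames = make_flat_stack(det, 2, 750.0, shape=(64, 64))
        assert not np.array_equal(frames[0].pixels, frames[1].pixels)

    def test_frame_means_obey_the_poisson_z_score_bound(self):
        """Per-pixel mean over 16 Poisson-only frames sits within
        3 sigma / sqrt(16) of the expected mean for >= 99% of pixels."""
        det = DetectorConfig(psf_sigma_mm=0.0, gain=1.0, read_noise=0.0, seed=5)
        mu = 400.0
        frames = np.stack([f.pixels for f in make_flat_stack(det, 16, mu, shape=(64, 64))])
        z = (frames.mean(axis=0) - mu) / (np.sqrt(mu) / np.sqrt(16))
        assert (np.abs(z) <= 3.0).mean() >= 0.99


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(psf_sigma_mm=-0.1, gain=1.0, read_noise=0.0),
            dict(psf_sigma_mm=0.1, gain=0.0, read_noise=0.0),
            dict(psf_sigma_mm=0.1, gain=1.0, read_noise=-1.0),
            dict(psf_sigma_mm=0.1, gain=1.0, read_noise=0.0, pixel_pitch_mm=0.0),
        ],
    )
    def test_invalid_detector_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            detector_preset("medium")

    def test_edge_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(kind="edge", edge_angle_deg=45.0)
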