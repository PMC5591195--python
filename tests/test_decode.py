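"""Decoder: spot detection, channel mapping, trace extraction, overlap filter."""

import numpy as np
import pytest

from smsweep import (
    SweepConfig, KineticModel, CameraModel, SpotPeak,
    detect_spots, fit_channel_map, extract_trace, filter_overlaps,
    render_swept_stack, dual_channel_layout,
    InvalidArgumentError, InsufficientDataError,
)
from smsweep.decode import sweep_footprint
from smsweep.simulate import gaussian_patch


def _spot_image(shape, centers, amp=1000.0, sigma=1.087, offset=0.0):
    img = np.full(shape, offset)
    for x, y in centers:
        patch, r0, c0 = gaussian_patch(x, y, sigma, shape)
        img[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += amp * patch
    return img


class TestDetectSpots:
    def test_single_noiseless_spot_center_within_tenth_pixel(self):
        img = _spot_image((64, 64), [(20.3, 30.6)])
        peaks = detect_spots(img, min_separation_px=5, intensity_threshold=1.0)
        assert len(peaks) == 1
        assert peaks[0].x == pytest.approx(20.3, abs=0.1)
        assert peaks[0].y == pytest.approx(30.6, abs=0.1)
        assert peaks[0].fwhm_px == pytest.approx(2.56, abs=0.3)

    def test_blank_image_yields_no_peaks(self):
        assert detect_spots(np.zeros((32, 32)), 5, intensity_threshold=1.0) == []

    def test_close_pair_mutually_rejected(self):
        # two resolvable spots 4 px apart: both must be dropped, not just one
        img = _spot_image((64, 64), [(20.0, 30.0), (24.0, 30.0)])
        peaks = detect_spots(img, min_separation_px=10, intensity_threshold=1.0)
        assert peaks == []

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(InvalidArgumentError):
            detect_spots(img, 5, 1.0)


class TestChannelMap:
    def _peaks(self, xy):
        return [SpotPeak(x=float(x), y=float(y)) for x, y in xy]

    def test_identity_placed_beads(self, rng):
        xy = rng.uniform(10, 50, size=(8, 2))
        m = fit_channel_map(self._peaks(xy), self._peaks(xy))
        np.testing.assert_allclose(m.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(m.offset, 0, atol=1e-9)
        assert m.residual_rms_px < 1e-9

    def test_pure_translation(self, rng):
        xy = rng.uniform(10, 50, size=(6, 2))
        right = xy + np.array([256.0, 0.0])
        m = fit_channel_map(self._peaks(xy), self._peaks(right))
        np.testing.assert_allclose(m.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(m.offset, [256.0, 0.0], atol=1e-9)

    def test_affine_warp_recovered_under_jitter(self, rng):
        A = np.array([[1.01, 0.003], [-0.002, 0.99]])
        b = np.array([128.0, 2.0])
        xy = rng.uniform(5, 60, size=(25, 2))
        right = xy @ A.T + b + rng.normal(0, 0.05, size=(25, 2))
        m = fit_channel_map(self._peaks(xy), self._peaks(right))
        np.testing.assert_allclose(m.matrix, A, atol=1e-2)
        np.testing.assert_allclose(m.offset, b, atol=0.5)
        assert m.residual_rms_px < 0.2

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_channel_map(self._peaks([(1, 1), (2, 2)]), self._peaks([(1, 1), (2, 2)]))


class TestExtractTrace:
    def test_always_bright_trace_uniform(self, blinking_sweep, quiet_camera,
                                         always_bright, small_layout):
        stack, gt = render_swept_stack([((8.0, 20.0), always_bright)], blinking_sweep,
                                       quiet_camera, small_layout, 6, seed=1,
                                       noise=False)
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep)
        nominal = 0.7 * 60.0 * 4.0
        assert tr.values == pytest.approx(nominal, rel=0.02)
        assert tr.n_samples == 6 * 5

    def test_dark_substeps_sit_at_background(self, blinking_sweep, quiet_camera,
                                             small_layout):
        from smsweep.simulate import StateTrajectory, integrate_substeps
        # deterministic trajectory: dark during substeps 2-3 of frame 0
        stack, gt = render_swept_stack(
            [((8.0, 20.0), KineticModel(k_on=1.0, k_off=0.0, bright_rate=60.0))],
            blinking_sweep, quiet_camera, small_layout, 2, seed=1, noise=False)
        # overwrite via a fresh render with an explicit two-switch molecule
        traj = StateTrajectory(np.array([8.0, 16.0]), 1, 2 * 21.7,
                               emission_rates=(0.0, 60.0))
        counts = integrate_substeps(traj, blinking_sweep, 2)
        assert counts[0, 2] == 0 and counts[0, 3] == 0
        # decoded trace of the rendered absorbing molecule never goes dark
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep)
        assert tr.values.min() > 100

    def test_single_step_equals_conventional_photometry(self, quiet_camera,
                                                        always_bright, small_layout):
        cfg = SweepConfig(1, 0.0, 0.25, 20.0)
        stack, _ = render_swept_stack([((8.0, 20.0), always_bright)], cfg,
                                      quiet_camera, small_layout, 4, seed=0,
                                      noise=False)
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), cfg)
        right = stack.channel("right")
        manual = right[:, 17:24, 5:12].sum(axis=(1, 2))
        np.testing.assert_allclose(tr.raw_values, manual, rtol=1e-12)

    def test_even_box_rejected(self, blinking_sweep, quiet_camera, always_bright,
                               small_layout):
        stack, _ = render_swept_stack([((8.0, 20.0), always_bright)], blinking_sweep,
                                      quiet_camera, small_layout, 2, seed=0,
                                      noise=False)
        with pytest.raises(InvalidArgumentError):
            extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep, box_px=6)

    def test_window_out_of_bounds_rejected(self, blinking_sweep, quiet_camera,
                                           always_bright, small_layout):
        stack, _ = render_swept_stack([((8.0, 20.0), always_bright)], blinking_sweep,
                                      quiet_camera, small_layout, 2, seed=0,
                                      noise=False)
        with pytest.raises(InvalidArgumentError):
            extract_trace(stack, SpotPeak(40.0, 20.0), blinking_sweep)


class TestRoundTrip:
    def test_noiseless_roundtrip_within_two_percent(self, blinking_sweep, quiet_camera,
                                                    small_layout):
        m = KineticModel(k_on=217.0, k_off=80.0, bright_rate=60.0)
        stack, gt = render_swept_stack([((8.0, 20.0), m)], blinking_sweep,
                                       quiet_camera, small_layout, 50, seed=21,
                                       noise=False)
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep)
        expected = gt.expected_photons[0] * 0.7
        # error relative to the bright-state amplitude: neighbor-substep PSF
        # bleed is a constant absolute offset, so dim partial substeps would
        # otherwise show huge relative errors on near-zero expectations
        full_scale = 0.7 * 60.0 * blinking_sweep.substep_ms
        rel = np.abs(tr.values - expected) / full_scale
        assert rel.max() < 0.02

    def test_noisy_trace_tracks_ground_truth(self, blinking_sweep, small_layout):
        # a bright molecule: decoded trace correlates > 0.95 with the truth
        m = KineticModel(k_on=217.0, k_off=80.0, bright_rate=150.0)
        stack, gt = render_swept_stack([((8.0, 20.0), m)], blinking_sweep,
                                       CameraModel(), small_layout, 400, seed=2,
                                       background_rate=0.2)
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep)
        r = np.corrcoef(tr.values, gt.expected_photons[0])[0, 1]
        assert r > 0.95

    def test_trace_length_is_frames_times_steps(self, blinking_sweep, quiet_camera,
                                                always_bright, small_layout):
        stack, _ = render_swept_stack([((8.0, 20.0), always_bright)], blinking_sweep,
                                      quiet_camera, small_layout, 7, seed=0,
                                      noise=False)
        tr = extract_trace(stack, SpotPeak(8.0, 20.0), blinking_sweep)
        assert tr.values.shape == (7 * blinking_sweep.n_steps,)


class TestOverlapFilter:
    def setup_method(self):
        self.cfg = SweepConfig(5, 96, 0.25, 20.0)  # L = 24 px

    def test_same_row_within_sweep_both_removed(self):
        peaks = [SpotPeak(10.0, 20.0), SpotPeak(20.0, 20.0)]
        assert filter_overlaps(peaks, self.cfg, box_px=7) == []

    def test_vertical_neighbors_kept(self):
        peaks = [SpotPeak(10.0, 20.0), SpotPeak(10.0, 30.0)]
        assert len(filter_overlaps(peaks, self.cfg, box_px=7)) == 2

    def test_matches_brute_force_oracle(self, rng):
        peaks = [SpotPeak(x, y) for x, y in
                 np.column_stack([rng.uniform(0, 400, 500), rng.uniform(0, 400, 500)])]
        fast = filter_overlaps(peaks, self.cfg, box_px=7)
        boxes = [sweep_footprint(p, self.cfg, 7) for p in peaks]

        def intersects(a, b):
            return a[0] <= b[1] and b[0] <= a[1] and a[2] <= b[3] and b[2] <= a[3]

        slow = [p for i, p in enumerate(peaks)
                if not any(j != i and intersects(boxes[i], boxes[j])
                           for j in range(len(peaks)))]
        assert [(p.x, p.y) for p in fast] == [(p.x, p.y) for p in slow]
        assert 0 < len(fast) < 500

    def test_empty_input(self):
        assert filter_overlaps([], self.cfg, 7) == []


class TestThroughputCrossover:
    def test_swept_fov_beats_cropped_fov_at_low_density_only(self, rng):
        # usable molecules: full FOV with overlap filtering vs a 1/N-cropped
        # FOV imaged conventionally (all molecules usable, no sweep overlap)
        cfg = SweepConfig(5, 96, 0.25, 20.0)
        H = W = 200.0
        # footprint pair-collision area (2*31 x 2*7 px) puts the crossover
        # near 1.8e-3 molecules/px^2 (~0.1 /um^2 at 133 nm pixels)
        ratios = []
        densities = np.array([2e-4, 8e-4, 4e-3, 1.6e-2])
        for dens in densities:
            survivors, cropped = 0, 0
            for rep in range(8):
                n = rng.poisson(dens * H * W)
                xy = np.column_stack([rng.uniform(0, W - cfg.sweep_length_px, n),
                                      rng.uniform(0, H, n)])
                peaks = [SpotPeak(x, y) for x, y in xy]
                survivors += len(filter_overlaps(peaks, cfg, 7))
                cropped += int((xy[:, 1] < H / cfg.n_steps).sum())
            ratios.append(survivors / max(cropped, 1))
        assert ratios[0] > 1.0          # low density: sweeping wins
        assert ratios[-1] < 1.0         # high density: overlap kills throughput
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))  # monotone decline
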