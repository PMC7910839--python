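"""TIRF contact-area segmentation: averaging, blur, threshold, trace."""

import numpy as np
import pytest
from scipy import signal

from tcellact.contact_analysis import (
    area_trace,
    average_cycle_pair,
    blur,
    segment_area,
)
from tcellact.imaging_io import AcquisitionMetadata, ImageStack


class TestAverageCyclePair:
    def test_identical_and_constant_pairs(self, rng):
        f = rng.uniform(0, 10, (8, 8))
        np.testing.assert_array_equal(average_cycle_pair(f, f), f)
        np.testing.assert_allclose(
            average_cycle_pair(np.zeros((4, 4)), np.full((4, 4), 2.0)), 1.0
        )

    def test_matches_elementwise_mean_oracle(self, rng):
        a, b = rng.uniform(0, 100, (2, 16, 16))
        np.testing.assert_allclose(average_cycle_pair(a, b), (a + b) / 2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            average_cycle_pair(np.zeros((4, 4)), np.zeros((4, 5)))


class TestBlur:
    def test_uniform_frame_unchanged(self):
        f = np.full((32, 32), 7.0)
        np.testing.assert_allclose(blur(f), f)

    def test_single_pixel_symmetric_and_conserving(self):
        f = np.zeros((31, 31))
        f[15, 15] = 1000.0
        out = blur(f)
        assert out.sum() == pytest.approx(1000.0, rel=0.005)
        np.testing.assert_allclose(out, out[::-1, :])     # row symmetry
        np.testing.assert_allclose(out, out[:, ::-1])     # col symmetry

    def test_matches_direct_convolution_oracle(self, rng):
        f = rng.uniform(0, 100, (40, 40))
        sigma, radius = 1.0, 2
        x = np.arange(-radius, radius + 1)
        k1d = np.exp(-x**2 / (2 * sigma**2))
        k1d /= k1d.sum()
        kernel = np.outer(k1d, k1d)
        oracle = signal.convolve2d(f, kernel, mode="same", boundary="symm")
        got = blur(f, kernel_px=5)
        np.testing.assert_allclose(got[3:-3, 3:-3], oracle[3:-3, 3:-3], rtol=1e-10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            blur(np.zeros((8, 8)), kernel_px=4)


class TestSegmentArea:
    def test_zero_frame_and_high_threshold(self):
        area, _ = segment_area(np.zeros((16, 16)), 10.0)
        assert area == 0.0
        frame = np.full((16, 16), 5.0)
        area, _ = segment_area(frame, 100.0)
        assert area == 0.0

    def test_disc_area_matches_pixel_count_oracle(self):
        n, r = 96, 25
        rr, cc = np.indices((n, n))
        disc = (np.hypot(rr - n / 2, cc - n / 2) <= r).astype(float) * 100.0
        area, mask = segment_area(disc, 50.0, pixel_size_um=0.160)
        n_oracle = int((np.hypot(rr - n / 2, cc - n / 2) <= r).sum())
        assert area == pytest.approx(n_oracle * 0.160**2)
        # and close to the continuous disc area pi r^2 within discretization
        assert area == pytest.approx(np.pi * (r * 0.160) ** 2, rel=0.05)

    def test_area_monotone_nonincreasing_in_threshold(self, rng):
        frame = blur(rng.uniform(0, 200, (64, 64)), 5)
        thresholds = np.linspace(0, 220, 40)
        areas = [segment_area(frame, th)[0] for th in thresholds]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestAreaTrace:
    def _stack(self, frames, period=4.0):
        frames = np.asarray(frames, dtype=np.float64)
        t = np.sort(np.concatenate(
            [np.arange(len(frames) // 2) * period + 2.501,
             np.arange(len(frames) // 2) * period + 2.653]))
        return ImageStack(frames, t)

    def test_empty_field_gives_zero_trace(self, rng):
        frames = rng.normal(100, 10, (12, 32, 32)).clip(0)
        trace = area_trace(self._stack(frames), threshold=200.0)
        np.testing.assert_array_equal(trace.area_um2, 0.0)

    def test_constant_disc_gives_constant_trace(self):
        n = 64
        rr, cc = np.indices((n, n))
        disc = 100.0 + 300.0 * (np.hypot(rr - n / 2, cc - n / 2) <= 12)
        frames = np.tile(disc, (8, 1, 1))
        trace = area_trace(self._stack(frames), threshold=250.0)
        assert np.ptp(trace.area_um2) == 0.0

    def test_odd_frame_count_rejected_in_pair_mode(self):
        frames = np.zeros((5, 8, 8))
        stack = ImageStack(frames, np.arange(5.0))
        with pytest.raises(ValueError):
            area_trace(stack, threshold=1.0)

    def test_plateau_recovery_on_synthetic_cell(self, small_dataset, small_scenario):
        sc = small_scenario
        trace = area_trace(small_dataset.stacks["tcr"], threshold="auto",
                           contact_time_s=sc.contact_time_s)
        plateau = np.median(trace.area_um2[-5:])
        assert plateau == pytest.approx(sc.area_plateau_um2, rel=0.10)

    def test_segmented_disc_radius_within_blur_kernel(self, small_dataset, small_scenario):
        sc = small_scenario
        trace = area_trace(small_dataset.stacks["tcr"], threshold="auto",
                           contact_time_s=sc.contact_time_s)
        r_true = np.sqrt(sc.area_plateau_um2 / np.pi)
        r_measured = np.sqrt(np.median(trace.area_um2[-5:]) / np.pi)
        assert abs(r_measured - r_true) < 5 * sc.pixel_size_um  # one kernel width
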