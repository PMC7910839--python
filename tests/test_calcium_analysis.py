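"""Ratiometric calcium pipeline: background, ratio, ROI mean, normalization."""

import numpy as np
import pytest

from tcellact.calcium_analysis import (
    CalciumTrace,
    calcium_trace,
    normalize_trace,
    ratio_image,
    roi_mean,
    subtract_background,
)
from tcellact.imaging_io import AcquisitionMetadata, ImageStack


def _stack(frames, period=4.0):
    frames = np.asarray(frames, dtype=np.float64)
    return ImageStack(frames, np.arange(len(frames)) * period)


class TestSubtractBackground:
    def test_uniform_frame_goes_to_zero(self):
        stack = _stack([np.full((32, 32), 100.0)])
        with pytest.warns(UserWarning):
            # flat frame: border median equals the maximum -> masked
            out = subtract_background(stack)
        assert np.all(np.isnan(out.frames[0]))

    def test_known_constant_offset_recovered(self, rng):
        signal = np.zeros((64, 64))
        signal[28:36, 28:36] = 500.0
        stack = _stack([signal + 50.0])
        out = subtract_background(stack)
        np.testing.assert_allclose(out.frames[0], signal, atol=1e-9)

    def test_fixed_scalar_method(self):
        stack = _stack([np.full((16, 16), 80.0) + np.eye(16)])
        out = subtract_background(stack, method=30.0)
        assert out.frames[0][0, 1] == pytest.approx(50.0)

    def test_empty_stack_raises(self):
        stack = ImageStack(np.zeros((1, 4, 4)), np.array([0.0]))
        stack.frames = np.zeros((0, 4, 4))
        stack.timestamps_s = np.zeros(0)
        with pytest.raises(ValueError):
            subtract_background(stack)


class TestRatioImage:
    def test_identity_and_doubling(self):
        f = np.full((8, 8), 200.0)
        np.testing.assert_allclose(ratio_image(f, f), 1.0)
        np.testing.assert_allclose(ratio_image(2 * f, f), 2.0)

    def test_matches_per_pixel_division_oracle(self, rng):
        a = rng.uniform(100, 1000, (16, 16))
        b = rng.uniform(100, 1000, (16, 16))
        np.testing.assert_allclose(ratio_image(a, b), a / b)

    def test_low_denominator_pixels_invalidated(self):
        a = np.full((4, 4), 100.0)
        b = np.full((4, 4), 100.0)
        b[0, 0] = 10.0  # below the 5 x read-noise floor (50)
        out = ratio_image(a, b, read_noise_counts=10.0)
        assert np.isnan(out[0, 0]) and np.isfinite(out[1, 1])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ratio_image(np.zeros((4, 4)), np.zeros((5, 5)))


class TestRoiMean:
    def test_uniform_value(self):
        img = np.full((64, 64), 1.7)
        assert roi_mean(img, (32, 32)) == pytest.approx(1.7)

    def test_pixel_membership_matches_enumeration_oracle(self):
        # radius 3.2 um at 0.160 um/px = 20 px; mark ROI pixels and compare
        img = np.zeros((64, 64))
        center = (31.0, 31.0)
        rr, cc = np.indices(img.shape)
        oracle = np.hypot(rr - center[0], cc - center[1]) <= 20.0
        img[oracle] = 1.0
        # mean over the ROI of the indicator image is exactly 1 iff the ROI
        # pixel set equals the oracle set
        assert roi_mean(img, center, 3.2, 0.160) == pytest.approx(1.0)
        assert roi_mean(1.0 - img, center, 3.2, 0.160) == pytest.approx(0.0)

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError):
            roi_mean(np.zeros((16, 16)), (40.0, 8.0))

    def test_monotone_under_uniform_scaling(self, rng):
        img = rng.uniform(0.5, 2.0, (48, 48))
        m1 = roi_mean(img, (24, 24))
        m2 = roi_mean(3.0 * img, (24, 24))
        assert m2 == pytest.approx(3.0 * m1)

    def test_invariant_under_masked_border(self, rng):
        img = rng.uniform(0.5, 2.0, (48, 48))
        padded = np.pad(img, 8, constant_values=np.nan)
        assert roi_mean(padded, (24 + 8, 24 + 8)) == pytest.approx(
            roi_mean(img, (24, 24))
        )


class TestNormalizeTrace:
    def test_constant_trace_becomes_ones(self):
        t = np.arange(10) * 4.0
        trace = CalciumTrace(t, np.full(10, 0.9))
        out = normalize_trace(trace, (0, 20))
        np.testing.assert_allclose(out.normalized, 1.0)

    def test_basal_mean_and_peak_arithmetic(self):
        t = np.arange(10) * 4.0
        ratio = np.concatenate([np.full(5, 0.8), np.full(5, 2.0)])
        out = normalize_trace(CalciumTrace(t, ratio), (0, 16))
        assert out.normalized[:5].mean() == pytest.approx(1.0)
        assert out.normalized[-1] == pytest.approx(2.5)

    def test_empty_basal_window_raises(self):
        trace = CalciumTrace(np.arange(10) * 4.0, np.ones(10))
        with pytest.raises(ValueError):
            normalize_trace(trace, (100, 120))


def test_fold_change_recovery_on_synthetic_cell(small_dataset, small_scenario):
    """The normalized trace recovers the programmed calcium fold change."""
    sc = small_scenario
    ca = calcium_trace(
        small_dataset.stacks["ca340"], small_dataset.stacks["ca375"],
        basal_window=(0.0, sc.contact_time_s - 1e-9),
    )
    plateau = np.nanmedian(ca.normalized[-5:])
    assert plateau == pytest.approx(sc.ratio_fold, rel=0.05)
    basal = np.nanmean(ca.normalized[ca.timestamps_s < sc.contact_time_s])
    assert basal == pytest.approx(1.0, abs=0.02)
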