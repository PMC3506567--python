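"""Conjugate-view and posterior-only activity estimators and ROI machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scintidose.calibration import CalibrationResult
from scintidose.phantom import CountImage, build_projection
from scintidose.quantify import (
    RoiMask,
    activity_cv,
    activity_pa,
    background_correct,
    extrapolate_partial,
    mirror_roi,
    roi_rate,
)

from .conftest import TRUE_K, TRUE_MU, box_phantom


def forward_rates(camera, activity, T, x, a):
    """Independent oracle: closed-form anterior/posterior totals of a box source."""
    shape = camera.sensitivity_k * activity * (1 - math.exp(-camera.mu * x)) / (camera.mu * x)
    r_p = shape * math.exp(-camera.mu * a)
    r_a = shape * math.exp(-camera.mu * (T - a - x))
    return r_a, r_p


class TestRoiRate:
    def test_zero_image(self):
        img = CountImage(np.zeros((5, 5), dtype=int), "posterior", 1.0, 1.0)
        roi = RoiMask.from_pixels([(0, 0), (1, 1)])
        assert roi_rate(img, roi) == (0.0, 0.0)

    def test_uniform_image(self):
        img = CountImage(np.full((5, 5), 7, dtype=int), "posterior", 1.0, 1.0)
        roi = RoiMask.from_pixels([(r, c) for r in range(2) for c in range(3)])
        total, mean = roi_rate(img, roi)
        assert total == 42.0 and mean == 7.0

    def test_counts_divided_by_dwell_time(self):
        img = CountImage(np.full((3, 3), 10, dtype=int), "posterior", 1.0, dwell_time=2.0)
        total, mean = roi_rate(img, RoiMask.from_pixels([(0, 0)]))
        assert total == 5.0

    def test_matches_brute_force_sum_on_arbitrary_fixture(self):
        rng = np.random.default_rng(5)
        pix = rng.integers(0, 100, size=(5, 5))
        img = CountImage(pix, "posterior", 1.0, 1.0)
        roi_pixels = [(0, 1), (2, 2), (4, 0), (3, 3)]
        expected = sum(pix[r, c] for r, c in roi_pixels)
        total, mean = roi_rate(img, RoiMask.from_pixels(roi_pixels))
        assert total == expected
        assert mean == expected / 4

    def test_out_of_bounds_rejected(self):
        img = CountImage(np.zeros((3, 3), dtype=int), "posterior", 1.0, 1.0)
        with pytest.raises(ValueError, match="outside"):
            roi_rate(img, RoiMask.from_pixels([(5, 5)]))


class TestMirrorRoi:
    def test_centered_symmetric_mask_maps_to_itself(self):
        roi = RoiMask.from_pixels([(0, 3), (0, 4), (0, 5)])  # symmetric on 9 cols
        assert mirror_roi(roi, 9).pixels == roi.pixels

    def test_specific_pixel(self):
        roi = RoiMask.from_pixels([(3, 0)])
        assert mirror_roi(roi, 256).pixels == {(3, 255)}

    @settings(max_examples=30, deadline=None)
    @given(
        pixels=st.sets(
            st.tuples(st.integers(0, 63), st.integers(0, 63)), min_size=1, max_size=20
        )
    )
    def test_mirror_is_an_involution(self, pixels):
        roi = RoiMask.from_pixels(pixels)
        assert mirror_roi(mirror_roi(roi, 64), 64).pixels == roi.pixels


class TestExtrapolatePartial:
    def test_full_roi_is_identity(self):
        assert extrapolate_partial(50.0, 10, 10) == 50.0

    def test_half_kidney_doubles(self):
        assert extrapolate_partial(50.0, 5, 10) == 100.0

    def test_exact_on_uniform_synthetic_kidney(self, camera):
        spec = box_phantom(camera)
        img = build_projection(spec, "posterior")
        full = sorted(spec.compartments[0].footprint)
        part = full[: len(full) // 3]
        rate_part, _ = roi_rate(img, RoiMask.from_pixels(part))
        rate_full, _ = roi_rate(img, RoiMask.from_pixels(full))
        assert extrapolate_partial(rate_part, len(part), len(full)) == pytest.approx(
            rate_full, rel=1e-12
        )

    def test_zero_partial_pixels_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_partial(1.0, 0, 10)


class TestBackgroundCorrect:
    def test_zero_background_leaves_counts(self):
        total, clamped = background_correct(10.0, 0.0, 20.0, 6.0, 3)
        assert total == 30.0 and not clamped

    def test_thickness_scaled_subtraction(self):
        # 10 - 4*(20-6)/20 = 7.2 cps/pixel
        total, clamped = background_correct(10.0, 4.0, 20.0, 6.0, 1)
        assert total == pytest.approx(7.2)
        assert not clamped

    def test_zero_kidney_thickness_subtracts_full_background(self):
        total, _ = background_correct(10.0, 4.0, 20.0, 0.0, 1)
        assert total == pytest.approx(6.0)

    def test_negative_result_clamped_and_flagged(self):
        total, clamped = background_correct(1.0, 10.0, 20.0, 6.0, 5)
        assert total == 0.0 and clamped

    def test_kidney_thicker_than_body_rejected(self):
        with pytest.raises(ValueError):
            background_correct(1.0, 1.0, 10.0, 11.0, 1)


class TestActivityCV:
    def test_frozen_worked_example(self, calib_truth):
        # independent evaluation: geo-mean 100 cps divided by the closed-form
        # forward response sqrt(R_A*R_P)/A = k*exp(-mu*(T-x)/2)*(1-exp(-mu*x))/(mu*x)
        k, mu, T, x = TRUE_K, TRUE_MU, 20.0, 6.0
        response = k * math.exp(-mu * (T - x) / 2) * (1 - math.exp(-mu * x)) / (mu * x)
        oracle = 100.0 / response
        est = activity_cv(100.0, 100.0, T, x, calib_truth)
        assert est.activity == pytest.approx(oracle, rel=1e-12)
        assert est.activity == pytest.approx(29.5255, rel=1e-5)

    def test_thin_source_limit(self, calib_truth):
        est = activity_cv(100.0, 100.0, 20.0, 0.0, calib_truth)
        assert est.activity == pytest.approx(100.0 * math.exp(TRUE_MU * 10.0) / TRUE_K, rel=1e-12)

    @pytest.mark.parametrize("depth_a", [0.0, 1.0, 4.0, 7.0, 13.9])
    def test_inverts_noiseless_forward_model_at_any_depth(self, camera, calib_truth, depth_a):
        T, x, activity = 20.0, 6.0, 123.0
        spec = box_phantom(camera, activity=activity, depth_a=depth_a, trunk_T=T)
        r_a = build_projection(spec, "anterior").pixels.sum()
        r_p = build_projection(spec, "posterior").pixels.sum()
        est = activity_cv(r_a, r_p, T, x, calib_truth)
        assert abs(est.activity / activity - 1) < 1e-6

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_linear_in_counts(self, scale):
        calib = CalibrationResult(TRUE_K, TRUE_MU, 1.0, 0)
        a1 = activity_cv(100.0, 80.0, 20.0, 6.0, calib).activity
        a2 = activity_cv(100.0 * scale, 80.0 * scale, 20.0, 6.0, calib).activity
        assert a2 == pytest.approx(scale * a1, rel=1e-9)

    def test_negative_counts_rejected(self, calib_truth):
        with pytest.raises(ValueError):
            activity_cv(-1.0, 1.0, 20.0, 6.0, calib_truth)


class TestActivityPA:
    def test_frozen_worked_example(self, calib_truth):
        k, mu, a, x = TRUE_K, TRUE_MU, 4.0, 6.0
        response = k * math.exp(-mu * a) * (1 - math.exp(-mu * x)) / (mu * x)
        oracle = 100.0 / response
        est = activity_pa(100.0, a, x, calib_truth)
        assert est.activity == pytest.approx(oracle, rel=1e-12)
        assert est.activity == pytest.approx(20.6612, rel=1e-5)

    def test_point_source_at_surface(self, calib_truth):
        est = activity_pa(100.0, 0.0, 0.0, calib_truth)
        assert est.activity == pytest.approx(100.0 / TRUE_K, rel=1e-12)

    def test_exact_recovery_with_true_depth(self, camera, calib_truth):
        activity, a, x = 77.0, 5.0, 6.0
        spec = box_phantom(camera, activity=activity, depth_a=a)
        r_p = build_projection(spec, "posterior").pixels.sum()
        est = activity_pa(r_p, a, x, calib_truth)
        assert abs(est.activity / activity - 1) < 1e-6

    @pytest.mark.parametrize("delta", [-1.0, 0.5, 1.0, 2.0])
    def test_depth_misspecification_bias_is_exponential(self, camera, calib_truth, delta):
        activity, a, x = 77.0, 5.0, 6.0
        spec = box_phantom(camera, activity=activity, depth_a=a)
        r_p = build_projection(spec, "posterior").pixels.sum()
        est = activity_pa(r_p, a + delta, x, calib_truth)
        assert est.activity / activity == pytest.approx(math.exp(TRUE_MU * delta), rel=1e-9)
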