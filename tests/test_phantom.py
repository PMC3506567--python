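"""Forward model: slab attenuation, mirroring, noise, and series generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scintidose.phantom import (
    CameraModel,
    PhantomSpec,
    SourceRegion,
    biphasic_kinetics,
    build_projection,
    ellipsoid_footprint,
    make_calibration_series,
    make_patient_series,
    monoexp_kinetics,
    sample_counts,
)

from .conftest import TRUE_K, TRUE_MU, box_phantom


def slab_total_rate(k, A, mu, depth, x):
    """Independent closed form: footprint-summed rate of a box source."""
    return k * A * math.exp(-mu * depth) * (1 - math.exp(-mu * x)) / (mu * x)


class TestBuildProjection:
    def test_zero_activity_gives_zero_image(self, camera):
        spec = box_phantom(camera, activity=0.0)
        img = build_projection(spec, "posterior")
        assert np.all(img.pixels == 0)

    def test_posterior_total_matches_slab_closed_form(self, camera):
        spec = box_phantom(camera, activity=100.0, thickness_x=6.0, depth_a=4.0)
        img = build_projection(spec, "posterior")
        expected = slab_total_rate(TRUE_K, 100.0, TRUE_MU, 4.0, 6.0)
        assert img.pixels.sum() == pytest.approx(expected, rel=1e-12)

    def test_posterior_total_matches_per_pixel_numeric_summation(self, camera):
        # brute-force oracle: integrate attenuation over depth slices per pixel
        spec = box_phantom(camera, activity=100.0)
        img = build_projection(spec, "posterior")
        region = spec.compartments[0]
        n_pix = len(region.footprint)
        rho = region.activity / (n_pix * region.thickness_x * spec.pixel_size**2)
        dz = region.thickness_x / 20000
        z = np.arange(region.depth_a + dz / 2, region.depth_a + region.thickness_x, dz)
        per_pixel = TRUE_K * rho * np.sum(np.exp(-TRUE_MU * z)) * dz * spec.pixel_size**2
        assert img.pixels.sum() == pytest.approx(per_pixel * n_pix, rel=1e-6)

    def test_anterior_posterior_ratio_is_depth_asymmetry_factor(self, camera):
        T, x, a = 20.0, 6.0, 4.0
        spec = box_phantom(camera, thickness_x=x, depth_a=a, trunk_T=T)
        ant = build_projection(spec, "anterior").pixels.sum()
        post = build_projection(spec, "posterior").pixels.sum()
        assert ant / post == pytest.approx(math.exp(-TRUE_MU * (T - x - 2 * a)), rel=1e-12)

    def test_rate_linear_in_activity(self, camera):
        base = box_phantom(camera, activity=50.0)
        doubled = box_phantom(camera, activity=100.0)
        r1 = build_projection(base, "posterior").pixels.sum()
        r2 = build_projection(doubled, "posterior").pixels.sum()
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_posterior_rate_decreases_with_depth(self, camera):
        totals = [
            build_projection(box_phantom(camera, depth_a=a), "posterior").pixels.sum()
            for a in (0.0, 2.0, 5.0, 10.0)
        ]
        assert all(t1 > t2 for t1, t2 in zip(totals, totals[1:]))

    def test_anterior_image_of_symmetric_phantom_is_its_own_mirror(self, camera):
        # footprint symmetric about the vertical center line of a 31-wide grid
        footprint = frozenset((r, c) for r in range(10, 20) for c in range(13, 18))
        region = SourceRegion("kid", footprint, thickness_x=6.0, depth_a=4.0, activity=80.0)
        spec = PhantomSpec(20.0, 1.0, 32, 31, (region,), camera)
        ant = build_projection(spec, "anterior").pixels
        assert np.allclose(ant, ant[:, ::-1])

    def test_anterior_is_mirrored_relative_to_posterior(self, camera):
        # off-center source: anterior footprint lands on mirrored columns
        footprint = frozenset((r, c) for r in range(5, 8) for c in range(0, 3))
        region = SourceRegion("kid", footprint, thickness_x=2.0, depth_a=9.0, activity=10.0)
        spec = PhantomSpec(20.0, 1.0, 16, 16, (region,), camera)
        ant = build_projection(spec, "anterior").pixels
        assert ant[5, 0] == 0
        assert ant[5, 15] > 0

    def test_compartment_outside_slab_is_rejected_by_name(self, camera):
        footprint = frozenset({(1, 1)})
        region = SourceRegion("too_deep", footprint, thickness_x=6.0, depth_a=15.0, activity=1.0)
        with pytest.raises(ValueError, match="too_deep"):
            PhantomSpec(20.0, 1.0, 8, 8, (region,), camera)

    def test_ellipsoid_projects_less_than_enclosing_box_but_same_activity_total(self, camera):
        fp = ellipsoid_footprint((16, 16), (6.0, 4.0), (32, 32))
        ell = SourceRegion(
            "k", fp, thickness_x=6.0, depth_a=4.0, activity=100.0, shape="ellipsoid",
            center_cm=(16.5, 16.5), semi_axes_cm=(6.0, 4.0),
        )
        spec = PhantomSpec(20.0, 1.0, 32, 32, (ell,), camera)
        img = build_projection(spec, "posterior")
        # chord is maximal at the center pixel and falls off outward
        assert img.pixels[16, 16] == img.pixels.max()
        # total rate is bounded by the zero-attenuation limit k*A
        assert 0 < img.pixels.sum() < TRUE_K * 100.0


class TestSampleCounts:
    def test_zero_rate_gives_zero_counts(self, camera):
        spec = box_phantom(camera, activity=0.0)
        img = build_projection(spec, "posterior")
        counts = sample_counts(img, seed=1)
        assert np.all(counts.pixels == 0)

    def test_same_seed_is_reproducible(self, camera, phantom):
        img = build_projection(phantom, "posterior")
        a = sample_counts(img, seed=7)
        b = sample_counts(img, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_poisson_mean_recovered_over_many_seeds(self, camera):
        from scintidose.phantom import RateImage

        rate = RateImage(
            pixels=np.full((1, 1), 1e4), view="posterior", pixel_size=1.0, dwell_time=1.0
        )
        draws = [sample_counts(rate, seed=s).pixels[0, 0] for s in range(1000)]
        assert np.mean(draws) == pytest.approx(1e4, rel=0.01)


class TestCalibrationSeries:
    def test_zero_activity_gives_zero_series(self, camera):
        series = make_calibration_series(camera, [1.0, 2.0, 3.0], 0.0, 300.0)
        assert (series["counts"] == 0).all()

    def test_adjacent_depth_ratio_is_attenuation_factor(self, camera):
        series = make_calibration_series(camera, [4.0, 5.0], 330.0, 300.0)
        ratio = series["counts"].iloc[1] / series["counts"].iloc[0]
        assert ratio == pytest.approx(math.exp(-TRUE_MU), rel=1e-12)

    def test_seeded_series_reproducible(self, camera):
        a = make_calibration_series(camera, [1.0, 5.0, 9.0], 330.0, 300.0, seed=3)
        b = make_calibration_series(camera, [1.0, 5.0, 9.0], 330.0, 300.0, seed=3)
        assert a.equals(b)

    def test_empty_depths_rejected(self, camera):
        with pytest.raises(ValueError):
            make_calibration_series(camera, [], 330.0, 300.0)


class TestPatientSeries:
    def test_pure_physical_decay_when_lambda_bio_zero(self, camera, phantom):
        lam = 0.004
        series = make_patient_series(
            phantom, {"kidney": monoexp_kinetics(100.0, 0.0)},
            times_h=(1.0, 24.0), seed=0, lambda_phys=lam, noiseless=True,
        )
        t0_total = series[0][1].pixels.sum()
        t1_total = series[1][1].pixels.sum()
        assert t1_total / t0_total == pytest.approx(math.exp(-lam * 23.0), rel=1e-10)

    def test_monoexp_activities_follow_effective_decay(self, camera, phantom):
        lam_bio, lam_phys, a0 = 0.007, 0.00434, 100.0
        times = (1.0, 24.0, 48.0, 168.0)
        series = make_patient_series(
            phantom, {"kidney": monoexp_kinetics(a0, lam_bio)},
            times_h=times, seed=0, lambda_phys=lam_phys, noiseless=True,
        )
        base = build_projection(phantom.with_activities({"kidney": 1.0}), "posterior").pixels.sum()
        for (_, post, t) in series:
            expected = a0 * math.exp(-(lam_bio + lam_phys) * t)
            assert post.pixels.sum() / base == pytest.approx(expected, rel=1e-9)

    def test_biphasic_peaks_after_time_zero(self):
        lam_clear, lam_up = 0.005, 0.05
        kin = biphasic_kinetics(100.0, lam_clear, lam_up)
        t_peak = math.log(lam_up / lam_clear) / (lam_up - lam_clear)  # analytic maximum
        assert t_peak > 0
        assert kin(t_peak) > kin(0.0)
        assert kin(t_peak) > kin(t_peak * 4)

    def test_non_increasing_times_rejected(self, phantom):
        with pytest.raises(ValueError):
            make_patient_series(
                phantom, {"kidney": monoexp_kinetics(1.0, 0.0)}, times_h=(2.0, 1.0), seed=0
            )

    def test_nonpositive_a0_rejected(self):
        with pytest.raises(ValueError):
            monoexp_kinetics(0.0, 0.01)


@settings(max_examples=30, deadline=None)
@given(
    activity=st.floats(min_value=0.1, max_value=1e4),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_projection_scales_linearly_in_activity(activity, scale):
    camera = CameraModel(sensitivity_k=TRUE_K, mu=TRUE_MU, dwell_time=1.0)
    r1 = build_projection(box_phantom(camera, activity=activity), "posterior").pixels.sum()
    r2 = build_projection(box_phantom(camera, activity=activity * scale), "posterior").pixels.sum()
    assert r2 == pytest.approx(scale * r1, rel=1e-9)
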