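"""Tests for tilt/coma vectors, lid-wiper axes, projections, circular stats
and confidence ellipses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidwiper.metrics import (
    PolarVector,
    centroid,
    circular_sd,
    coma_vector,
    confidence_ellipse,
    compute_biomarkers,
    lid_wiper_coma,
    lid_wiper_gradient,
    lwa_from_means,
    lwa_standard_error,
    population_axes,
    tilt_vector,
    wrap_angle,
)
from lidwiper.zernike import CoefficientVector

# normative cohort means of (X-tilt, Y-tilt) and (X-coma, Y-coma), um
TILT_MEANS = (0.60, -1.13)
COMA_MEANS = (-0.14, 0.16)


def coeffs_with(**terms):
    c = np.zeros(21)
    mapping = {"y_tilt": 1, "x_tilt": 2, "y_coma": 7, "x_coma": 8}
    for k, v in terms.items():
        c[mapping[k]] = v
    return CoefficientVector(coeffs=c)


class TestPolarVector:
    def test_unit_x_vector(self):
        v = PolarVector.from_cartesian(1.0, 0.0)
        assert (v.magnitude, v.angle_deg) == (1.0, 0.0)

    def test_zero_vector_is_degenerate(self):
        v = PolarVector.from_cartesian(0.0, 0.0)
        assert v.degenerate and v.magnitude == 0.0 and v.angle_deg == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(-100, 100), y=st.floats(-100, 100))
    def test_cartesian_roundtrip(self, x, y):
        v = PolarVector.from_cartesian(x, y)
        bx, by = v.to_cartesian()
        assert math.isclose(bx, x, abs_tol=1e-9)
        assert math.isclose(by, y, abs_tol=1e-9)


class TestVectorsFromCoefficients:
    def test_tilt_vector_from_normative_means(self):
        cv = coeffs_with(x_tilt=TILT_MEANS[0], y_tilt=TILT_MEANS[1])
        v = tilt_vector(cv)
        assert v.magnitude == pytest.approx(1.2794, abs=1e-4)
        assert v.angle_deg == pytest.approx(297.97, abs=0.01)

    def test_coma_vector_is_sign_flipped(self):
        cv = coeffs_with(x_coma=COMA_MEANS[0], y_coma=COMA_MEANS[1])
        v = coma_vector(cv)
        assert v.magnitude == pytest.approx(0.2126, abs=1e-4)
        assert v.angle_deg == pytest.approx(311.19, abs=0.01)

    def test_pure_negative_y_coma_points_up_after_flip(self):
        v = coma_vector(coeffs_with(y_coma=-1.0))
        assert v.angle_deg == pytest.approx(90.0)


class TestLWA:
    def test_tilt_axis_matches_published_value(self):
        assert lwa_from_means([TILT_MEANS]) == pytest.approx(298.06, abs=1.0)

    def test_coma_axis_matches_published_value(self):
        assert lwa_from_means([(-COMA_MEANS[0], -COMA_MEANS[1])]) == pytest.approx(
            311.59, abs=1.0)

    def test_single_vector_at_45_degrees(self):
        assert lwa_from_means([(1.0, 1.0)]) == pytest.approx(45.0)

    def test_zero_mean_vector_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            lwa_from_means([(1.0, 0.0), (-1.0, 0.0)])

    def test_standard_error_shrinks_with_n(self, rng):
        base = rng.normal([0.6, -1.13], [0.76, 1.55], size=(50, 2))
        big = rng.normal([0.6, -1.13], [0.76, 1.55], size=(5000, 2))
        assert lwa_standard_error(big) < lwa_standard_error(base)


class TestProjections:
    def test_aligned_tilt_gives_unit_gradient(self):
        t = PolarVector(magnitude=2.5, angle_deg=123.0)
        assert lid_wiper_gradient(t, 123.0, zone_radius=2.5) == pytest.approx(1.0)

    def test_perpendicular_tilt_projects_to_zero(self):
        t = PolarVector(magnitude=2.5, angle_deg=30.0)
        assert lid_wiper_gradient(t, 120.0) == pytest.approx(0.0, abs=1e-12)

    def test_normative_mean_gradient(self):
        t = PolarVector.from_cartesian(*TILT_MEANS)
        lwa = lwa_from_means([TILT_MEANS])
        assert lid_wiper_gradient(t, lwa) == pytest.approx(0.512, abs=1e-3)

    def test_normative_mean_coma_projection(self):
        flipped = (-COMA_MEANS[0], -COMA_MEANS[1])
        c = PolarVector.from_cartesian(*flipped)
        lwa = lwa_from_means([flipped])
        assert lid_wiper_coma(c, lwa) == pytest.approx(0.213, abs=1e-3)

    def test_antiparallel_coma_projects_negative(self):
        c = PolarVector(magnitude=1.0, angle_deg=200.0)
        assert lid_wiper_coma(c, 20.0) == pytest.approx(-1.0)

    def test_zero_coma_projects_to_zero(self):
        c = PolarVector.from_cartesian(0.0, 0.0)
        assert lid_wiper_coma(c, 298.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(mag=st.floats(0.01, 10), ang=st.floats(0, 360), lwa=st.floats(0, 360))
    def test_projection_pythagoras(self, mag, ang, lwa):
        # parallel and perpendicular projections recover the magnitude
        v = PolarVector(magnitude=mag, angle_deg=ang)
        par = lid_wiper_gradient(v, lwa, zone_radius=1.0)
        perp = lid_wiper_gradient(v, lwa + 90.0, zone_radius=1.0)
        assert par**2 + perp**2 == pytest.approx(mag**2, rel=1e-9)


class TestCentroid:
    def test_identical_vectors(self):
        c = centroid([(1.0, 2.0)] * 5)
        assert c.to_cartesian() == pytest.approx((1.0, 2.0))

    def test_antipodal_pair_cancels(self):
        c = centroid([(1.0, 1.0), (-1.0, -1.0)])
        assert c.magnitude == pytest.approx(0.0, abs=1e-12)
        assert c.degenerate

    def test_matches_brute_force_mean(self, rng):
        pts = rng.normal(0, 1, size=(100, 2))
        c = centroid(pts)
        assert c.to_cartesian() == pytest.approx(tuple(pts.mean(axis=0)), abs=1e-12)

    def test_centroid_of_gradient_vectors_equals_mean_tilt_over_r(self, rng):
        # consistency between per-eye projections and the population mean
        tilts = rng.normal([0.6, -1.13], [0.76, 1.55], size=(200, 2))
        c = centroid(tilts / 2.5)
        mean = tilts.mean(axis=0)
        assert c.magnitude == pytest.approx(np.hypot(*mean) / 2.5, rel=1e-12)


class TestCircularSD:
    def test_identical_angles_have_zero_spread(self):
        assert circular_sd([77.0, 77.0, 77.0]) == pytest.approx(0.0, abs=1e-6)

    def test_right_angle_pair(self):
        # Rbar = cos(45 deg); sqrt(-2 ln Rbar) = 0.83255 rad = 47.70 deg
        assert circular_sd([0.0, 90.0]) == pytest.approx(47.70, abs=0.01)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.floats(-720, 720))
    def test_rotation_invariance(self, shift):
        angles = np.array([10.0, 40.0, 300.0, 355.0])
        assert circular_sd(angles + shift) == pytest.approx(
            circular_sd(angles), abs=1e-8)

    def test_uniform_angles_are_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            circular_sd([0.0, 90.0, 180.0, 270.0])


class TestConfidenceEllipse:
    def test_isotropic_data_ellipse_radius(self, rng):
        pts = rng.normal(0, 1, size=(10_000, 2))
        e = confidence_ellipse(pts, level=0.95)
        target = math.sqrt(5.991)
        assert e.semi_axes[0] == pytest.approx(target, rel=0.05)
        assert e.semi_axes[1] == pytest.approx(target, rel=0.05)

    def test_centroid_ellipse_shrinks_as_sqrt_n(self, rng):
        pts = rng.normal(0, 1, size=(4000, 2))
        data = confidence_ellipse(pts, level=0.95)
        mean = confidence_ellipse(pts, level=0.95, of_mean=True)
        assert mean.semi_axes[0] == pytest.approx(
            data.semi_axes[0] / math.sqrt(4000), rel=1e-9)

    def test_orientation_recovers_construction_rotation(self, rng):
        raw = rng.normal(0, [3.0, 0.5], size=(5000, 2))
        angle = 25.0
        a = math.radians(angle)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        e = confidence_ellipse(raw @ rot.T, level=0.95)
        assert e.orientation_deg % 180 == pytest.approx(angle, abs=2.0)

    def test_coverage_of_data_ellipse(self, rng):
        pts = rng.normal(0, 1, size=(20_000, 2))
        e = confidence_ellipse(pts, level=0.95)
        inside = np.mean([e.contains(p) for p in pts])
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_singular_cloud_raises(self):
        pts = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        with pytest.raises(ValueError, match="singular"):
            confidence_ellipse(pts)


class TestPopulationAxes:
    def test_thinning_directions_are_antipodal(self):
        cvs = [coeffs_with(x_tilt=TILT_MEANS[0], y_tilt=TILT_MEANS[1],
                           x_coma=COMA_MEANS[0], y_coma=COMA_MEANS[1])
               for _ in range(3)]
        records, axes = compute_biomarkers(cvs)
        assert wrap_angle(axes.tilt_lwa - 180.0) == pytest.approx(118.06, abs=1.0)
        assert wrap_angle(axes.coma_lwa - 180.0) == pytest.approx(131.59, abs=1.0)
        for r in records:
            assert r.lid_wiper_gradient == pytest.approx(0.512, abs=1e-3)
            assert r.lid_wiper_coma == pytest.approx(0.213, abs=1e-3)

    def test_axis_from_mean_vector_not_circular_mean(self):
        # two eyes with very different magnitudes: the mean vector leans
        # toward the stronger one, unlike a circular mean of unit axes
        vectors = [(10.0, 0.0), (0.0, 1.0)]
        assert lwa_from_means(vectors) == pytest.approx(
            math.degrees(math.atan2(0.5, 5.0)))
        axes = population_axes(vectors, [(1.0, 0.0), (0.0, 1.0)])
        assert axes.tilt_lwa < 45.0
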