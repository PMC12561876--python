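"""Segment-angle and slope metrics on centerlines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from stentmorph import (
    Centerline,
    SegmentVector,
    algorithm1_change,
    algorithm1_profile,
    algorithm2_slope,
    angle_between,
    fit_segment_vector,
    split_segments,
)


def _sinusoid_centerline(amplitude, wavelength, n_rows=400, phase=0.0) -> Centerline:
    t = np.arange(n_rows, dtype=float)
    return Centerline(t, amplitude * np.sin(2 * np.pi * t / wavelength + phase))


class TestSplitSegments:
    def test_even_division(self):
        segs = split_segments(Centerline(np.arange(200.0), np.zeros(200)), k=100)
        assert len(segs) == 100
        assert all(len(s) == 2 for s in segs)

    def test_remainder_spread_over_leading_segments(self):
        segs = split_segments(Centerline(np.arange(205.0), np.zeros(205)), k=100)
        sizes = [len(s) for s in segs]
        assert sizes[:5] == [3] * 5 and sizes[5:] == [2] * 95
        assert sum(sizes) == 205
        # contiguous, ordered, non-overlapping partition
        joined = np.concatenate([s[:, 0] for s in segs])
        assert np.array_equal(joined, np.arange(205.0))

    def test_k_one_is_whole_centerline(self):
        cl = Centerline(np.arange(10.0), np.zeros(10))
        (seg,) = split_segments(cl, k=1)
        assert len(seg) == 10

    def test_too_few_points_names_minimum(self):
        with pytest.raises(ValueError, match="200"):
            split_segments(Centerline(np.arange(150.0), np.zeros(150)), k=100)


def _principal_direction_oracle(points: np.ndarray) -> np.ndarray:
    """Closed-form dominant eigenvector of the 2x2 scatter matrix."""
    c = points - points.mean(axis=0)
    a = float((c[:, 0] ** 2).sum())
    b = float((c[:, 0] * c[:, 1]).sum())
    d = float((c[:, 1] ** 2).sum())
    lam = 0.5 * (a + d) + math.sqrt(0.25 * (a - d) ** 2 + b * b)
    if b != 0:
        v = np.array([b, lam - a])
    elif a >= d:
        v = np.array([1.0, 0.0])
    else:
        v = np.array([0.0, 1.0])
    return v / np.linalg.norm(v)


class TestFitSegmentVector:
    def test_vertical_line(self):
        pts = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        v = fit_segment_vector(pts)
        assert (v.vx, v.vy) == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_45_degree_line(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        v = fit_segment_vector(pts)
        assert (v.vx, v.vy) == pytest.approx((math.sqrt(2) / 2, math.sqrt(2) / 2), abs=1e-12)

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="degenerate segment"):
            fit_segment_vector(np.ones((4, 2)))

    def test_matches_closed_form_eigenvector_on_random_clouds(self, rng):
        for _ in range(100):
            n = rng.integers(2, 60)
            slope = rng.normal(0, 1.5)
            t = np.sort(rng.uniform(0, 20, n))
            pts = np.column_stack([t, slope * t + rng.normal(0, 0.3, n)])
            if not (pts - pts.mean(0)).any():
                continue
            v = fit_segment_vector(pts)
            w = _principal_direction_oracle(pts)
            if w[0] < 0 or (w[0] == 0 and w[1] < 0):
                w = -w
            assert np.allclose([v.vy, v.vx], w, atol=1e-6)


class TestAngleBetween:
    def test_identical_vectors_zero(self):
        v = SegmentVector(0.0, 1.0)
        assert angle_between(v, v) == 0.0

    def test_orthogonal_vectors_ninety(self):
        assert angle_between(SegmentVector(1.0, 0.0), SegmentVector(0.0, 1.0)) == pytest.approx(90.0)

    def test_dot_product_overshoot_returns_exact_zero(self):
        # |v|^2 = 1 + 1e-14 passes the unit check but dots with itself to > 1
        v = SegmentVector(1e-7, 1.0)
        assert v.vx * v.vx + v.vy * v.vy > 1.0
        assert angle_between(v, v) == 0.0

    def test_pi_approximation_flag_scales_conversion(self):
        a, b = SegmentVector(1.0, 0.0), SegmentVector(0.0, 1.0)
        assert angle_between(a, b, pi_value=3.14) == pytest.approx(90.0 * math.pi / 3.14)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0, math.pi), st.floats(0, math.pi))
    def test_symmetric_and_bounded(self, t1, t2):
        a = SegmentVector(math.cos(t1), math.sin(t1)) if math.sin(t1) > 0 else SegmentVector(abs(math.cos(t1)), abs(math.sin(t1)))
        b = SegmentVector(math.cos(t2), math.sin(t2)) if math.sin(t2) > 0 else SegmentVector(abs(math.cos(t2)), abs(math.sin(t2)))
        assert angle_between(a, b) == angle_between(b, a)
        assert 0.0 <= angle_between(a, b) <= 180.0


class TestAlgorithm1:
    def test_straight_centerline_all_angles_zero(self):
        cl = Centerline(np.arange(300.0), np.full(300, 12.0))
        profile = algorithm1_profile(cl, k=100)
        assert profile.mean_deg == pytest.approx(0.0, abs=1e-9)
        assert profile.angles_deg.size == 99

    def test_two_arms_meeting_at_thirty_degrees(self):
        # two straight arms, 15 degrees either side of vertical: interior bend of 30
        n = 20
        t = np.arange(2 * n, dtype=float)
        slope = math.tan(math.radians(15.0))
        lateral = np.where(t < n, slope * t, slope * (n - 1) - slope * (t - (n - 1)))
        profile = algorithm1_profile(Centerline(t, lateral), k=2)
        assert profile.angles_deg.tolist() == [pytest.approx(30.0, abs=1e-9)]

    def test_mean_angle_increases_with_amplitude(self):
        means = [
            algorithm1_profile(_sinusoid_centerline(a, 180.0), k=100).mean_deg
            for a in (5.0, 10.0, 15.0, 20.0)
        ]
        assert np.all(np.diff(means) > 0)


class TestAlgorithm1Change:
    def test_identical_centerlines_give_zero(self):
        cl = _sinusoid_centerline(10.0, 300.0)
        profile = algorithm1_change(cl, cl, k=100)
        assert profile.angles_deg.size == 100
        # acos near a dot product of 1 amplifies rounding to ~sqrt(eps)
        assert profile.mean_deg == pytest.approx(0.0, abs=1e-5)

    def test_rigid_rotation_appears_in_every_segment(self):
        cl = _sinusoid_centerline(10.0, 300.0)
        theta = math.radians(10.0)
        pts = cl.as_points() - cl.as_points().mean(axis=0)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        rotated = pts @ rot.T
        post = Centerline(rotated[:, 0], rotated[:, 1])
        profile = algorithm1_change(cl, post, k=100)
        assert np.allclose(profile.angles_deg, 10.0, atol=1e-6)

    def test_straightening_cohort_pair_changes_angles(self):
        pre = _sinusoid_centerline(16.0, 250.0)
        post = _sinusoid_centerline(8.0, 250.0)
        assert algorithm1_change(pre, post, k=100).mean_deg > 0


class TestAlgorithm2:
    def test_single_step_gradient(self):
        profile = algorithm2_slope(Centerline(np.array([0.0, 1.0]), np.array([0.0, 3.0])))
        assert profile.gradients.tolist() == [3.0]
        assert profile.abs_sum == 3.0
        assert profile.mean_abs == 3.0

    def test_vertical_centerline_scores_zero(self):
        profile = algorithm2_slope(Centerline(np.arange(50.0), np.full(50, 9.0)))
        assert profile.mean_abs == 0.0

    def test_dense_sinusoid_matches_quadrature_oracle(self):
        A, lam, n = 12.0, 240.0, 4800  # integer number of periods
        cl = _sinusoid_centerline(A, lam, n_rows=n)
        omega = 2 * np.pi / lam
        analytic, _ = integrate.quad(
            lambda t: abs(A * omega * np.cos(omega * t)), 0, n - 1, limit=400
        )
        analytic /= n - 1
        assert algorithm2_slope(cl).mean_abs == pytest.approx(analytic, rel=0.02)

    def test_reversal_invariance_of_mean_abs(self):
        cl = _sinusoid_centerline(9.0, 130.0, n_rows=300)
        reversed_cl = Centerline(-cl.axial[::-1], cl.lateral[::-1])
        assert algorithm2_slope(reversed_cl).mean_abs == pytest.approx(
            algorithm2_slope(cl).mean_abs, abs=1e-12
        )


def test_translation_invariance_of_both_metrics():
    cl = _sinusoid_centerline(11.0, 170.0, n_rows=300)
    shifted = Centerline(cl.axial + 37.0, cl.lateral - 12.5)
    assert algorithm1_profile(shifted, k=50).mean_deg == pytest.approx(
        algorithm1_profile(cl, k=50).mean_deg, abs=1e-9
    )
    assert algorithm2_slope(shifted).mean_abs == pytest.approx(
        algorithm2_slope(cl).mean_abs, abs=1e-12
    )
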