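"""Unit and property tests for the tortuosity metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocutort.metrics import (
    DegeneratePolylineError,
    MetricConfig,
    arc_length,
    compute_all,
    i2e,
    pad,
    resample_polyline,
    soam,
    turning_angles,
)


def circle_points(r, ds, n, center=(0.0, 0.0)):
    """n+1 points along a circle of radius r at uniform arc step ds."""
    t = np.arange(n + 1) * ds / r
    return np.column_stack((center[0] + r * np.cos(t), center[1] + r * np.sin(t)))


class TestResampling:
    def test_line_point_count(self):
        line = np.array([[0.0, 0.0], [100.0, 0.0]])
        rs = resample_polyline(line, 5.0)
        assert rs.shape == (21, 2)
        assert np.allclose(np.diff(rs[:, 0]), 5.0)

    def test_idempotent_on_uniform_polyline(self):
        p = np.column_stack((np.arange(0, 105, 5.0), np.zeros(21)))
        rs = resample_polyline(p, 5.0)
        assert np.allclose(rs, p, atol=1e-9)

    def test_endpoints_preserved_exactly(self):
        p = np.array([[0.3, 0.7], [10.2, 5.5], [20.9, -3.1]])
        rs = resample_polyline(p, 3.0)
        assert np.array_equal(rs[0], p[0])
        assert np.array_equal(rs[-1], p[-1])

    def test_semicircle_arc_length(self):
        # dense semicircle resampled at 1 px: arc length within 0.5% of pi*r
        r = 100.0
        t = np.linspace(0, np.pi, 4000)
        dense = np.column_stack((r * np.cos(t), r * np.sin(t)))
        rs = resample_polyline(dense, 1.0)
        assert arc_length(rs) == pytest.approx(np.pi * r, rel=5e-3)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegeneratePolylineError):
            resample_polyline(np.zeros((5, 2)), 1.0)


class TestTurningAngles:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([[0, 0], [1, 0], [2, 0]], [0.0]),  # collinear
            ([[0, 0], [1, 0], [1, 1]], [np.pi / 2]),  # right angle
        ],
    )
    def test_known_angles(self, points, expected):
        assert np.allclose(turning_angles(np.array(points, float)), expected)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_regular_polygon_exterior_angles(self, n):
        t = 2 * np.pi * np.arange(n + 2) / n
        poly = np.column_stack((np.cos(t), np.sin(t)))
        assert np.allclose(turning_angles(poly), 2 * np.pi / n, atol=1e-12)

    def test_zero_chord_rejected(self):
        with pytest.raises(DegeneratePolylineError):
            turning_angles(np.array([[0, 0], [0, 0], [1, 1]], float))


class TestClosedForms:
    def test_straight_line_degenerate_values(self):
        line = np.column_stack((np.linspace(0, 400, 81), np.zeros(81)))
        res = compute_all(line)
        assert res.soam == 0.0
        assert res.pad == 0.0
        assert res.i2e == 1.0

    def test_right_angle_hand_computation(self):
        p = np.array([[0, 0], [1, 0], [1, 1]], float)
        assert soam(p) == pytest.approx(np.pi / 4, abs=1e-12)
        assert pad(p) == pytest.approx(np.pi / 4, abs=1e-12)
        assert i2e(p, e=1) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_circle_soam_inverse_radius(self):
        # total turning of an arc equals arclength / radius
        p = circle_points(r=200.0, ds=2.0, n=200)
        assert soam(p) == pytest.approx(1 / 200.0, rel=1e-2)

    def test_circle_i2e_closed_form(self):
        # 1 / cos(e*ds / (2r)) exactly for uniform arc-step circle samples
        r, ds = 100.0, 10.0
        p = circle_points(r, ds, n=40)
        assert i2e(p, e=1) == pytest.approx(1 / math.cos(ds / (2 * r)), abs=1e-6)
        assert i2e(p, e=2) == pytest.approx(1 / math.cos(2 * ds / (2 * r)), abs=1e-6)

    def test_pad_equals_spacing_times_soam_under_uniform_spacing(self):
        rng = np.random.default_rng(5)
        steps = rng.normal(size=(40, 2))
        steps = 3.0 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        p = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
        assert pad(p) == pytest.approx(3.0 * soam(p), rel=1e-12)


def naive_metrics(p, e=2):
    """Independent loop-based oracle for SOAM / PAD / I2e."""
    p = np.asarray(p, float)
    L = sum(
        math.dist(p[k], p[k + 1]) for k in range(len(p) - 1)
    )
    thetas, dists = [], []
    for k in range(1, len(p) - 1):
        v0 = p[k] - p[k - 1]
        v1 = p[k + 1] - p[k]
        c = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
        thetas.append(math.acos(max(-1.0, min(1.0, c))))
        dists.append(0.5 * (np.linalg.norm(v0) + np.linalg.norm(v1)))
    ratios = []
    for k in range(e, len(p) - e):
        a = math.dist(p[k - e], p[k])
        b = math.dist(p[k], p[k + e])
        base = math.dist(p[k - e], p[k + e])
        ratios.append((a + b) / base)
    return (
        sum(thetas) / L,
        sum(t * d for t, d in zip(thetas, dists)) / L,
        sum(ratios) / len(ratios),
    )


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_polylines_match_naive_implementation(self, seed):
        rng = np.random.default_rng(seed)
        # random 10-point walks that never fold back exactly
        steps = rng.uniform(1.0, 4.0, 9)[:, None] * _unit(rng.normal(size=(9, 2)))
        p = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
        s0, p0, i0 = naive_metrics(p, e=2)
        assert soam(p) == pytest.approx(s0, abs=1e-12)
        assert pad(p) == pytest.approx(p0, abs=1e-12)
        assert i2e(p, e=2) == pytest.approx(i0, abs=1e-12)


def _unit(v):
    return v / np.linalg.norm(v, axis=1, keepdims=True)


coords = st.floats(-500, 500)


@st.composite
def rough_polylines(draw):
    """Random polylines with chords long enough to avoid degeneracy."""
    n = draw(st.integers(8, 25))
    seed = draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    headings = np.cumsum(rng.uniform(-0.6, 0.6, n))
    steps = rng.uniform(2.0, 6.0, n)[:, None] * np.column_stack(
        (np.cos(headings), np.sin(headings))
    )
    return np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))


class TestInvariants:
    @given(rough_polylines(), st.floats(-300, 300), st.floats(-300, 300),
           st.floats(0, 2 * np.pi))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance(self, p, tx, ty, ang):
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        q = p @ rot.T + np.array([tx, ty])
        assert soam(q) == pytest.approx(soam(p), rel=1e-9)
        assert pad(q) == pytest.approx(pad(p), rel=1e-9)
        assert i2e(q) == pytest.approx(i2e(p), rel=1e-9)

    @given(rough_polylines())
    @settings(max_examples=40, deadline=None)
    def test_reversal_invariance(self, p):
        q = p[::-1]
        assert soam(q) == pytest.approx(soam(p), rel=1e-12)
        assert pad(q) == pytest.approx(pad(p), rel=1e-12)
        assert i2e(q) == pytest.approx(i2e(p), rel=1e-12)

    @given(rough_polylines(), st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_scaling_behavior(self, p, s):
        q = p * s
        # SOAM scales inversely; PAD and I2e are scale-free
        assert soam(q) == pytest.approx(soam(p) / s, rel=1e-9)
        assert pad(q) == pytest.approx(pad(p), rel=1e-9)
        assert i2e(q) == pytest.approx(i2e(p), rel=1e-9)

    @given(rough_polylines())
    @settings(max_examples=40, deadline=None)
    def test_ranges(self, p):
        assert soam(p) >= 0
        assert pad(p) >= 0
        assert i2e(p) >= 1.0 - 1e-12


class TestComputeAll:
    def test_reversed_polyline_identical_result(self, rng):
        p = np.column_stack((np.linspace(0, 400, 200),
                             10 * np.sin(np.linspace(0, 8 * np.pi, 200))))
        a = compute_all(p)
        b = compute_all(p[::-1])
        assert a.soam == pytest.approx(b.soam, rel=1e-9)
        assert a.pad == pytest.approx(b.pad, rel=1e-9)
        assert a.i2e == pytest.approx(b.i2e, rel=1e-9)

    def test_min_points_enforced(self):
        short = np.array([[0, 0], [30, 0]], float)
        with pytest.raises(DegeneratePolylineError):
            compute_all(short, MetricConfig(resample_spacing_px=5.0, min_points=10))

    def test_folding_curve_rejected_by_i2e(self):
        # out-and-back path: p[k-e] coincides with p[k+e]
        p = np.array([[0, 0], [5, 0], [10, 0], [5, 0], [0, 0]], float)
        with pytest.raises(DegeneratePolylineError):
            i2e(p, e=2)

    def test_provenance_carried_through(self):
        line = np.column_stack((np.linspace(0, 400, 81), np.zeros(81)))
        res = compute_all(line, subject_id="s1", site="retina", eye="OD")
        assert (res.subject_id, res.site, res.eye) == ("s1", "retina", "OD")
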