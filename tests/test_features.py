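"""Loop geometry features against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcgmi import (arc_length, beat_features, fit_optimal_plane, loop_area,
                   max_centroid_distance, max_vector, project_to_plane,
                   record_features, velocity_stats)
from vcgmi.delineate import BeatLoops
from vcgmi.features import DegenerateLoopError
from vcgmi.io import FEATURE_NAMES


def random_rotation(rng):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))


def tilted_ellipse(a, b, n, rng, center=None):
    """A planar ellipse with known half-axes in a random 3D orientation."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    flat = np.column_stack([a * np.cos(theta), b * np.sin(theta),
                            np.zeros(n)])
    rot = random_rotation(rng)
    pts = flat @ rot.T
    if center is not None:
        pts = pts + np.asarray(center)
    return pts


class TestOptimalPlane:
    def test_planar_points_have_null_third_singular_value(self):
        rng = np.random.default_rng(0)
        flat = rng.standard_normal((50, 2))
        pts = np.column_stack([flat, np.full(50, 2.0)])
        plane = fit_optimal_plane(pts)
        assert plane.singular_values[2] < 1e-9
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_centroid_is_the_mean(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]], float)
        assert np.allclose(fit_optimal_plane(pts).centroid, [1, 1, 0])

    def test_recovers_construction_normal(self):
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        pts = tilted_ellipse(2.0, 0.7, 100, np.random.default_rng(2))
        plane = fit_optimal_plane(pts)
        # the normal of the fitted plane annihilates every centered point
        proj = (pts - plane.centroid) @ plane.normal
        assert np.max(np.abs(proj)) < 1e-9

    def test_axes_are_orthonormal(self):
        pts = np.random.default_rng(3).standard_normal((30, 3))
        plane = fit_optimal_plane(pts)
        assert np.allclose(plane.axes.T @ plane.axes, np.eye(3), atol=1e-9)
        assert np.all(np.diff(plane.singular_values) <= 1e-12)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateLoopError):
            fit_optimal_plane(np.ones((5, 3)))


class TestProjection:
    def test_isometric_on_planar_loops(self):
        pts = tilted_ellipse(1.5, 0.5, 80, np.random.default_rng(4))
        loop2d = project_to_plane(pts, fit_optimal_plane(pts))
        d3 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d2 = np.linalg.norm(loop2d[:, None] - loop2d[None, :], axis=-1)
        assert np.max(np.abs(d3 - d2)) < 1e-9

    def test_centroid_projects_to_origin(self):
        pts = np.random.default_rng(5).standard_normal((20, 3))
        plane = fit_optimal_plane(pts)
        assert np.allclose(project_to_plane(plane.centroid[None], plane), 0.0,
                           atol=1e-12)

    def test_equals_dot_product_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((40, 3))
        plane = fit_optimal_plane(pts)
        got = project_to_plane(pts, plane)
        oracle = np.array([[(p - plane.centroid) @ plane.axes[:, 0],
                            (p - plane.centroid) @ plane.axes[:, 1]]
                           for p in pts])
        assert np.allclose(got, oracle, atol=1e-12)


class TestArcLength:
    def test_dense_unit_circle(self):
        theta = np.linspace(0, 2 * np.pi, 1000)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        assert arc_length(circle) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_two_points(self):
        assert arc_length(np.array([[0, 0], [3, 4]])) == 5.0

    def test_matches_segment_sum_oracle(self):
        rng = np.random.default_rng(7)
        poly = rng.standard_normal((25, 2))
        oracle = sum(float(np.linalg.norm(poly[i + 1] - poly[i]))
                     for i in range(len(poly) - 1))
        assert arc_length(poly) == pytest.approx(oracle, abs=1e-12)

    def test_does_not_close_the_loop(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert arc_length(square) == 3.0  # no closing segment


class TestMaxVector:
    def test_single_point(self):
        assert max_vector(np.array([[1.0, 2.0, 2.0]])) == 3.0

    def test_per_lead_maxima_combine_non_simultaneously(self):
        pts = np.array([[3, 0, 0], [0, 4, 0]], float)
        assert max_vector(pts) == 5.0           # literal per-lead maxima
        assert max_vector(pts, strict_max_norm=True) == 4.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((30, 3))
        oracle = np.sqrt(pts[:, 0].max() ** 2 + pts[:, 1].max() ** 2
                         + pts[:, 2].max() ** 2)
        assert max_vector(pts) == pytest.approx(oracle, abs=1e-12)


class TestMaxCentroidDistance:
    def test_unit_circle(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(400)])
        assert max_centroid_distance(pts) == pytest.approx(1.0, abs=1e-9)

    def test_square_vertices(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0]], float)
        assert max_centroid_distance(pts) == pytest.approx(np.sqrt(2))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((35, 3))
        c = pts.mean(axis=0)
        oracle = max(float(np.linalg.norm(p - c)) for p in pts)
        assert max_centroid_distance(pts) == pytest.approx(oracle, abs=1e-12)


class TestVelocityStats:
    def test_constant_speed_line(self):
        pts = np.outer(np.arange(100) * 0.001, [1.0, 0.0, 0.0])
        vmax, vmean, vstd = velocity_stats(pts, fs=1000.0)
        assert (vmax, vmean, vstd) == pytest.approx((1.0, 1.0, 0.0), abs=1e-9)

    def test_uniform_circle_mean_speed(self):
        r, d, fs = 0.8, 0.2, 1000.0
        n = int(d * fs)
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.zeros(n)])
        _, vmean, _ = velocity_stats(pts, fs)
        assert vmean == pytest.approx(2 * np.pi * r / d, rel=5e-3)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((40, 3))
        speeds = [float(np.linalg.norm(pts[i + 1] - pts[i])) * 500.0
                  for i in range(39)]
        vmax, vmean, vstd = velocity_stats(pts, fs=500.0)
        assert vmax == pytest.approx(max(speeds), abs=1e-9)
        assert vmean == pytest.approx(np.mean(speeds), abs=1e-9)
        assert vstd == pytest.approx(np.std(speeds), abs=1e-9)


class TestLoopArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert loop_area(sq) == 1.0

    def test_triangle(self):
        tri = np.array([[0, 0], [1, 0], [0, 1]], float)
        assert loop_area(tri) == 0.5

    def test_matches_fan_triangulation_oracle(self):
        rng = np.random.default_rng(11)
        # star-shaped polygon: sorted angles, random radii -> always simple
        angles = np.sort(rng.uniform(0, 2 * np.pi, 17))
        radii = rng.uniform(0.5, 2.0, 17)
        poly = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        fan = 0.0
        for i in range(1, len(poly) - 1):
            v1, v2 = poly[i] - poly[0], poly[i + 1] - poly[0]
            fan += 0.5 * (v1[0] * v2[1] - v1[1] * v2[0])
        assert loop_area(poly) == pytest.approx(abs(fan), abs=1e-12)

    def test_figure_eight_gives_absolute_signed_area(self):
        # bowtie: the two lobes have opposite orientation, signed sum 0
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        assert loop_area(bowtie) == pytest.approx(0.0, abs=1e-12)


class TestBeatFeatures:
    def _beat(self, rng, a=1.2, b=0.5):
        qrs = tilted_ellipse(a, b, 100, rng)
        t = tilted_ellipse(0.4 * a, 0.4 * b, 200, rng)
        return BeatLoops(r_index=500, qrs_points=qrs, t_points=t,
                         rr_prev_ms=800.0)

    def test_planar_ellipse_area_and_perimeter(self):
        rng = np.random.default_rng(12)
        a, b = 1.3, 0.6
        beat = self._beat(rng, a, b)
        feats = beat_features(beat, fs=1000.0)
        assert feats["areaQRS"] == pytest.approx(np.pi * a * b, rel=0.01)
        # Ramanujan's ellipse perimeter approximation
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert feats["arcQRS"] == pytest.approx(perim, rel=0.01)

    def test_homogeneity_under_voltage_doubling(self):
        rng = np.random.default_rng(13)
        beat = self._beat(rng)
        doubled = BeatLoops(beat.r_index, 2 * beat.qrs_points,
                            2 * beat.t_points, beat.rr_prev_ms)
        f1 = beat_features(beat, fs=1000.0)
        f2 = beat_features(doubled, fs=1000.0)
        for name in FEATURE_NAMES:
            factor = 4.0 if name.startswith("area") else 2.0
            assert f2[name] == pytest.approx(factor * f1[name], rel=1e-9)

    def test_rigid_motion_invariance_except_max_vector(self):
        rng = np.random.default_rng(14)
        beat = self._beat(rng)
        f1 = beat_features(beat, fs=1000.0)
        rot = random_rotation(rng)
        shift = rng.standard_normal(3)
        moved = BeatLoops(beat.r_index, beat.qrs_points @ rot.T + shift,
                          beat.t_points @ rot.T + shift, beat.rr_prev_ms)
        f2 = beat_features(moved, fs=1000.0)
        for name in FEATURE_NAMES:
            if name in ("maxVecQRS", "maxVecT"):
                continue  # literal per-lead maxima are frame-dependent
            assert f2[name] == pytest.approx(f1[name], rel=1e-6)
        # the maxima follow the literal per-lead formula in the new frame
        q = moved.qrs_points
        literal = np.sqrt(q[:, 0].max() ** 2 + q[:, 1].max() ** 2
                          + q[:, 2].max() ** 2)
        assert f2["maxVecQRS"] == pytest.approx(literal, abs=1e-12)


class TestRecordFeatures:
    def test_single_beat_identity(self):
        v = {k: float(i) for i, k in enumerate(FEATURE_NAMES)}
        assert record_features([v]) == v

    def test_median_aggregation(self):
        vs = [{k: x for k in FEATURE_NAMES} for x in (1.0, 2.0, 9.0)]
        agg = record_features(vs)
        assert all(v == 2.0 for v in agg.values())
        mean_agg = record_features(vs, aggregate="mean")
        assert all(v == 4.0 for v in mean_agg.values())

    def test_unknown_aggregate_rejected(self):
        v = {k: 0.0 for k in FEATURE_NAMES}
        with pytest.raises(ValueError):
            record_features([v], aggregate="mode")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_projected_arc_length_equals_3d_for_planar_loops(seed):
    """Projection onto the optimal plane preserves planar arc length."""
    rng = np.random.default_rng(seed)
    pts = tilted_ellipse(rng.uniform(0.5, 2.0), rng.uniform(0.2, 0.5),
                         60, rng, center=rng.standard_normal(3))
    loop2d = project_to_plane(pts, fit_optimal_plane(pts))
    arc3d = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    assert arc_length(loop2d) == pytest.approx(arc3d, abs=1e-9)
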