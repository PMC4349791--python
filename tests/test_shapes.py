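"""Boundary representations: canonical polygon, B-spline, resampling, GPA."""

import numpy as np
import pytest

from spineret.shapes import (
    Contour,
    NinePointShape,
    bspline_boundary,
    bspline_control_points,
    canonical_contour,
    evaluate_periodic_bspline,
    procrustes_align,
    resample_contour,
)
from spineret.synthetic import class_by_name, classes_for_region, sample_shape

from conftest import random_smooth_contour


# ---------------------------------------------------------------- oracles
def deboor_point(control, t):
    """Independent de Boor (Cox-de Boor recursion) evaluation of the same
    periodic uniform cubic B-spline: knots -3..n+3, wrapped coefficients."""
    control = np.asarray(control, float)
    n = len(control)
    coeffs = np.vstack([control, control[:3]])
    knots = np.arange(-3, n + 4, dtype=float)
    t = t % n

    def basis(i, k):
        if k == 0:
            return 1.0 if knots[i] <= t < knots[i + 1] else 0.0
        left = (t - knots[i]) / (knots[i + k] - knots[i]) * basis(i, k - 1)
        right = (knots[i + k + 1] - t) / (knots[i + k + 1] - knots[i + 1]) * basis(
            i + 1, k - 1
        )
        return left + right

    return sum(coeffs[i] * basis(i, 3) for i in range(len(coeffs)))


def ordered_polygon_oracle(points):
    """Independent duplicate-collapsing pass over the 9 landmarks in order."""
    out = []
    for p in points:
        if not out or np.linalg.norm(p - out[-1]) > 1e-9:
            out.append(p)
    if len(out) > 1 and np.linalg.norm(out[-1] - out[0]) <= 1e-9:
        out.pop()
    return np.asarray(out)


def arc_position_on_polygon(point, poly):
    """Arc-length coordinate of a point lying on a closed polygon."""
    ring = np.vstack([poly, poly[:1]])
    s = 0.0
    for a, b in zip(ring[:-1], ring[1:]):
        seg = b - a
        seg_len = np.linalg.norm(seg)
        u = np.dot(point - a, seg) / seg_len**2
        if -1e-9 <= u <= 1 + 1e-9:
            proj = a + np.clip(u, 0, 1) * seg
            if np.linalg.norm(point - proj) < 1e-6:
                return s + np.clip(u, 0, 1) * seg_len
        s += seg_len
    raise AssertionError("point not on polygon")


# ---------------------------------------------------------------- tests
class TestCanonicalContour:
    def test_normal_shape_collapses_to_seven_vertices(self):
        shape = sample_shape(class_by_name("cervical", "normal"), seed=1)
        contour = canonical_contour(shape)
        assert len(contour) == 7
        assert contour.closed

    def test_rectangle_perimeter_exact(self):
        w, h = 40.0, 20.0
        pts = np.array(
            [
                [0, h], [w / 2, h], [w, h],  # lower edge (y down: larger y)
                [w, 0], [w / 2, 0], [0, 0],  # upper edge
                [0, 0], [0, h / 2], [0, h],  # anterior edge, 7==6 and 9==1
            ],
            dtype=float,
        )
        shape = NinePointShape(pts)
        assert canonical_contour(shape).perimeter() == 2 * (w + h)

    def test_traversal_order_matches_oracle_on_random_shapes(self):
        labels = [c for c in classes_for_region("cervical")]
        for seed in range(50):
            shape = sample_shape(labels[seed % len(labels)], seed=seed)
            contour = canonical_contour(shape)
            assert np.allclose(contour.points, ordered_polygon_oracle(shape.points))

    def test_self_intersection_warns_but_returns(self):
        pts = np.array(
            [[0, 10], [10, 12], [20, 10], [0, 0], [10, -2], [20, 0],
             [20, 0], [20, 5], [0, 10]],
            dtype=float,
        )  # posterior/anterior corners swapped -> bow-tie
        shape = NinePointShape(pts)
        with pytest.warns(RuntimeWarning, match="self-intersects"):
            contour = canonical_contour(shape)
        assert len(contour) >= 4


class TestResampleContour:
    def test_circle_points_stay_on_circle(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        r = 10.0
        c = Contour(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        out = resample_contour(c, 128)
        assert len(out) == 128
        radii = np.linalg.norm(out.points, axis=1)
        assert np.all(np.abs(radii - r) < 0.01 * r)

    def test_perimeter_preserved_on_random_smooth_contours(self, rng):
        for _ in range(50):
            c = Contour(random_smooth_contour(rng))
            out = resample_contour(c, 128)
            assert abs(out.perimeter() - c.perimeter()) / c.perimeter() < 0.005

    def test_open_contour_rejected(self):
        c = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), closed=False)
        with pytest.raises(ValueError, match="closed"):
            resample_contour(c, 16)


class TestBSpline:
    def test_collinear_control_points_stay_on_segment(self):
        control = np.column_stack([np.linspace(0, 9, 10), np.linspace(0, 18, 10)])
        pts = evaluate_periodic_bspline(control, np.linspace(0, 10, 200, endpoint=False))
        # convex hull of collinear points is the segment y = 2x
        assert np.all(np.abs(pts[:, 1] - 2 * pts[:, 0]) < 1e-9)

    def test_matches_de_boor_recursion_oracle(self):
        rng = np.random.default_rng(3)
        control = rng.uniform(-10, 10, size=(27, 2))
        params = rng.uniform(0, 27, size=200)
        ours = evaluate_periodic_bspline(control, params)
        expected = np.array([deboor_point(control, t) for t in params])
        assert np.max(np.abs(ours - expected)) < 1e-9

    def test_27_control_points_equally_spaced_by_arc_length(self):
        shape = sample_shape(class_by_name("cervical", "severe-claw"), seed=9)
        poly = canonical_contour(shape)
        control = bspline_control_points(shape, 27)
        perimeter = poly.perimeter()
        arcs = np.array([arc_position_on_polygon(p, poly.points) for p in control])
        gaps = np.diff(arcs)
        assert np.all(np.abs(gaps - perimeter / 27) < 1e-6)

    def test_boundary_has_requested_samples(self):
        shape = sample_shape(class_by_name("lumbar", "B-LHC"), seed=2)
        curve = bspline_boundary(shape, n_control=27, n_samples=128)
        assert len(curve) == 128 and curve.arc_uniform

    def test_too_few_control_points_rejected(self):
        shape = sample_shape(class_by_name("cervical", "normal"), seed=1)
        with pytest.raises(ValueError, match="n_control"):
            bspline_boundary(shape, n_control=3)

    def test_similarity_equivariance(self):
        """Fitting then transforming equals transforming then fitting."""
        shape = sample_shape(class_by_name("cervical", "moderate-traction"), seed=4)
        angle, scale, shift = np.deg2rad(25), 1.7, np.array([5.0, -3.0])
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        transformed = NinePointShape(
            shape.points @ rot.T * scale + shift, shape.region, shape.label
        )
        fit_then_tx = bspline_boundary(shape).points @ rot.T * scale + shift
        tx_then_fit = bspline_boundary(transformed).points
        assert np.max(np.abs(fit_then_tx - tx_then_fit)) < 1e-6


class TestProcrustes:
    def _square(self):
        return np.array([0, 0, 1, 0, 1, 1, 0, 1], dtype=float)

    def test_identical_shapes_zero_variance(self):
        aligned = procrustes_align([self._square()] * 5)
        assert np.allclose(aligned.shapes.std(axis=0), 0.0, atol=1e-12)
        assert np.allclose(aligned.shapes.mean(axis=0), aligned.mean_shape, atol=1e-9)

    def test_similarity_copies_coincide(self, rng):
        base = rng.uniform(-5, 5, size=(8, 2))
        angle = 0.7
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        copy = base @ rot.T * 2.5 + np.array([10.0, -4.0])
        aligned = procrustes_align([base.ravel(), copy.ravel()])
        assert np.max(np.abs(aligned.shapes[0] - aligned.shapes[1])) < 1e-7

    def test_mean_properties(self, rng):
        shapes = [rng.uniform(-5, 5, size=16) for _ in range(6)]
        aligned = procrustes_align(shapes)
        mean_pts = aligned.mean_shape.reshape(-1, 2)
        assert np.allclose(mean_pts.mean(axis=0), 0.0, atol=1e-9)
        assert abs(np.linalg.norm(aligned.mean_shape) - 1.0) < 1e-9
        assert np.allclose(aligned.shapes.mean(axis=0), aligned.mean_shape, atol=1e-9)

    def test_two_shape_mean_matches_analytic_midpoint(self, rng):
        """For two shapes the GPA mean is the normalized sum of the first
        shape and the optimally rotated second shape (closed form), up to
        an irrelevant global rotation."""
        a = rng.uniform(-5, 5, size=(7, 2))
        b = rng.uniform(-5, 5, size=(7, 2))

        def prep(p):
            z = p[:, 0] + 1j * p[:, 1]
            z = z - z.mean()
            return z / np.linalg.norm(z)

        z1, z2 = prep(a), prep(b)
        z2_rot = z2 * np.exp(-1j * np.angle(np.vdot(z1, z2)))
        m = (z1 + z2_rot) / np.linalg.norm(z1 + z2_rot)

        aligned = procrustes_align([a.ravel(), b.ravel()])
        got = aligned.mean_shape.reshape(-1, 2)
        got_z = got[:, 0] + 1j * got[:, 1]
        # compare up to global rotation: |<m_impl, m_analytic>| == 1
        assert abs(abs(np.vdot(got_z, m)) - 1.0) < 1e-7

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_align([np.zeros(8), self._square()])

    def test_single_shape_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            procrustes_align([self._square()])
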