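"""Vertebra shape boundary representations.

Two boundary schemes are supported: the nine-anatomical-point
representation (9-APR) familiar to bone morphometrists -- four body
corners, lower/upper edge midpoints, an anterior midpoint, and two
anterior-osteophyte marker points -- and a closed third-order B-spline
boundary (B-SR) built from 27 points equally spaced along the 9-APR
polygon.  The module also houses closed-contour arc-length resampling
and generalized Procrustes alignment, shared by the active shape model
and the contour feature extractors.

Conventions: image coordinates with x right, y down, 0-based pixel
centers, sub-pixel values allowed.  Canonical contours are traversed in
landmark order 1..9 (clockwise in image coordinates) starting at
landmark 1 (lower anterior corner).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from shapely.geometry import LineString

__all__ = [
    "NinePointShape",
    "Contour",
    "AlignedShapeSet",
    "canonical_contour",
    "resample_contour",
    "evaluate_periodic_bspline",
    "bspline_boundary",
    "procrustes_align",
]

#: Number of control points placed on the 9-APR polygon for the B-SR.
DEFAULT_N_CONTROL = 27
#: Number of arc-length-uniform samples of the B-SR curve (power of two
#: so that shape-signature DFTs are cheap).
DEFAULT_N_SAMPLES = 128

_DUP_TOL = 1e-9


@dataclass
class NinePointShape:
    """Ordered 9-APR landmark set with its irregularity class label.

    ``points[i]`` is landmark ``i+1``: 1/3 lower anterior/posterior
    corners, 4/6 upper posterior/anterior corners, 2/5 lower/upper edge
    midpoints, 8 anterior midpoint, 7/9 upper/lower osteophyte points.
    For a normal vertebra point 7 coincides with 6 and point 9 with 1.
    """

    points: np.ndarray
    region: str = "cervical"
    label: str = "normal"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (9, 2):
            raise ValueError(f"expected 9 (x, y) landmarks, got {self.points.shape}")
        if not (self.points[0, 1] > self.points[5, 1]):
            raise ValueError("landmark 1 must lie below landmark 6 (y1 > y6)")

    def point(self, i: int) -> np.ndarray:
        """Return landmark ``i`` (1-based)."""
        return self.points[i - 1]

    @property
    def is_normal_morphology(self) -> bool:
        """True when both osteophyte points coincide with the corners."""
        return bool(
            np.allclose(self.points[6], self.points[5])
            and np.allclose(self.points[8], self.points[0])
        )


@dataclass
class Contour:
    """Closed ordered boundary point sequence."""

    points: np.ndarray
    closed: bool = True
    arc_uniform: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if len(self.points) < 4:
            raise ValueError("contour needs at least 4 points")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(d < _DUP_TOL):
            raise ValueError("contour has consecutive duplicate points")

    def __len__(self) -> int:
        return len(self.points)

    def edge_lengths(self) -> np.ndarray:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    def perimeter(self) -> float:
        return float(self.edge_lengths().sum())

    def is_simple(self) -> bool:
        ring = np.vstack([self.points, self.points[:1]])
        return bool(LineString(ring).is_simple)


@dataclass
class AlignedShapeSet:
    """Shapes in a common frame after generalized Procrustes alignment.

    The mean shape has centroid at the origin and unit Frobenius norm;
    the per-shape similarity transforms map the aligned frame back to
    the original coordinates.
    """

    shapes: np.ndarray  # (n, 2L) aligned landmark vectors
    mean_shape: np.ndarray  # (2L,)
    transforms: list = field(default_factory=list)  # (scale, rotation, (tx, ty))

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.size // 2


def _collapse_duplicates(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates (including the wrap-around pair)."""
    keep = [points[0]]
    for p in points[1:]:
        if np.linalg.norm(p - keep[-1]) > _DUP_TOL:
            keep.append(p)
    while len(keep) > 1 and np.linalg.norm(keep[-1] - keep[0]) <= _DUP_TOL:
        keep.pop()
    return np.asarray(keep, dtype=float)


def canonical_contour(shape: NinePointShape) -> Contour:
    """Closed polygon through the 9-APR landmarks in traversal order.

    Traversal is 1-2-3 (lower edge, anterior to posterior), 3-4
    (posterior edge), 4-5-6 (upper edge, posterior to anterior) and
    6-7-8-9-1 (anterior edge through the osteophyte points).  Degenerate
    duplicates -- a normal vertebra has 7==6 and 9==1 -- are collapsed.
    A self-intersecting polygon triggers a warning but is still
    returned, so that malformed expert annotations remain inspectable.
    """
    pts = _collapse_duplicates(shape.points)
    contour = Contour(pts, closed=True)
    if not contour.is_simple():
        warnings.warn(
            f"canonical contour for class {shape.label!r} self-intersects",
            RuntimeWarning,
            stacklevel=2,
        )
    return contour


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample a closed contour to exactly ``n`` arc-length-uniform points.

    The first output point is the contour's start point; subsequent
    points sit at arc positions ``k * P / n`` along the polygonal
    boundary (perimeter ``P``), so the traversal direction and the
    perimeter (within the chord-shortening of resampling) are preserved.
    """
    if not c.closed:
        raise ValueError("resample_contour requires a closed contour")
    if n < 8:
        raise ValueError("need at least 8 resample points")
    ring = np.vstack([c.points, c.points[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(n) * total / n
    x = np.interp(targets, s, ring[:, 0])
    y = np.interp(targets, s, ring[:, 1])
    return Contour(np.column_stack([x, y]), closed=True, arc_uniform=True)


def evaluate_periodic_bspline(control: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Evaluate a closed uniform cubic B-spline at parameter values.

    ``control`` is an (n, 2) array of control points; the curve is the
    periodic degree-3 B-spline with uniform knots, parameterized on
    ``[0, n)`` (one knot span per control point).  ``params`` values are
    taken modulo ``n``.
    """
    control = np.asarray(control, dtype=float)
    ncp = len(control)
    if ncp < 4:
        raise ValueError("a cubic B-spline needs at least 4 control points")
    # wrap the first 3 control points; knots -3..n+3 give a curve valid on [0, n]
    coeffs = np.vstack([control, control[:3]])
    knots = np.arange(-3, ncp + 4, dtype=float)
    spline = BSpline(knots, coeffs, 3, extrapolate=False)
    return spline(np.mod(np.asarray(params, dtype=float), ncp))


def bspline_boundary(
    shape: NinePointShape,
    n_control: int = DEFAULT_N_CONTROL,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> Contour:
    """Closed third-order B-spline boundary (B-SR) of a 9-APR shape.

    ``n_control`` points are placed equally spaced by arc length on the
    canonical 9-APR polygon (27 by default) and treated as control
    points of a closed uniform cubic B-spline; the curve is evaluated
    densely and resampled to ``n_samples`` arc-length-uniform points.
    """
    if n_control < 4:
        raise ValueError("n_control must be at least 4")
    poly = canonical_contour(shape)
    control = resample_contour(poly, n_control).points
    dense_t = np.linspace(0.0, n_control, 16 * n_samples, endpoint=False)
    dense = evaluate_periodic_bspline(control, dense_t)
    return resample_contour(Contour(dense, closed=True), n_samples)


def bspline_control_points(
    shape: NinePointShape, n_control: int = DEFAULT_N_CONTROL
) -> np.ndarray:
    """The ``n_control`` equal-arc-length points on the 9-APR polygon."""
    if n_control < 4:
        raise ValueError("n_control must be at least 4")
    return resample_contour(canonical_contour(shape), n_control).points


def _as_complex(vec: np.ndarray) -> np.ndarray:
    v = np.asarray(vec, dtype=float).reshape(-1, 2)
    return v[:, 0] + 1j * v[:, 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag]).ravel()


def procrustes_align(
    shapes, tol: float = 1e-12, max_iter: int = 200
) -> AlignedShapeSet:
    """Generalized Procrustes alignment of landmark configurations.

    Each shape (a length-2L vector of interleaved x, y coordinates) is
    centered, scaled to unit Frobenius norm, and rotated to the current
    estimate of the mean; the mean is re-estimated and re-normalized
    until it changes by less than ``tol``.  Convergence is far tighter
    than the 1e-7 contract so that the stored mean equals the mean of
    the aligned shapes to numerical precision.
    """
    arr = np.asarray([np.asarray(s, dtype=float).ravel() for s in shapes])
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("need at least 2 shapes to align")
    if arr.shape[1] % 2:
        raise ValueError("shape vectors must have even length (x, y pairs)")

    z = np.array([_as_complex(v) for v in arr])
    centroids = z.mean(axis=1)
    z = z - centroids[:, None]
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate zero-size shape cannot be aligned")
    z = z / norms[:, None]

    mean = z[0].copy()
    rotations = np.zeros(len(z))
    for _ in range(max_iter):
        inner = z @ mean.conj()  # <z_i, mean>
        phase = inner / np.abs(inner)
        aligned = z * np.conj(phase)[:, None]
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean()
        new_mean = new_mean / np.linalg.norm(new_mean)
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            break
    inner = z @ mean.conj()
    phase = inner / np.abs(inner)
    rotations = np.angle(phase)
    aligned = z * np.conj(phase)[:, None]
    # rescale into the mean's frame so that mean(aligned) is exactly the
    # stored unit-norm mean (the average of unit-norm shapes is shorter)
    nu = np.linalg.norm(aligned.mean(axis=0))
    aligned = aligned / nu
    mean = aligned.mean(axis=0)

    transforms = [
        (float(norms[i] * nu), float(rotations[i]),
         (float(centroids[i].real), float(centroids[i].imag)))
        for i in range(len(z))
    ]
    return AlignedShapeSet(
        shapes=np.array([_from_complex(a) for a in aligned]),
        mean_shape=_from_complex(mean),
        transforms=transforms,
    )
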