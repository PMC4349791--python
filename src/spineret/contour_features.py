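"""Contour-based fracture characterization (CB-FC).

Only the boundary participates.  Three descriptor families:

* GSP -- global shape profile: area, perimeter, compactness,
  eccentricity, convexity, rectangularity and aspect ratio of the
  closed boundary polygon;
* shape signatures -- one-dimensional boundary functions: the central
  distance (CD) ``r(n) = |P_n - C|`` and the centered complex
  coordinates (CC) ``z(n) = (x_n - C_x) + i (y_n - C_y)``;
* FD -- Fourier descriptors: DFT magnitudes of a signature, normalized
  so the result is invariant to translation, rotation, scale and the
  choice of starting point.

The signature centroid is the mean of the boundary samples (contours
are arc-length uniform, so this tracks the area centroid) -- it makes
the CC signature exactly zero-mean, which is what removes translation.

FD normalization: for the real-valued CD signature only frequencies
``1..N/2-1`` carry information; their magnitudes are divided by the DC
magnitude.  For CC the DC term is dropped and the remaining magnitudes
are divided by the magnitude of the first positive-frequency
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .region_features import FeatureVector
from .shapes import Contour

__all__ = [
    "ShapeSignature",
    "gsp",
    "central_distance",
    "complex_coords",
    "fourier_descriptor",
    "contour_feature_set",
]

GSP_NAMES = ("area", "perimeter", "compactness", "eccentricity",
             "convexity", "rectangularity", "aspect_ratio")


@dataclass
class ShapeSignature:
    """One-dimensional boundary function (CD real, CC complex)."""

    kind: str  # CD | CC
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        if self.kind not in ("CD", "CC"):
            raise ValueError(f"unknown signature kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.kind == "CD" and np.any(self.values < 0):
            raise ValueError("central distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _polygon_second_moments(pts: np.ndarray) -> tuple[float, float, float]:
    """Central second area moments (mu20, mu02, mu11) of a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    if (np.roll(x, -1) * y - x * np.roll(y, -1)).sum() / 2.0 > 0:
        # make orientation counter-clockwise so signed formulas are positive
        x, y = x[::-1], y[::-1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    ixx = np.sum((x**2 + x * xn + xn**2) * cross) / 12.0
    iyy = np.sum((y**2 + y * yn + yn**2) * cross) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    return ixx - area * cx**2, iyy - area * cy**2, ixy - area * cx * cy


def gsp(c: Contour) -> FeatureVector:
    """Global shape profile of a closed simple contour.

    Area (shoelace), polygonal perimeter, compactness ``4 pi A / P**2``,
    eccentricity from the second area moments, convexity ``A / A_hull``,
    rectangularity ``A / A_minrect`` and aspect ratio (long/short side
    of the minimal-area enclosing rectangle).
    """
    if not c.closed:
        raise ValueError("GSP requires a closed contour")
    poly = Polygon(c.points)
    if not poly.is_valid or not c.is_simple():
        raise ValueError("GSP requires a simple (non-self-intersecting) contour")
    area = poly.area
    if area <= 0:
        raise ValueError("contour encloses zero area")
    perimeter = c.perimeter()
    compactness = min(4.0 * np.pi * area / perimeter**2, 1.0)

    mu20, mu02, mu11 = _polygon_second_moments(c.points)
    common = np.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    eccentricity = float(np.sqrt(max(1.0 - lam2 / lam1, 0.0))) if lam1 > 0 else 0.0

    convexity = min(area / poly.convex_hull.area, 1.0)
    rect = poly.minimum_rotated_rectangle
    rect_pts = np.asarray(rect.exterior.coords)[:-1]
    sides = np.linalg.norm(np.diff(rect_pts, axis=0), axis=1)
    long_side, short_side = max(sides[0], sides[1]), min(sides[0], sides[1])
    rectangularity = min(area / rect.area, 1.0) if rect.area > 0 else 1.0
    aspect = float(long_side / short_side) if short_side > 0 else 1.0

    return FeatureVector(
        [area, perimeter, compactness, eccentricity, convexity, rectangularity, aspect],
        list(GSP_NAMES),
        "GSP",
    )


def _centroid(c: Contour) -> np.ndarray:
    return c.points.mean(axis=0)


def central_distance(c: Contour) -> ShapeSignature:
    """CD signature: distance of each boundary point from the centroid."""
    if not c.closed:
        raise ValueError("central distance requires a closed contour")
    center = _centroid(c)
    r = np.linalg.norm(c.points - center, axis=1)
    if np.allclose(r, 0):
        raise ValueError("degenerate contour: all points at the centroid")
    return ShapeSignature("CD", r)


def complex_coords(c: Contour) -> ShapeSignature:
    """CC signature: centroid-shifted boundary points as complex numbers."""
    center = _centroid(c)
    shifted = c.points - center
    return ShapeSignature("CC", shifted[:, 0] + 1j * shifted[:, 1])


def fourier_descriptor(s: ShapeSignature) -> FeatureVector:
    """Similarity-invariant Fourier descriptor of a shape signature.

    The DFT (1/N normalization) of the signature is taken and phases are
    discarded.  CD: magnitudes of frequencies 1..N/2-1 divided by the DC
    magnitude (length N/2 - 1).  CC: the DC term is dropped and all
    remaining magnitudes are divided by the first positive-frequency
    magnitude, which is itself omitted (length N - 2).
    """
    n = len(s)
    if n < 8 or n % 2:
        raise ValueError("signature length must be even and >= 8")
    u = np.fft.fft(np.asarray(s.values), n) / n
    mag = np.abs(u)
    if s.kind == "CD":
        if mag[0] < 1e-12:
            raise ValueError("zero DC component: cannot scale-normalize CD descriptor")
        values = mag[1 : n // 2] / mag[0]
        names = [f"fd_cd_{k}" for k in range(1, n // 2)]
        return FeatureVector(values, names, "FD-CD", normalized=True)
    if mag[1] < 1e-12:
        raise ValueError("zero reference descriptor: cannot scale-normalize CC descriptor")
    values = mag[2:] / mag[1]
    names = [f"fd_cc_{k}" for k in range(2, n)]
    return FeatureVector(values, names, "FD-CC", normalized=True)


def contour_feature_set(
    c: Contour, algorithms: tuple = ("GSP", "FD-CD", "FD-CC")
) -> dict[str, FeatureVector]:
    """All requested contour descriptors of one boundary."""
    out: dict[str, FeatureVector] = {}
    for alg in algorithms:
        if alg == "GSP":
            out[alg] = gsp(c)
        elif alg == "FD-CD":
            out[alg] = fourier_descriptor(central_distance(c))
        elif alg == "FD-CC":
            out[alg] = fourier_descriptor(complex_coords(c))
        else:
            raise ValueError(f"unknown contour algorithm {alg!r}")
    return out
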