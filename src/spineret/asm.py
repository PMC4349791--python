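"""Active shape model segmentation.

Two coupled statistical sub-models are trained from annotated images:

* shape model -- PCA of Procrustes-aligned landmark configurations,
  keeping the smallest number of modes whose cumulative variance
  reaches a threshold (98% by default).  It constrains where landmarks
  may sit relative to each other.
* profile model -- for each landmark, the mean and covariance of the
  normalized first-difference gray profile sampled along the "whisker"
  (the boundary normal), learned over the training images.  It says
  what the image should look like across the boundary at that landmark.

Search alternates the two: each landmark moves to the whisker position
whose profile has the smallest Mahalanobis distance to its profile
model, then the global pose (similarity transform) and the shape
parameters ``b`` are re-fitted with every ``|b_i|`` clamped to
``3 sqrt(lambda_i)``.  Iteration stops when at most 5% of landmarks
move more than one pixel.  Search is single-resolution and requires a
pose initialization -- automatic vertebra localization is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .shapes import AlignedShapeSet, procrustes_align

__all__ = [
    "ShapeModel",
    "ProfileModel",
    "FittedShape",
    "build_shape_model",
    "build_profile_model",
    "asm_search",
    "save_models",
    "load_models",
]

FORMAT_VERSION = 1
RIDGE = 1e-6


@dataclass
class ShapeModel:
    """PCA point-distribution model of aligned landmark vectors."""

    mean_shape: np.ndarray  # (2L,)
    eigenvectors: np.ndarray  # (2L, t)
    eigenvalues: np.ndarray  # (t,)
    variance_retained: float

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.size // 2

    def constrain(self, b: np.ndarray) -> np.ndarray:
        """Clamp shape parameters to +-3 standard deviations per mode."""
        lim = 3.0 * np.sqrt(self.eigenvalues)
        return np.clip(b, -lim, lim)

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        return self.mean_shape + self.eigenvectors @ b


@dataclass
class ProfileModel:
    """Per-landmark normalized gray-derivative profile statistics."""

    means: np.ndarray  # (L, 2k)
    covariances: np.ndarray  # (L, 2k, 2k)
    half_length: int
    _inv: np.ndarray | None = field(default=None, repr=False)

    def inverse_covariances(self) -> np.ndarray:
        """Ridge-regularized covariance inverses (small training sets
        routinely give singular covariances)."""
        if self._inv is None:
            dim = self.covariances.shape[-1]
            eye = np.eye(dim)
            self._inv = np.stack(
                [np.linalg.inv(c + RIDGE * eye) for c in self.covariances]
            )
        return self._inv


@dataclass
class FittedShape:
    landmarks: np.ndarray  # (L, 2)
    b: np.ndarray
    pose: tuple  # (scale, rotation, (tx, ty))
    iterations: int
    converged: bool


def build_shape_model(aligned, variance_threshold: float = 0.98) -> ShapeModel:
    """PCA of aligned shape vectors, keeping modes to a variance target.

    ``aligned`` is an :class:`AlignedShapeSet` or an (n, 2L) array of
    pre-aligned shape vectors.  The smallest ``t`` with cumulative
    explained variance >= ``variance_threshold`` is kept; eigenvector
    signs are fixed by making each one's largest-magnitude component
    positive, so model building is deterministic given input order.
    """
    vectors = aligned.shapes if isinstance(aligned, AlignedShapeSet) else np.asarray(aligned, dtype=float)
    if len(vectors) < 3:
        raise ValueError("need at least 3 shapes to build a shape model")
    mean = vectors.mean(axis=0)
    centered = vectors - mean
    cov = centered.T @ centered / len(vectors)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        t = 0
    else:
        cum = np.cumsum(evals) / total
        t = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        # drop numerically-zero trailing modes
        while t > 0 and evals[t - 1] < 1e-12 * total:
            t -= 1
    evecs = evecs[:, :t]
    for i in range(t):
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    retained = float(evals[:t].sum() / total) if total > 0 else 1.0
    return ShapeModel(mean, evecs, evals[:t], retained)


def _landmark_normals(landmarks: np.ndarray) -> np.ndarray:
    """Unit boundary normals ("whisker" directions) per landmark.

    The tangent at landmark i runs from its previous to its next
    neighbour in the closed traversal order, skipping coincident
    neighbours (a normal vertebra has duplicate osteophyte points).
    """
    n = len(landmarks)
    normals = np.zeros_like(landmarks)
    for i in range(n):
        step = 1
        nxt = landmarks[(i + step) % n]
        while np.linalg.norm(nxt - landmarks[i]) < 1e-9 and step < n:
            step += 1
            nxt = landmarks[(i + step) % n]
        step = 1
        prv = landmarks[(i - step) % n]
        while np.linalg.norm(prv - landmarks[i]) < 1e-9 and step < n:
            step += 1
            prv = landmarks[(i - step) % n]
        tangent = nxt - prv
        norm = np.linalg.norm(tangent)
        if norm < 1e-9:
            normals[i] = (1.0, 0.0)
        else:
            normals[i] = (-tangent[1] / norm, tangent[0] / norm)
    return normals


def _sample_profile(img: np.ndarray, point: np.ndarray, normal: np.ndarray,
                    half: int) -> np.ndarray:
    """Intensities at 2*half+1 unit steps along the whisker
    (bilinear interpolation, edge-replicated outside the image)."""
    offsets = np.arange(-half, half + 1)
    xs = point[0] + offsets * normal[0]
    ys = point[1] + offsets * normal[1]
    return map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _normalized_diff(profile: np.ndarray) -> np.ndarray:
    d = np.diff(profile)
    s = np.abs(d).sum()
    return d / s if s > 1e-12 else np.zeros_like(d)


def build_profile_model(images, landmark_sets, half_length: int = 8) -> ProfileModel:
    """Learn per-landmark whisker profile statistics from training data.

    For each landmark of each annotated image, 2k+1 intensities are
    sampled along the whisker, first-differenced and normalized by the
    sum of absolute values; the per-landmark mean and covariance over
    the training set form the model.  A whisker leaving the image is
    sampled with edge replication (a warning is emitted).
    """
    images = list(images)
    landmark_sets = [np.asarray(s, dtype=float).reshape(-1, 2) for s in landmark_sets]
    if len(images) != len(landmark_sets) or not images:
        raise ValueError("need one landmark set per training image")
    n_landmarks = len(landmark_sets[0])
    profiles = [[] for _ in range(n_landmarks)]
    for img, lms in zip(images, landmark_sets):
        img = np.asarray(img, dtype=float)
        h, w = img.shape
        normals = _landmark_normals(lms)
        for i in range(n_landmarks):
            span = half_length * np.abs(normals[i])
            if (lms[i] - span).min() < 0 or lms[i][0] + span[0] > w - 1 or lms[i][1] + span[1] > h - 1:
                warnings.warn("whisker exits image; sampling edge-replicated",
                              RuntimeWarning, stacklevel=2)
            prof = _sample_profile(img, lms[i], normals[i], half_length)
            profiles[i].append(_normalized_diff(prof))
    means = np.array([np.mean(p, axis=0) for p in profiles])
    covs = []
    for p in profiles:
        arr = np.asarray(p)
        if len(arr) > 1:
            covs.append(np.cov(arr, rowvar=False, ddof=1))
        else:
            covs.append(np.zeros((arr.shape[1], arr.shape[1])))
    return ProfileModel(means, np.asarray(covs), half_length)


def _fit_pose(model_pts: np.ndarray, target_pts: np.ndarray):
    """Least-squares similarity transform model -> target.

    Returns (scale, rotation, translation) with
    ``target ~ scale * R(rotation) @ model + translation``.
    """
    mc = model_pts.mean(axis=0)
    tc = target_pts.mean(axis=0)
    zm = (model_pts - mc)[:, 0] + 1j * (model_pts - mc)[:, 1]
    zt = (target_pts - tc)[:, 0] + 1j * (target_pts - tc)[:, 1]
    denom = np.vdot(zm, zm).real
    beta = np.vdot(zm, zt) / denom  # scale * e^{i rot}
    scale = abs(beta)
    rot = np.angle(beta)
    # translation maps the (rotated, scaled) model centroid onto target centroid
    t = tc - scale * _apply_rot(mc, rot)
    return float(scale), float(rot), t


def _apply_rot(pts: np.ndarray, rot: float) -> np.ndarray:
    c, s = np.cos(rot), np.sin(rot)
    pts = np.atleast_2d(pts)
    out = np.column_stack([c * pts[:, 0] - s * pts[:, 1],
                           s * pts[:, 0] + c * pts[:, 1]])
    return out[0] if out.shape[0] == 1 and pts.shape[0] == 1 else out


def _pose_forward(pts: np.ndarray, pose) -> np.ndarray:
    scale, rot, t = pose
    return scale * _apply_rot(pts, rot) + t


def _pose_inverse(pts: np.ndarray, pose) -> np.ndarray:
    scale, rot, t = pose
    return _apply_rot((pts - t) / scale, -rot)


def asm_search(
    image: np.ndarray,
    shape_model: ShapeModel,
    profile_model: ProfileModel,
    init_landmarks: np.ndarray,
    max_iter: int = 50,
    search_range: int = 4,
    move_tol: float = 1.0,
    pose_iterations: int = 8,
    pose_search_range: int = 6,
) -> FittedShape:
    """Iterative ASM boundary search from an initial landmark placement.

    Per iteration: each landmark examines ``2 * search_range + 1``
    candidate positions along its whisker and moves to the one whose
    normalized derivative profile has minimal Mahalanobis distance to
    the landmark's profile model (staying put is always a candidate, so
    the chosen profile cost never exceeds the cost of not moving); the
    result is then regularized by re-fitting pose and shape parameters
    with the +-3 sigma clamp.

    The first ``pose_iterations`` iterations fit the similarity pose
    only (shape parameters held at zero) with the wider
    ``pose_search_range``: the rigid stage absorbs the initialization
    offset before the deformable modes are released, which keeps the
    shape constraint from locking onto a mis-posed local minimum.
    Converged when, after the pose stage, at most 5% of landmarks move
    more than ``move_tol`` pixels.
    """
    img = np.asarray(image, dtype=float)
    x = np.asarray(init_landmarks, dtype=float).reshape(-1, 2).copy()
    if len(x) != shape_model.n_landmarks:
        raise ValueError("initialization landmark count does not match the model")
    k = profile_model.half_length
    inv_covs = profile_model.inverse_covariances()
    mean_pts = shape_model.mean_shape.reshape(-1, 2)

    b = np.zeros(shape_model.n_modes)
    pose = (1.0, 0.0, np.zeros(2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pose_stage = it <= pose_iterations
        m = pose_search_range if pose_stage else search_range
        normals = _landmark_normals(x)
        suggested = x.copy()
        for i in range(len(x)):
            samples = _sample_profile(img, x[i], normals[i], m + k)
            diffs = np.diff(samples)
            costs = np.empty(2 * m + 1)
            for c in range(-m, m + 1):
                window = diffs[c + m : c + m + 2 * k]
                s = np.abs(window).sum()
                g = window / s if s > 1e-12 else np.zeros_like(window)
                r = g - profile_model.means[i]
                costs[c + m] = float(r @ inv_covs[i] @ r)
            j = int(np.argmin(costs))
            offset = float(j - m)
            if 0 < j < 2 * m:
                # sub-pixel refinement: parabola through the cost minimum
                denom = costs[j - 1] - 2 * costs[j] + costs[j + 1]
                if denom > 1e-12:
                    offset += 0.5 * (costs[j - 1] - costs[j + 1]) / denom
            suggested[i] = x[i] + offset * normals[i]

        pose = _fit_pose(mean_pts, suggested)
        if pose_stage:
            b = np.zeros(shape_model.n_modes)
        else:
            model_frame = _pose_inverse(suggested, pose)
            b = shape_model.constrain(
                shape_model.eigenvectors.T
                @ (model_frame.ravel() - shape_model.mean_shape)
            )
        new_x = _pose_forward(shape_model.reconstruct(b).reshape(-1, 2), pose)

        moved = np.linalg.norm(new_x - x, axis=1)
        x = new_x
        if not pose_stage and np.mean(moved > move_tol) <= 0.05:
            converged = True
            break
    return FittedShape(x, b, (pose[0], pose[1], tuple(pose[2])), it, converged)


def train_asm(images, landmark_sets, variance_threshold: float = 0.98,
              half_length: int = 8) -> tuple[ShapeModel, ProfileModel]:
    """Procrustes-align the training landmarks, then build both sub-models."""
    aligned = procrustes_align([np.asarray(s, dtype=float).ravel() for s in landmark_sets])
    return (build_shape_model(aligned, variance_threshold),
            build_profile_model(images, landmark_sets, half_length))


def save_models(shape_model: ShapeModel, profile_model: ProfileModel,
                path: str | Path) -> None:
    """Serialize both sub-models to one human-readable JSON file."""
    payload = {
        "format_version": FORMAT_VERSION,
        "shape_model": {
            "mean_shape": shape_model.mean_shape.tolist(),
            "eigenvectors": shape_model.eigenvectors.tolist(),
            "eigenvalues": shape_model.eigenvalues.tolist(),
            "variance_retained": shape_model.variance_retained,
        },
        "profile_model": {
            "means": profile_model.means.tolist(),
            "covariances": profile_model.covariances.tolist(),
            "half_length": profile_model.half_length,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_models(path: str | Path) -> tuple[ShapeModel, ProfileModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    sm = payload["shape_model"]
    pm = payload["profile_model"]
    return (
        ShapeModel(np.array(sm["mean_shape"]), np.array(sm["eigenvectors"]),
                   np.array(sm["eigenvalues"]), sm["variance_retained"]),
        ProfileModel(np.array(pm["means"]), np.array(pm["covariances"]),
                     pm["half_length"]),
    )
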