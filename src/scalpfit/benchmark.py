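"""Landmark-based template registration — the comparison method.

Conventional neuronavigation coregistration maps a head template onto the
subject with a least-squares similarity transform (rotation, isotropic
scale, translation; Umeyama solution, reflections disallowed) fitted on
annotated fiducials: either the 3 classic ones (nasion, left/right
preauricular) or 7 (adding the topmost/backmost/leftmost/rightmost scalp
extremities).  The benchmark reconstruction is the posed template mean
shape — no per-subject morphing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .mesh_core import TriMesh
from .registration import PoseParams
from .sampling import AxisFrame
from .shape_model import MorphableModel

__all__ = [
    "LandmarkSet",
    "LandmarkRegistration",
    "pick_extremities",
    "landmark_register",
    "FIDUCIALS_3",
    "EXTREMITIES",
]

FIDUCIALS_3 = ("nasion", "lpa", "rpa")
EXTREMITIES = ("topmost", "backmost", "leftmost", "rightmost")
_KNOWN = set(FIDUCIALS_3) | set(EXTREMITIES)


@dataclass
class LandmarkSet:
    """Ordered named landmark coordinates in a declared frame."""

    names: tuple
    coordinates: np.ndarray
    frame: str = "unspecified"

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, np.float64))
        if len(self.names) != len(self.coordinates):
            raise ValueError("names and coordinates disagree in length")
        if len(self.names) < 3:
            raise ValueError("need at least 3 landmarks")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        unknown = set(self.names) - _KNOWN
        if unknown:
            raise ValueError(f"unknown landmark names: {sorted(unknown)}")
        if len(self.names) == 3 and set(self.names) != set(FIDUCIALS_3):
            raise ValueError("a 3-landmark set must be exactly nasion/lpa/rpa")


def pick_extremities(mesh: TriMesh, frame: AxisFrame) -> LandmarkSet:
    """Topmost, backmost, leftmost, rightmost vertices along the frame axes
    (ties broken by lowest vertex index)."""
    rel = mesh.vertices - frame.origin
    dirs = {
        "topmost": frame.up,
        "backmost": -frame.front,
        "leftmost": frame.left,
        "rightmost": -frame.left,
    }
    coords = []
    for name in EXTREMITIES:
        proj = rel @ dirs[name]
        coords.append(mesh.vertices[int(np.argmax(proj))])
    return LandmarkSet(EXTREMITIES, np.stack(coords))


def _umeyama_similarity(src: np.ndarray, dst: np.ndarray, anisotropic: bool = False):
    """Least-squares similarity transform dst ~ s * R @ src + t.

    Umeyama's closed form with reflections disallowed.  With
    ``anisotropic=True``, per-axis scales are refit in the source frame after
    the rotation is fixed (a sensitivity-analysis variant).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    var_s = (cs**2).sum() / n
    if var_s <= 0:
        raise ValueError("collinear or coincident source landmarks")
    cov = cd.T @ cs / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate landmark configuration")
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    if scale <= 0:
        raise ValueError("non-positive scale")
    scales = np.full(3, scale)
    if anisotropic:
        rs = cs  # per-axis least squares in the source frame
        rd = cd @ R
        denom = (rs**2).sum(axis=0)
        good = denom > 0
        scales = np.where(good, (rs * rd).sum(axis=0) / np.where(good, denom, 1), scale)
        scales = np.clip(scales, 1e-6, None)
    t = mu_d - R @ (scales * mu_s)
    return R, scales, t


class LandmarkRegistration(BaseEstimator):
    """Similarity-transform registration from template to subject landmarks.

    ``fit(X, y)`` takes template landmark coordinates ``X`` and subject
    landmark coordinates ``y`` (same order).  Attributes: ``pose_``,
    ``residuals_`` (per-landmark error after transform), ``rmse_``.
    """

    def __init__(self, anisotropic_scale: bool = False):
        self.anisotropic_scale = anisotropic_scale

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.atleast_2d(np.asarray(y, float))
        if X.shape != y.shape or len(X) < 3:
            raise ValueError("need >= 3 corresponding landmark pairs")
        R, scales, t = _umeyama_similarity(X, y, self.anisotropic_scale)
        self.pose_ = PoseParams(scales, Rotation.from_matrix(R).as_rotvec(), t)
        mapped = self.pose_.apply(X)
        self.residuals_ = np.linalg.norm(mapped - y, axis=1)
        self.rmse_ = float(np.sqrt(np.mean(self.residuals_**2)))
        return self

    def predict(self, X):
        return self.pose_.apply(np.atleast_2d(np.asarray(X, float)))


def landmark_register(
    template_landmarks: LandmarkSet,
    subject_landmarks: LandmarkSet,
    model: MorphableModel,
    anisotropic_scale: bool = False,
):
    """Register the template to the subject via corresponding landmarks.

    Returns ``(pose, reconstruction)`` where the reconstruction is the posed
    model mean mesh, plus per-landmark residuals on the pose object
    (``pose.landmark_residuals``).
    """
    if template_landmarks.names != subject_landmarks.names:
        raise ValueError("landmark sets must list the same names in order")
    est = LandmarkRegistration(anisotropic_scale=anisotropic_scale).fit(
        template_landmarks.coordinates, subject_landmarks.coordinates
    )
    pose = est.pose_
    pose.landmark_residuals = est.residuals_  # type: ignore[attr-defined]
    return pose, pose.apply(model.mean_mesh)
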