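"""Linear statistical shape model (3D morphable model) over corresponded meshes.

A model is a mean mesh plus ``k`` orthonormal deformation modes in dense
vertex correspondence.  An instance with weights ``w`` is synthesized as

    S_w = S_mean + sum_i  w_i * e_i * v_i

where ``v_i`` is a unit eigenvector of the flattened-vertex covariance and
``e_i`` is that mode's standard deviation (square root of the covariance
eigenvalue), so weights drawn from N(0, 1) reproduce the training-population
spread.  The SD convention makes the weight-norm regularizer of the fitting
objective penalize deviations in population-SD units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .mesh_core import TriMesh, load_mesh, save_mesh

__all__ = [
    "MorphableModel",
    "ShapeWeights",
    "MorphableModelPCA",
    "synthesize",
    "build_from_meshes",
    "variance_fraction",
    "truncate",
    "save_model",
    "load_model",
]

RELATIVE_EIGENVALUE_TOL = 1e-8  # modes with e_i < tol * e_1 are dropped


@dataclass
class ShapeWeights:
    """Per-mode weights of a model instance (population-SD units)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=np.float64))


@dataclass
class MorphableModel:
    """Mean mesh + eigenvalues (mode SDs) + unit eigenvectors, in dense
    correspondence."""

    mean_mesh: TriMesh
    eigenvalues: np.ndarray          # (k,) non-increasing, positive mode SDs
    eigenvectors: np.ndarray         # (k, 3n) unit rows
    eigenvalue_convention: str = "sd"
    landmarks: dict = field(default_factory=dict)   # name -> vertex index
    frame: dict = field(default_factory=dict)       # front/left/up unit axes

    def __post_init__(self) -> None:
        self.eigenvalues = np.atleast_1d(np.asarray(self.eigenvalues, np.float64))
        self.eigenvectors = np.atleast_2d(np.asarray(self.eigenvectors, np.float64))
        n3 = 3 * self.mean_mesh.n_vertices
        if self.eigenvectors.shape != (len(self.eigenvalues), n3):
            raise ValueError("eigenvectors must be (k, 3n)")
        if len(self.eigenvalues) and np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if len(self.eigenvalues) and self.eigenvalues.min() <= 0:
            raise ValueError("eigenvalues must be positive")

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return self.mean_mesh.n_vertices


def synthesize(model: MorphableModel, w: Union[ShapeWeights, Sequence[float]]) -> TriMesh:
    """Instance mesh ``mean + sum_i w_i e_i v_i``; faces copied from the mean."""
    wv = w.w if isinstance(w, ShapeWeights) else np.atleast_1d(np.asarray(w, float))
    if len(wv) > model.n_components:
        raise ValueError(
            f"got {len(wv)} weights for a {model.n_components}-component model"
        )
    flat = model.mean_mesh.vertices.reshape(-1).copy()
    if len(wv):
        flat = flat + (wv * model.eigenvalues[: len(wv)]) @ model.eigenvectors[: len(wv)]
    return TriMesh(
        flat.reshape(-1, 3), model.mean_mesh.faces.copy(), units=model.mean_mesh.units
    )


class MorphableModelPCA(BaseEstimator):
    """PCA shape-model builder over meshes in dense correspondence.

    Parameters
    ----------
    rel_tol : float
        Modes with SD below ``rel_tol * leading SD`` are dropped.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (3n,) flattened mean vertices
    components_ : (k, 3n) unit eigenvectors, sign-fixed so the
        largest-magnitude entry of each is positive
    singular_sds_ : (k,) mode standard deviations, non-increasing
    model_ : the assembled :class:`MorphableModel`
    """

    def __init__(self, rel_tol: float = RELATIVE_EIGENVALUE_TOL):
        self.rel_tol = rel_tol

    def fit(self, X, y=None, faces=None, units: str = "mm"):
        """Fit on meshes (list of TriMesh) or a stacked (n_train, 3n) array.

        When ``X`` is an array, ``faces`` must carry the shared topology.
        """
        if isinstance(X, np.ndarray):
            if faces is None:
                raise ValueError("faces required with array input")
            data = np.asarray(X, dtype=np.float64)
        else:
            meshes = list(X)
            if len(meshes) < 2:
                raise ValueError("need at least 2 training meshes")
            faces = meshes[0].faces
            units = meshes[0].units
            for m in meshes[1:]:
                if m.n_vertices != meshes[0].n_vertices or not np.array_equal(
                    m.faces, faces
                ):
                    raise ValueError("training meshes must share topology")
            data = np.stack([m.vertices.reshape(-1) for m in meshes])
        if len(data) < 2:
            raise ValueError("need at least 2 training samples")

        pca = PCA(n_components=min(len(data) - 1, data.shape[1]), svd_solver="full")
        pca.fit(data)
        sds = np.sqrt(pca.explained_variance_)
        comps = pca.components_
        keep = sds > self.rel_tol * (sds[0] if len(sds) else 0.0)
        sds, comps = sds[keep], comps[keep]
        # deterministic sign: largest-magnitude entry positive
        for i in range(len(comps)):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.mean_ = pca.mean_
        self.components_ = comps
        self.singular_sds_ = sds
        mean_mesh = TriMesh(pca.mean_.reshape(-1, 3), np.asarray(faces), units=units)
        self.model_ = MorphableModel(mean_mesh, sds, comps)
        return self

    def transform(self, X):
        """Project flattened vertex rows onto the modes (weights in SD units)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.mean_) @ self.components_.T / self.singular_sds_

    def inverse_transform(self, W):
        W = np.atleast_2d(np.asarray(W, dtype=np.float64))
        return self.mean_ + (W * self.singular_sds_) @ self.components_


def build_from_meshes(training: Sequence[TriMesh]) -> MorphableModel:
    """PCA model from corresponded meshes (vertex-wise mean, flattened-vertex
    covariance eigen-decomposition, near-zero modes dropped)."""
    return MorphableModelPCA().fit(training).model_


def variance_fraction(model: MorphableModel, k_used: int) -> float:
    """Fraction of the eigenvalue sum carried by the first ``k_used`` modes."""
    if not 1 <= k_used <= model.n_components:
        raise ValueError("k_used out of range")
    e = model.eigenvalues
    return float(e[:k_used].sum() / e.sum())


def truncate(model: MorphableModel, k_new: int) -> MorphableModel:
    """Keep the first ``k_new`` modes, order preserved."""
    if not 1 <= k_new <= model.n_components:
        raise ValueError("k_new out of range")
    return MorphableModel(
        model.mean_mesh.copy(),
        model.eigenvalues[:k_new].copy(),
        model.eigenvectors[:k_new].copy(),
        model.eigenvalue_convention,
        dict(model.landmarks),
        {k: np.asarray(v) for k, v in model.frame.items()},
    )


# ---------------------------------------------------------------------------
# Container format: a directory with mean.ply, eigenvectors.npy (k, 3n),
# eigenvalues.npy (k,) and manifest.json recording counts, units, landmark
# vertex indices, frame axes and the eigenvalue convention, so externally
# built models can be dropped in by declaring theirs.

def save_model(model: MorphableModel, directory: Union[str, Path]) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_mesh(model.mean_mesh, d / "mean.ply")
    # PLY stores float32; keep full-precision copies for exact round trips
    np.save(d / "mean_vertices.npy", model.mean_mesh.vertices)
    np.save(d / "mean_faces.npy", model.mean_mesh.faces)
    np.save(d / "eigenvectors.npy", model.eigenvectors)
    np.save(d / "eigenvalues.npy", model.eigenvalues)
    manifest = {
        "n_vertices": model.n_vertices,
        "n_components": model.n_components,
        "units": model.mean_mesh.units,
        "eigenvalue_convention": model.eigenvalue_convention,
        "landmarks": {k: int(v) for k, v in model.landmarks.items()},
        "frame": {k: np.asarray(v).tolist() for k, v in model.frame.items()},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: Union[str, Path]) -> MorphableModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if (d / "mean_vertices.npy").exists():
        mean = TriMesh(
            np.load(d / "mean_vertices.npy"),
            np.load(d / "mean_faces.npy"),
            units=manifest.get("units", "mm"),
        )
    else:
        mean = load_mesh(d / "mean.ply", units=manifest.get("units", "mm"))
    eigenvectors = np.load(d / "eigenvectors.npy")
    eigenvalues = np.load(d / "eigenvalues.npy")
    return MorphableModel(
        mean,
        eigenvalues,
        eigenvectors,
        manifest.get("eigenvalue_convention", "sd"),
        {k: int(v) for k, v in manifest.get("landmarks", {}).items()},
        {k: np.asarray(v, dtype=float) for k, v in manifest.get("frame", {}).items()},
    )
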