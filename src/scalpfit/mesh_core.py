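"""Triangle-mesh and point-cloud primitives.

The package represents a head surface as a triangle mesh: an ``n x 3`` vertex
matrix, an ``m x 3`` face-index matrix, and the edge set induced by the face
sides.  All indices are 0-based internally; file formats that are 1-based
(OBJ) are converted at the I/O boundary.  Coordinates are stored in
millimeters unless a caller declares otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "WeightedGraph",
    "PointCloud",
    "compute_vertex_normals",
    "build_edge_graph",
    "nearest_neighbors",
    "polyline_length",
    "crop_by_reference_proximity",
    "load_mesh",
    "save_mesh",
    "load_point_cloud",
    "save_point_cloud",
]


@dataclass
class TriMesh:
    """Triangle mesh: vertices, faces, derived edges, optional unit normals."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: Optional[np.ndarray] = None
    units: str = "mm"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=np.float64)
            if self.vertex_normals.shape != self.vertices.shape:
                raise ValueError("vertex_normals must match vertices in shape")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges (l, 2), each row sorted, lexicographic order."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
            self.units,
        )

    def is_single_component(self) -> bool:
        e = self.edges
        n = self.n_vertices
        if n == 0:
            return False
        a = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        n_comp, _ = connected_components(a, directed=False)
        return n_comp == 1

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )


@dataclass
class WeightedGraph:
    """Undirected graph over mesh vertices with Euclidean edge lengths."""

    nodes: np.ndarray
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights must have equal length")
        if len(self.weights) and self.weights.min() <= 0:
            raise ValueError("edge weights must be strictly positive")

    def to_csr(self):
        n = int(self.nodes.max()) + 1 if len(self.nodes) else 0
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        w = np.concatenate([self.weights, self.weights])
        return coo_matrix((w, (i, j)), shape=(n, n)).tocsr()

    def adjacency_lists(self) -> list:
        """Sorted neighbor lists per node (dense 0..max_node indexing)."""
        n = int(self.nodes.max()) + 1 if len(self.nodes) else 0
        adj: list = [[] for _ in range(n)]
        for (a, b) in self.edges:
            adj[a].append(int(b))
            adj[b].append(int(a))
        return [sorted(x) for x in adj]


@dataclass
class PointCloud:
    """Ordered set of 3D points with optional unit normals."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("points must be a non-empty (q, 3) array")
        if self.normals is not None:
            self.normals = np.atleast_2d(np.asarray(self.normals, dtype=np.float64))
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")

    def __len__(self) -> int:
        return len(self.points)


def _face_normals_areas(mesh: TriMesh):
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norms = np.linalg.norm(cross, axis=1)
    return cross, norms  # cross has magnitude 2*area


def compute_vertex_normals(mesh: TriMesh) -> TriMesh:
    """Area-weighted per-vertex normals, oriented outward for closed meshes.

    Each vertex normal is the normalized sum of incident face normals weighted
    by face area.  Zero-area faces are skipped.  A majority vote against the
    centroid ray flips the whole field so that normals point away from the
    mesh centroid (well-defined for closed head-like surfaces).
    """
    if mesh.n_faces < 1:
        raise ValueError("mesh has no faces")
    cross, norms = _face_normals_areas(mesh)
    good = norms > 1e-300
    if not good.any():
        raise ValueError("all faces are degenerate")
    acc = np.zeros_like(mesh.vertices)
    f = mesh.faces[good]
    c = cross[good]
    for k in range(3):
        np.add.at(acc, f[:, k], c)
    lengths = np.linalg.norm(acc, axis=1)
    zero = lengths < 1e-300
    if zero.any():
        # isolated/degenerate vertices: fall back to centroid ray
        ray = mesh.vertices[zero] - mesh.vertices.mean(axis=0)
        ray_len = np.linalg.norm(ray, axis=1)
        ray_len[ray_len < 1e-300] = 1.0
        acc[zero] = ray / ray_len[:, None]
        lengths[zero] = 1.0
    normals = acc / lengths[:, None]
    outward = mesh.vertices - mesh.vertices.mean(axis=0)
    vote = np.sign(np.einsum("ij,ij->i", normals, outward)).sum()
    if vote < 0:
        normals = -normals
    return replace(mesh, vertex_normals=normals)


def build_edge_graph(mesh: TriMesh) -> WeightedGraph:
    """Undirected weighted graph of the mesh: nodes are vertices, weights are
    Euclidean edge lengths."""
    e = mesh.edges
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    if len(w) and w.min() <= 0:
        raise ValueError("mesh contains zero-length edges")
    return WeightedGraph(np.arange(mesh.n_vertices), e, w)


def nearest_neighbors(query: PointCloud, target: PointCloud):
    """Closest target point per query point; ties broken by lowest index.

    Returns (indices, distances).
    """
    q = query.points
    t = target.points
    if len(t) < 1:
        raise ValueError("target cloud is empty")
    tree = cKDTree(t)
    k = min(2, len(t))
    d, i = tree.query(q, k=k)
    if k == 1:
        return np.atleast_1d(i), np.atleast_1d(d)
    d = np.atleast_2d(d)
    i = np.atleast_2d(i)
    idx = i[:, 0].copy()
    dist = d[:, 0].copy()
    # possible tie: resolve by brute-force scan over the tied queries
    tied = np.flatnonzero(d[:, 1] - d[:, 0] <= 1e-12 * np.maximum(1.0, d[:, 0]))
    for qi in tied:
        dd = np.linalg.norm(t - q[qi], axis=1)
        best = dd.min()
        idx[qi] = int(np.flatnonzero(dd <= best + 1e-12 * max(1.0, best))[0])
        dist[qi] = dd[idx[qi]]
    return idx, dist


def polyline_length(points: np.ndarray) -> float:
    """Sum of consecutive-point Euclidean distances; 0 for a single point."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(p) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def _region_distance(points: np.ndarray, region, metric: str) -> np.ndarray:
    if metric == "vertex":
        cloud = region.points if isinstance(region, PointCloud) else region.vertices
        tree = cKDTree(cloud)
        d, _ = tree.query(points)
        return np.atleast_1d(d)
    if metric == "surface":
        if not isinstance(region, TriMesh):
            raise TypeError("surface metric requires TriMesh regions")
        _, d, _ = _trimesh.proximity.closest_point_naive(
            region.to_trimesh(), points
        )
        return np.asarray(d)
    raise ValueError(f"unknown metric {metric!r}")


def crop_by_reference_proximity(
    mesh: TriMesh,
    reference_region: Union[PointCloud, TriMesh],
    other_region: Union[PointCloud, TriMesh],
    margin: float = 0.0,
    metric: str = "vertex",
) -> TriMesh:
    """Sub-mesh of vertices distinctively closer to the reference region.

    A vertex is kept when ``dist(v, reference) + margin < dist(v, other)``
    (``<=`` at margin 0 so an exact tie to itself survives the identity
    crop).  Faces touching any removed vertex are dropped.  The mesh must be
    aligned to the reference shape beforehand.
    """
    d_ref = _region_distance(mesh.vertices, reference_region, metric)
    d_other = _region_distance(mesh.vertices, other_region, metric)
    keep = d_ref + margin <= d_other
    if not keep.any():
        raise ValueError("proximity crop removed every vertex")
    new_index = -np.ones(mesh.n_vertices, dtype=np.int64)
    new_index[keep] = np.arange(keep.sum())
    face_keep = keep[mesh.faces].all(axis=1)
    new_faces = new_index[mesh.faces[face_keep]]
    normals = None
    if mesh.vertex_normals is not None:
        normals = mesh.vertex_normals[keep]
    return TriMesh(mesh.vertices[keep], new_faces, normals, mesh.units)


# ---------------------------------------------------------------------------
# I/O.  Vertex order is correspondence-critical, so meshes are loaded with
# processing disabled (no merging or reordering).

def load_mesh(path: Union[str, Path], units: str = "mm") -> TriMesh:
    tm = _trimesh.load(str(path), process=False, maintain_order=True, force="mesh")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), units=units)


def save_mesh(mesh: TriMesh, path: Union[str, Path], encoding: str = "binary") -> None:
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        data = _trimesh.exchange.ply.export_ply(
            tm, encoding="ascii" if encoding == "ascii" else "binary"
        )
        path.write_bytes(data)
    elif path.suffix.lower() == ".obj":
        path.write_text(_trimesh.exchange.obj.export_obj(tm))
    else:
        raise ValueError("supported mesh formats: .ply, .obj")


def load_point_cloud(path: Union[str, Path]) -> PointCloud:
    """CSV with header x,y,z[,nx,ny,nz], one row per ordered sample."""
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    normals = None
    if {"nx", "ny", "nz"}.issubset(df.columns):
        normals = df[["nx", "ny", "nz"]].to_numpy(dtype=np.float64)
    return PointCloud(pts, normals)


def save_point_cloud(cloud: PointCloud, path: Union[str, Path]) -> None:
    data = {"x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2]}
    if cloud.normals is not None:
        data.update(
            nx=cloud.normals[:, 0], ny=cloud.normals[:, 1], nz=cloud.normals[:, 2]
        )
    pd.DataFrame(data).to_csv(path, index=False)
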