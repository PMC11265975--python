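"""Sparse contiguous surface sampling as constrained walks on the mesh graph.

Emulates how an operator sweeps a tracked pointer over the scalp: the head is
divided into ``n_steps + 1`` angular sections along the arc running from the
frontmost point over the top of the head to the back and on towards the neck.
Each walk step is a weighted-shortest path between seeded-random endpoint
vertices in consecutive sections, restricted to those two sections, which
produces the characteristic zigzag sweep when successive endpoints alternate
between low (near-ear) and high (near-vertex) elevation bands.

Strategies
----------
side_to_top      two passes (left then right hemisphere), side-to-top zigzag
side_to_side     one pass over the full arc, endpoints alternating hemispheres
half_side_to_top one side-to-top pass on a single hemisphere
random_walk      uniform random adjacent-vertex moves until a target length
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .mesh_core import PointCloud, TriMesh, WeightedGraph, polyline_length

__all__ = [
    "AxisFrame",
    "SectionMap",
    "Trajectory",
    "partition_sections",
    "sample_strategy",
    "estimate_sample_normals",
    "surface_coverage",
    "save_trajectory",
    "load_trajectory",
    "STRATEGIES",
]

STRATEGIES = ("side_to_top", "side_to_side", "half_side_to_top", "random_walk")


@dataclass
class AxisFrame:
    """Head coordinate frame: origin plus orthonormal front/up/left axes."""

    origin: np.ndarray
    front: np.ndarray
    up: np.ndarray
    left: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.front = np.asarray(self.front, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        self.left = np.asarray(self.left, dtype=np.float64)
        axes = np.stack([self.front, self.up, self.left])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")

    def transformed(self, pose) -> "AxisFrame":
        """Frame carried through a similarity pose (axes re-orthonormalized
        through the rotation only)."""
        R = pose.rotation_matrix()
        return AxisFrame(
            pose.apply(self.origin[None, :])[0],
            R @ self.front,
            R @ self.up,
            R @ self.left,
        )


@dataclass
class SectionMap:
    """Per-vertex section (front-to-back angle bin) and sub-section
    (elevation band: 0 low/near-ear, 1 mid, 2 high/top) labels."""

    section_of_vertex: np.ndarray
    subsection_of_vertex: np.ndarray
    frame: AxisFrame
    n_sections: int


@dataclass
class Trajectory:
    """Ordered sampled points of one walk (possibly several continuous
    passes, identified by ``segment_ids``)."""

    points: np.ndarray
    vertex_ids: Optional[np.ndarray]
    normals: Optional[np.ndarray]
    length: float
    geodesic_length: float
    strategy: str
    seed: int
    step_index: Optional[np.ndarray] = None
    segment_ids: Optional[np.ndarray] = None

    def as_point_cloud(self) -> PointCloud:
        return PointCloud(self.points.copy(),
                          None if self.normals is None else self.normals.copy())


def _arc_angle(vertices: np.ndarray, frame: AxisFrame) -> np.ndarray:
    """Angle along the front -> top -> back -> neck arc, in [0, 2*pi)."""
    rel = vertices - frame.origin
    f = rel @ frame.front
    u = rel @ frame.up
    return np.mod(np.arctan2(u, f), 2.0 * np.pi)


def _elevation_angle(vertices: np.ndarray, frame: AxisFrame) -> np.ndarray:
    """Angle from the up axis within the lateral plane: 0 at the vertex
    (top of head), ~pi/2 at ear level."""
    rel = vertices - frame.origin
    u = rel @ frame.up
    lat = np.abs(rel @ frame.left)
    return np.arctan2(lat, u)


def partition_sections(
    mesh: TriMesh, graph: WeightedGraph, n_steps: int, frame: AxisFrame
) -> SectionMap:
    """Partition vertices into ``n_steps + 1`` equal-angle sections ordered
    front-to-back(-to-neck), each split into 3 equal-angle elevation bands."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    theta = _arc_angle(mesh.vertices, frame)
    n_sections = n_steps + 1
    lo, hi = theta.min(), theta.max()
    width = (hi - lo) / n_sections
    if width <= 0:
        raise ValueError("degenerate angular extent")
    section = np.minimum(((theta - lo) / width).astype(np.int64), n_sections - 1)
    counts = np.bincount(section, minlength=n_sections)
    if counts.min() == 0:
        raise ValueError(
            f"mesh too coarse for {n_steps} steps: empty section(s) "
            f"{np.flatnonzero(counts == 0).tolist()}"
        )
    psi = _elevation_angle(mesh.vertices, frame)
    sub = np.zeros(mesh.n_vertices, dtype=np.int64)
    for s in range(n_sections):
        members = np.flatnonzero(section == s)
        p = psi[members]
        plo, phi = p.min(), p.max()
        w = max((phi - plo) / 3.0, 1e-12)
        band = np.minimum(((p - plo) / w).astype(np.int64), 2)
        sub[members] = 2 - band  # small elevation angle = top = band 2
    return SectionMap(section, sub, frame, n_sections)


def _restricted_shortest_path(csr, nodes: np.ndarray, src: int, dst: int):
    """Dijkstra path from src to dst inside the induced subgraph on nodes."""
    sub = csr[nodes][:, nodes]
    local = {int(v): i for i, v in enumerate(nodes)}
    if src not in local or dst not in local:
        return None
    d, pred = dijkstra(
        sub, directed=False, indices=local[src], return_predecessors=True
    )
    j = local[dst]
    if not np.isfinite(d[j]):
        return None
    path = [j]
    while path[-1] != local[src]:
        path.append(int(pred[path[-1]]))
    return [int(nodes[i]) for i in reversed(path)]


def _choice(rng: np.random.Generator, candidates: np.ndarray) -> int:
    candidates = np.sort(np.asarray(candidates))
    return int(candidates[rng.integers(len(candidates))])


def _endpoint_pool(section_members, band_mask, hemi_mask):
    """Narrow an endpoint candidate pool, relaxing band then hemisphere."""
    pool = section_members[band_mask[section_members] & hemi_mask[section_members]]
    if len(pool) == 0:
        pool = section_members[hemi_mask[section_members]]
    if len(pool) == 0:
        pool = section_members
    return pool


def sample_strategy(
    mesh: TriMesh,
    graph: WeightedGraph,
    sections: Optional[SectionMap],
    strategy: str,
    n_steps: int,
    seed: int,
    target_length: Optional[float] = None,
) -> Trajectory:
    """Generate one sampling walk; a pure function of its inputs and seed.

    For ``random_walk``, ``target_length`` (mm) terminates the walk; it
    defaults to ``150 * n_steps`` (about one zigzag step's worth of scalp
    per nominal step on an adult head).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    csr = graph.to_csr()
    verts = mesh.vertices

    if strategy == "random_walk":
        if target_length is None:
            target_length = 150.0 * n_steps
        adj = graph.adjacency_lists()
        current = _choice(rng, np.arange(mesh.n_vertices))
        path = [current]
        acc = 0.0
        while acc < target_length:
            nxt = adj[current][rng.integers(len(adj[current]))]
            acc += float(np.linalg.norm(verts[nxt] - verts[current]))
            path.append(nxt)
            current = nxt
        return _walk_to_trajectory(
            mesh, [(np.asarray(path), np.zeros(len(path), dtype=np.int64))],
            strategy, n_steps, seed, None,
        )

    if sections is None:
        raise ValueError("non-random strategies need a SectionMap")
    frame = sections.frame
    rel_left = (verts - frame.origin) @ frame.left
    rel_up = (verts - frame.origin) @ frame.up
    up_span = rel_up.max() - rel_up.min()
    left_mask = rel_left >= 0
    section_members = [
        np.flatnonzero(sections.section_of_vertex == s)
        for s in range(sections.n_sections)
    ]
    band_masks = [sections.subsection_of_vertex == b for b in range(3)]
    all_mask = np.ones(mesh.n_vertices, dtype=bool)

    def start_vertex(hemi_mask) -> int:
        """Pre-auricular start: lateral-extreme vertices of section 0's low
        band."""
        pool = _endpoint_pool(section_members[0], band_masks[0], hemi_mask)
        order = pool[np.argsort(-np.abs(rel_left[pool]), kind="stable")]
        return _choice(rng, order[: max(1, len(order) // 4)])

    def one_pass(hemi_mask, alternate_hemis=False):
        current = start_vertex(hemi_mask if not alternate_hemis else left_mask)
        walk = [current]
        steps = [0]
        for step in range(n_steps):
            band = band_masks[2] if step % 2 == 0 else band_masks[0]
            if alternate_hemis:
                hmask = left_mask if step % 2 == 1 else ~left_mask
                band = band_masks[0]  # dip towards the opposite ear each step
                restrict_h = all_mask
            else:
                hmask = hemi_mask
                restrict_h = hemi_mask
            end = _choice(
                rng, _endpoint_pool(section_members[step + 1], band, hmask)
            )
            if alternate_hemis:
                # cross over the top, never under the chin
                floor = min(rel_up[current], rel_up[end]) - 0.05 * up_span
                restrict_h = rel_up >= floor
            restriction = np.flatnonzero(
                (
                    (sections.section_of_vertex == step)
                    | (sections.section_of_vertex == step + 1)
                )
                & restrict_h
            )
            restriction = np.union1d(restriction, [current, end])
            path = _restricted_shortest_path(csr, restriction, current, end)
            if path is None:
                raise RuntimeError(
                    f"{strategy}: step {step} has no path between sections "
                    f"{step} and {step + 1} within the restriction set"
                )
            walk.extend(path[1:])
            steps.extend([step] * (len(path) - 1))
            current = end
        return np.asarray(walk), np.asarray(steps)

    if strategy == "side_to_top":
        passes = [one_pass(left_mask), one_pass(~left_mask)]
    elif strategy == "half_side_to_top":
        passes = [one_pass(left_mask)]
    else:  # side_to_side
        passes = [one_pass(all_mask, alternate_hemis=True)]
    return _walk_to_trajectory(mesh, passes, strategy, n_steps, seed, sections)


def _walk_to_trajectory(mesh, passes, strategy, n_steps, seed, sections):
    verts = mesh.vertices
    ids, seg, stp = [], [], []
    for p, (walk, steps) in enumerate(passes):
        keep = np.ones(len(walk), dtype=bool)
        keep[1:] = walk[1:] != walk[:-1]  # drop consecutive repeats
        ids.append(walk[keep])
        stp.append(steps[keep])
        seg.append(np.full(int(keep.sum()), p))
    vertex_ids = np.concatenate(ids)
    segment_ids = np.concatenate(seg)
    step_index = np.concatenate(stp)
    points = verts[vertex_ids]
    length = sum(polyline_length(verts[w]) for w in ids)
    geo = 0.0
    for w in ids:
        geo += float(
            np.linalg.norm(verts[w[1:]] - verts[w[:-1]], axis=1).sum()
        )
    head_center = (
        sections.frame.origin if sections is not None else verts.mean(axis=0)
    )
    normals = None
    if len(points) > 4:
        cloud = estimate_sample_normals(
            PointCloud(points), min(12, len(points) - 1), head_center
        )
        normals = cloud.normals
    return Trajectory(
        points=points,
        vertex_ids=vertex_ids,
        normals=normals,
        length=float(length),
        geodesic_length=float(geo),
        strategy=strategy,
        seed=seed,
        step_index=step_index,
        segment_ids=segment_ids,
    )


def estimate_sample_normals(
    points: PointCloud, k_neighbors: int, head_center: np.ndarray
) -> PointCloud:
    """Per-point normals from local k-NN covariance (smallest-variance
    direction), oriented away from ``head_center``.

    Degenerate (collinear) neighborhoods fall back to the radial direction;
    the returned cloud carries a ``degenerate_mask`` attribute flagging them.
    """
    pts = points.points
    q = len(pts)
    if not (q > k_neighbors >= 3):
        raise ValueError("need q > k_neighbors >= 3")
    head_center = np.asarray(head_center, dtype=np.float64)
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k_neighbors + 1)
    normals = np.empty_like(pts)
    degenerate = np.zeros(q, dtype=bool)
    for i in range(q):
        local = pts[nbr[i]] - pts[nbr[i]].mean(axis=0)
        cov = local.T @ local
        evals, evecs = np.linalg.eigh(cov)
        if evals[1] <= 1e-10 * max(evals[2], 1e-300):
            degenerate[i] = True
            n = pts[i] - head_center
            nn = np.linalg.norm(n)
            normals[i] = n / nn if nn > 0 else np.array([0.0, 0.0, 1.0])
            continue
        normals[i] = evecs[:, 0]
    flip = np.einsum("ij,ij->i", normals, pts - head_center) < 0
    normals[flip] = -normals[flip]
    out = PointCloud(pts.copy(), normals)
    out.degenerate_mask = degenerate  # type: ignore[attr-defined]
    return out


def surface_coverage(trajectory: Trajectory, mesh: TriMesh, radius: float) -> float:
    """Fraction of mesh vertices within ``radius`` of any trajectory point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(trajectory.points)
    d, _ = tree.query(mesh.vertices)
    return float(np.mean(np.atleast_1d(d) <= radius))


# ---------------------------------------------------------------------------
# I/O: CSV of ordered samples plus a JSON sidecar for reproducibility


def save_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    path = Path(path)
    data = {"x": traj.points[:, 0], "y": traj.points[:, 1], "z": traj.points[:, 2]}
    if traj.normals is not None:
        data.update(
            nx=traj.normals[:, 0], ny=traj.normals[:, 1], nz=traj.normals[:, 2]
        )
    if traj.step_index is not None:
        data["step_index"] = traj.step_index
    if traj.segment_ids is not None:
        data["segment_id"] = traj.segment_ids
    if traj.vertex_ids is not None:
        data["vertex_id"] = traj.vertex_ids
    pd.DataFrame(data).to_csv(path, index=False)
    sidecar = {
        "strategy": traj.strategy,
        "seed": int(traj.seed),
        "length": traj.length,
        "geodesic_length": traj.geodesic_length,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    points = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    normals = None
    if {"nx", "ny", "nz"}.issubset(df.columns):
        normals = df[["nx", "ny", "nz"]].to_numpy(dtype=np.float64)
    step_index = (
        df["step_index"].to_numpy(np.int64) if "step_index" in df.columns else None
    )
    segment_ids = (
        df["segment_id"].to_numpy(np.int64) if "segment_id" in df.columns else None
    )
    vertex_ids = (
        df["vertex_id"].to_numpy(np.int64) if "vertex_id" in df.columns else None
    )
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if segment_ids is None:
        length = polyline_length(points)
    else:
        length = sum(
            polyline_length(points[segment_ids == s]) for s in np.unique(segment_ids)
        )
    return Trajectory(
        points=points,
        vertex_ids=vertex_ids,
        normals=normals,
        length=float(meta.get("length", length)),
        geodesic_length=float(meta.get("geodesic_length", length)),
        strategy=meta.get("strategy", "unknown"),
        seed=int(meta.get("seed", -1)),
        step_index=step_index,
        segment_ids=segment_ids,
    )
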