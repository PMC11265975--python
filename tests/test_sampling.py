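"""Sectioning, sampling-walk strategies, normals, coverage."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from scalpfit import (
    PointCloud,
    estimate_sample_normals,
    partition_sections,
    polyline_length,
    sample_strategy,
    surface_coverage,
)
from scalpfit.mesh_core import TriMesh, build_edge_graph
from scalpfit.sampling import STRATEGIES, Trajectory, load_trajectory, save_trajectory


@pytest.fixture(scope="module")
def sections6(template_head, head_graph, head_frame):
    return partition_sections(template_head, head_graph, 6, head_frame)


class TestPartitionSections:
    def test_labels_partition_all_vertices(self, template_head, sections6):
        assert sections6.section_of_vertex.shape == (template_head.n_vertices,)
        assert sections6.n_sections == 7
        assert set(np.unique(sections6.section_of_vertex)) == set(range(7))
        assert set(np.unique(sections6.subsection_of_vertex)) <= {0, 1, 2}

    def test_two_sections_split_front_back(self, template_head, head_graph, head_frame):
        smap = partition_sections(template_head, head_graph, 1, head_frame)
        rel = template_head.vertices - head_frame.origin
        theta = np.mod(
            np.arctan2(rel @ head_frame.up, rel @ head_frame.front), 2 * np.pi
        )
        boundary = (theta.min() + theta.max()) / 2
        expected = (theta - theta.min()) >= (theta.max() - theta.min()) / 2
        np.testing.assert_array_equal(smap.section_of_vertex == 1, expected)
        assert boundary > 0

    def test_matches_per_vertex_angle_binning_oracle(
        self, template_head, head_graph, head_frame
    ):
        n_steps = 5
        smap = partition_sections(template_head, head_graph, n_steps, head_frame)
        rel = template_head.vertices - head_frame.origin
        theta = np.mod(
            np.arctan2(rel @ head_frame.up, rel @ head_frame.front), 2 * np.pi
        )
        lo, hi = theta.min(), theta.max()
        oracle = np.minimum(
            ((theta - lo) / ((hi - lo) / (n_steps + 1))).astype(int), n_steps
        )
        np.testing.assert_array_equal(smap.section_of_vertex, oracle)

    def test_sections_ordered_front_to_back(self, template_head, sections6, head_frame):
        rel = template_head.vertices - head_frame.origin
        f = rel @ head_frame.front
        first = sections6.section_of_vertex == 0
        last = sections6.section_of_vertex == sections6.n_sections - 1
        assert f[first].mean() > f[last].mean()

    def test_too_coarse_mesh_errors(self, head_frame):
        # a single triangle cannot fill many angular sections
        mesh = TriMesh(
            np.array([[0.0, 100, 0], [1, 100, 0], [0, 100, 1]]),
            np.array([[0, 1, 2]]),
        )
        graph = build_edge_graph(mesh)
        with pytest.raises(ValueError, match="section"):
            partition_sections(mesh, graph, 12, head_frame)


class TestSampleStrategies:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_same_seed_is_bitwise_reproducible(
        self, template_head, head_graph, sections6, strategy
    ):
        a = sample_strategy(template_head, head_graph, sections6, strategy, 6, 123)
        b = sample_strategy(template_head, head_graph, sections6, strategy, 6, 123)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.vertex_ids, b.vertex_ids)
        assert a.length == b.length and a.geodesic_length == b.geodesic_length

    @pytest.mark.parametrize("n_steps", [1, 4, 10])
    def test_walks_are_graph_contiguous(
        self, template_head, head_graph, head_frame, n_steps
    ):
        sections = partition_sections(template_head, head_graph, n_steps, head_frame)
        adjacency = set(map(tuple, np.sort(head_graph.edges, axis=1)))
        for strategy in ("side_to_top", "side_to_side", "half_side_to_top"):
            traj = sample_strategy(
                template_head, head_graph, sections, strategy, n_steps, 7
            )
            for seg in np.unique(traj.segment_ids):
                ids = traj.vertex_ids[traj.segment_ids == seg]
                for a, b in zip(ids[:-1], ids[1:]):
                    assert (min(a, b), max(a, b)) in adjacency

    def test_random_walk_matches_seeded_choice_oracle(self):
        # triangle mesh: every vertex adjacent to the other two
        mesh = TriMesh(
            np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]),
            np.array([[0, 1, 2]]),
        )
        graph = build_edge_graph(mesh)
        traj = sample_strategy(
            mesh, graph, None, "random_walk", 1, seed=5, target_length=60.0
        )
        rng = np.random.default_rng(5)
        adj = {0: [1, 2], 1: [0, 2], 2: [0, 1]}
        current = int(np.arange(3)[rng.integers(3)])
        oracle = [current]
        acc = 0.0
        while acc < 60.0:
            nxt = adj[current][rng.integers(2)]
            acc += float(np.linalg.norm(mesh.vertices[nxt] - mesh.vertices[current]))
            oracle.append(nxt)
            current = nxt
        np.testing.assert_array_equal(traj.vertex_ids, oracle)

    def test_random_walk_reaches_target_length(self, template_head, head_graph):
        traj = sample_strategy(
            template_head, head_graph, None, "random_walk", 1,
            seed=3, target_length=800.0,
        )
        assert traj.length >= 800.0

    def test_half_strategy_stays_in_one_hemisphere(
        self, template_head, head_graph, sections6, head_frame
    ):
        traj = sample_strategy(
            template_head, head_graph, sections6, "half_side_to_top", 6, 11
        )
        lateral = (traj.points - head_frame.origin) @ head_frame.left
        # one hemisphere only, up to the section-boundary vertex ring
        assert lateral.min() > -1e-9

    def test_length_equals_polyline_per_segment(
        self, template_head, head_graph, sections6
    ):
        traj = sample_strategy(
            template_head, head_graph, sections6, "side_to_top", 6, 2
        )
        total = sum(
            polyline_length(traj.points[traj.segment_ids == s])
            for s in np.unique(traj.segment_ids)
        )
        assert traj.length == pytest.approx(total, abs=1e-9)
        # walks follow edges, so geodesic length equals the polyline length
        assert traj.geodesic_length == pytest.approx(total, abs=1e-9)

    def test_geodesic_at_least_endpoint_distance(
        self, template_head, head_graph, sections6
    ):
        traj = sample_strategy(
            template_head, head_graph, sections6, "side_to_side", 6, 4
        )
        for s in np.unique(traj.segment_ids):
            pts = traj.points[traj.segment_ids == s]
            assert polyline_length(pts) >= np.linalg.norm(pts[-1] - pts[0]) - 1e-9

    def test_length_increases_with_steps_on_average(
        self, template_head, head_graph, head_frame
    ):
        steps = []
        lengths = []
        for n_steps in (1, 4, 8, 12):
            sections = partition_sections(
                template_head, head_graph, n_steps, head_frame
            )
            for seed in range(5):
                traj = sample_strategy(
                    template_head, head_graph, sections, "side_to_top",
                    n_steps, seed,
                )
                steps.append(n_steps)
                lengths.append(traj.length)
        rho, _ = spearmanr(steps, lengths)
        assert rho > 0.8

    def test_unknown_strategy_rejected(self, template_head, head_graph, sections6):
        with pytest.raises(ValueError, match="strategy"):
            sample_strategy(template_head, head_graph, sections6, "spiral", 3, 0)


class TestSampleNormals:
    def test_sphere_normals_near_radial(self, icosphere):
        pts = icosphere.vertices * 90.0
        cloud = estimate_sample_normals(PointCloud(pts), 8, np.zeros(3))
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cos = np.einsum("ij,ij->i", cloud.normals, radial)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 5.0

    def test_plane_normals_point_away_from_center(self, rng):
        pts = np.column_stack([rng.uniform(-10, 10, (2, 50)).T, np.zeros(50)])
        cloud = estimate_sample_normals(PointCloud(pts), 6, np.array([0, 0, -5.0]))
        np.testing.assert_allclose(cloud.normals, [[0, 0, 1.0]] * 50, atol=1e-9)

    def test_flipping_center_flips_normals(self, rng):
        pts = rng.standard_normal((40, 3)) * [20, 20, 1]
        a = estimate_sample_normals(PointCloud(pts), 6, np.array([0, 0, -50.0]))
        b = estimate_sample_normals(PointCloud(pts), 6, np.array([0, 0, 50.0]))
        np.testing.assert_allclose(a.normals, -b.normals, atol=1e-12)

    def test_collinear_neighborhood_falls_back_to_radial(self):
        pts = np.column_stack([np.linspace(0, 10, 12), np.zeros(12), np.zeros(12)])
        pts[:, 2] = 5.0
        cloud = estimate_sample_normals(PointCloud(pts), 4, np.zeros(3))
        assert cloud.degenerate_mask.all()
        assert (cloud.normals[:, 2] > 0).all()


class TestSurfaceCoverage:
    def test_full_visit_is_total_coverage(self, template_head):
        traj = Trajectory(
            points=template_head.vertices.copy(), vertex_ids=None, normals=None,
            length=0.0, geodesic_length=0.0, strategy="synthetic", seed=0,
        )
        assert surface_coverage(traj, template_head, 1e-9) == 1.0

    def test_tiny_radius_counts_only_exact_hits(self, template_head):
        traj = Trajectory(
            points=template_head.vertices[:10] + 5.0, vertex_ids=None,
            normals=None, length=0.0, geodesic_length=0.0,
            strategy="synthetic", seed=0,
        )
        assert surface_coverage(traj, template_head, 1e-12) == 0.0

    def test_matches_distance_threshold_oracle(
        self, template_head, head_graph, sections6
    ):
        traj = sample_strategy(
            template_head, head_graph, sections6, "side_to_top", 6, 9
        )
        radius = 10.0
        d = np.linalg.norm(
            template_head.vertices[:, None] - traj.points[None], axis=2
        ).min(axis=1)
        oracle = float(np.mean(d <= radius))
        assert surface_coverage(traj, template_head, radius) == pytest.approx(oracle)

    def test_sparse_walk_covers_a_few_percent(
        self, template_head_fine, head_frame
    ):
        graph = build_edge_graph(template_head_fine)
        sections = partition_sections(template_head_fine, graph, 8, head_frame)
        traj = sample_strategy(
            template_head_fine, graph, sections, "side_to_top", 8, 1
        )
        frac = len(np.unique(traj.vertex_ids)) / template_head_fine.n_vertices
        assert 0.005 < frac < 0.15


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path, template_head, head_graph, sections6):
        traj = sample_strategy(
            template_head, head_graph, sections6, "side_to_top", 6, 5
        )
        path = tmp_path / "walk.csv"
        save_trajectory(traj, path)
        back = load_trajectory(path)
        np.testing.assert_allclose(back.points, traj.points, atol=1e-12)
        np.testing.assert_allclose(back.normals, traj.normals, atol=1e-12)
        np.testing.assert_array_equal(back.segment_ids, traj.segment_ids)
        np.testing.assert_array_equal(back.step_index, traj.step_index)
        assert back.strategy == "side_to_top"
        assert back.seed == 5
        assert back.length == pytest.approx(traj.length)
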