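import numpy as np
import pytest
import trimesh

from scalpfit import (
    PointCloud,
    TriMesh,
    build_edge_graph,
    build_from_meshes,
    make_template_head,
)
from scalpfit.synthetic_data import PopulationSpec, make_population, template_frame


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def template_head():
    return make_template_head(3)


@pytest.fixture(scope="session")
def template_head_fine():
    return make_template_head(4)


@pytest.fixture(scope="session")
def head_graph(template_head):
    return build_edge_graph(template_head)


@pytest.fixture(scope="session")
def head_frame():
    return template_frame()


@pytest.fixture(scope="session")
def toy_model():
    """5-mode morphable model built from a coarse synthetic population."""
    spec = PopulationSpec(
        n_subjects=80,
        n_modes=5,
        mode_amplitudes=(8.0, 5.0, 3.0, 2.0, 1.5),
        template_resolution=3,
        seed=42,
    )
    pop = make_population(make_template_head(3), spec)
    model = build_from_meshes(pop.meshes)
    model.landmarks = dict(pop.template.landmarks)
    model.frame = {
        "origin": pop.template.frame.origin,
        "front": pop.template.frame.front,
        "up": pop.template.frame.up,
        "left": pop.template.frame.left,
    }
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_small_mesh(rng, n_extra=20):
    """Random connected triangulation: jittered sphere points + convex hull."""
    pts = rng.standard_normal((n_extra, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 1.0 + 0.1 * rng.random(n_extra)[:, None]
    hull = trimesh.convex.convex_hull(pts)
    return TriMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
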