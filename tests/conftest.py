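"""Shared fixtures: small analytic meshes and a tiny synthetic cohort."""

import numpy as np
import pytest

from aortavae.mesh_core import SurfaceMesh
from aortavae.synthetic_aaa import ShapeParams, TemplateSpec, generate_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tetrahedron():
    """Smallest closed triangulation: 4 vertices, 4 faces."""
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, faces, template_id="tetra")


@pytest.fixture
def unit_cube():
    """Cube as 12 triangles."""
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices, float),
                       np.asarray(box.faces, np.int64), template_id="cube")


@pytest.fixture(scope="session")
def small_tube():
    """Noise-free straight tube on a small template (8 x 6 = 48 vertices)."""
    params = ShapeParams(length=6.0, base_radius=1.0, sac_amplitude=0.0,
                         noise_sd=0.0)
    return generate_mesh(params, TemplateSpec(n_axial=8, n_circ=6))


@pytest.fixture(scope="session")
def bumpy_tube():
    """Tube with a sac and mild noise, for non-degenerate geometry tests."""
    params = ShapeParams(length=8.0, base_radius=1.0, sac_amplitude=1.0,
                         sac_center=0.5, sac_width=1.5, neck_angle=15.0,
                         torsion=10.0, noise_sd=0.01)
    return generate_mesh(params, TemplateSpec(n_axial=12, n_circ=8),
                         rng=np.random.default_rng(3))


def random_connected_graph_mesh(rng, n_max=30):
    """Random triangle fan/strip mesh giving a connected graph (for spectral
    oracles): a random triangulation over n vertices."""
    n = int(rng.integers(4, n_max + 1))
    verts = rng.normal(size=(n, 3))
    faces = [[0, 1, 2]]
    for v in range(3, n):
        # attach each new vertex to a random existing edge -> stays connected
        f = faces[int(rng.integers(len(faces)))]
        i, j = rng.choice(f, size=2, replace=False)
        faces.append([int(i), int(j), v])
    return SurfaceMesh(verts, np.asarray(faces, np.int64))
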