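import numpy as np
import pytest

from mitomorph import TriangleSurface, icosphere, make_mitochondrion


@pytest.fixture(scope="session")
def sphere_coarse():
    """Small closed OMM icosphere (320 triangles) for geometry-only tests."""
    v, f = icosphere(radius=3000.0, subdivisions=2)
    return TriangleSurface(v, f, surface_id="OMM")


@pytest.fixture(scope="session")
def scene_fine():
    """Classification-grade scene: subdivision-5 nested OMM/IMM (20,480 tris).

    Dense enough that the centroid-distance convention tracks the true
    surface distance to within ~10 A, as with real segmentation meshes.
    """
    omm, imm, truth = make_mitochondrion(
        radius=3000.0, spacing=135.0, subdivisions=5, seed=101
    )
    return omm, imm, truth


def make_grid_surface(nx=20, ny=20, pitch=50.0, z=0.0):
    """Flat right-triangle grid in the z=0 plane, normals +z."""
    xs = np.arange(nx + 1) * pitch - nx * pitch / 2
    ys = np.arange(ny + 1) * pitch - ny * pitch / 2
    verts = np.array([[x, y, z] for y in ys for x in xs])
    faces = []
    for j in range(ny):
        for i in range(nx):
            a = j * (nx + 1) + i
            b, c, d = a + 1, a + nx + 1, a + nx + 2
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleSurface(verts, np.array(faces), surface_id="OMM")


@pytest.fixture(scope="session")
def grid_surface():
    return make_grid_surface()
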