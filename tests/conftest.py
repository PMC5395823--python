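import numpy as np
import pytest
import trimesh

from facemaps.geodesic import GeodesicSolver, _barycentric_raw
from facemaps.mesh import SurfacePoint, TriangleMesh


def grid_mesh(extent=2.0, n=9, z=0.0):
    """Flat rectangular grid in the z-plane, diagonally triangulated."""
    xx, yy = np.meshgrid(np.linspace(0, extent, n), np.linspace(0, extent, n))
    pts = np.c_[xx.ravel(), yy.ravel(), np.full(n * n, z)]
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v0 = i * n + j
            v1 = v0 + 1
            v2 = v0 + n
            v3 = v2 + 1
            faces += [[v0, v1, v3], [v0, v3, v2]]
    return TriangleMesh(pts, np.array(faces))


def icosphere_mesh(subdivisions=4, radius=1.0):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def half_cylinder_mesh(radius=5.0, height=10.0, n_theta=48, n_z=25):
    """Open half-cylinder facing +x (unambiguous outward orientation)."""
    th = np.linspace(-np.pi / 2, np.pi / 2, n_theta)
    zz = np.linspace(-height / 2, height / 2, n_z)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zz for t in th])
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta - 1):
            v0 = i * n_theta + j
            v1 = v0 + 1
            v2 = v0 + n_theta
            v3 = v1 + n_theta
            faces += [[v0, v1, v3], [v0, v3, v2]]
    return TriangleMesh(verts, np.array(faces), orientation_axis=(1, 0, 0))


def surface_point_at(mesh, x, y):
    """SurfacePoint at planar coordinates (x, y) on a z-plane grid mesh."""
    target = np.array([x, y, mesh.vertices[0, 2]])
    for f in range(mesh.n_faces):
        tri = mesh.vertices[mesh.faces[f]]
        b = _barycentric_raw(tri, target)
        if b.min() >= -1e-12:
            b = np.clip(b, 0, None)
            return SurfacePoint(f, b / b.sum())
    raise ValueError(f"({x}, {y}) outside the grid")


def random_surface_point(mesh, rng):
    f = int(rng.integers(0, mesh.n_faces))
    return SurfacePoint(f, rng.dirichlet([1.0, 1.0, 1.0]))


@pytest.fixture(scope="session")
def plane():
    return grid_mesh()


@pytest.fixture(scope="session")
def plane_solver(plane):
    return GeodesicSolver(plane, steiner_per_edge=3)


@pytest.fixture(scope="session")
def sphere():
    return icosphere_mesh(subdivisions=4)


@pytest.fixture(scope="session")
def sphere_solver(sphere):
    return GeodesicSolver(sphere, steiner_per_edge=5)
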