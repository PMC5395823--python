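"""Triangle-mesh data model, OBJ/PLY I/O and rigid ensemble alignment.

The mesh is the basic carrier of every downstream quantity: landmarks live
on it as barycentric surface points, curvature is estimated from its vertex
normals, and geodesic traits are measured along its faces.  Vertex normals
follow an outward-orientation convention (the mean normal points toward a
configurable viewing axis, +z by default) so that convex features such as a
nose carry positive curvature downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "SurfacePoint",
    "TangentVector",
    "read_mesh",
    "write_mesh",
    "align_from_fiducials",
    "icp_align",
    "RigidTransform",
]


class MeshError(ValueError):
    """Raised for invalid mesh structure or file content."""


@dataclass(frozen=True)
class SurfacePoint:
    """A continuous location on a mesh: face index + barycentric weights."""

    face: int
    bary: np.ndarray  # (3,), nonnegative, sums to 1

    def __post_init__(self):
        b = np.asarray(self.bary, dtype=float)
        if b.shape != (3,):
            raise ValueError("barycentric weights must be length 3")
        if np.any(b < -1e-9) or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("barycentric weights must be >= 0 and sum to 1")
        object.__setattr__(self, "bary", np.clip(b, 0.0, None) / np.clip(b, 0.0, None).sum())

    def position(self, mesh: "TriangleMesh") -> np.ndarray:
        tri = mesh.vertices[mesh.faces[self.face]]
        return self.bary @ tri


@dataclass(frozen=True)
class TangentVector:
    """A 3-vector constrained to the plane of its anchor's face."""

    anchor: SurfacePoint
    vec: np.ndarray  # (3,), lies in the anchor face plane

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vec))


class TriangleMesh:
    """An edge-manifold (with boundary) triangular surface mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in length units (mm for facial scans).
    faces : (m, 3) int array
        Triangles as 0-based vertex indices, counterclockwise when viewed
        from outside the surface.
    orientation_axis : (3,) array, optional
        Axis toward which the mean surface normal should point; the face
        winding is flipped globally when it does not.  Default +z.
    """

    def __init__(self, vertices, faces, orientation_axis=(0.0, 0.0, 1.0), validate=True):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self.orientation_axis = np.asarray(orientation_axis, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3) triangles")
        if validate:
            self._validate()
        self._orient()
        self._cache: dict = {}

    # -- structure ---------------------------------------------------------

    def _validate(self):
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError(
                f"face index out of range: max {self.faces.max()} with {n} vertices"
            )
        if np.any(self.face_areas() < 1e-14):
            raise MeshError("mesh contains zero-area faces")
        edges = self.edges_sorted()
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshError("non-manifold edge: an edge is shared by more than 2 faces")

    def _orient(self):
        normals = self.face_normals_raw()
        areas = np.linalg.norm(np.cross(
            self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]],
            self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]), axis=1)
        mean_normal = (normals * areas[:, None]).sum(axis=0)
        if mean_normal @ self.orientation_axis < 0:
            self.faces = self.faces[:, ::-1].copy()

    def face_normals_raw(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        nrm = np.linalg.norm(cr, axis=1, keepdims=True)
        return cr / np.clip(nrm, 1e-300, None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_sorted(self) -> np.ndarray:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    # -- cached geometry ---------------------------------------------------

    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            self._cache["face_normals"] = self.face_normals_raw()
        return self._cache["face_normals"]

    def face_areas(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, unit length."""
        if "vertex_normals" not in self._cache:
            fn = self.face_normals()
            areas = self.face_areas()
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn * areas[:, None])
            nrm = np.linalg.norm(vn, axis=1, keepdims=True)
            self._cache["vertex_normals"] = vn / np.clip(nrm, 1e-300, None)
        return self._cache["vertex_normals"]

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0)))

    def kdtree(self) -> cKDTree:
        if "kdtree" not in self._cache:
            self._cache["kdtree"] = cKDTree(self.vertices)
        return self._cache["kdtree"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Return a rigidly moved copy (axis is rotated along)."""
        return TriangleMesh(
            self.vertices @ rotation.T + translation,
            self.faces.copy(),
            orientation_axis=rotation @ self.orientation_axis,
            validate=False,
        )

    def surface_point_at_vertex(self, vid: int) -> SurfacePoint:
        """A SurfacePoint coincident with vertex ``vid`` (first incident face)."""
        fids = np.nonzero(np.any(self.faces == vid, axis=1))[0]
        if not len(fids):
            raise MeshError(f"vertex {vid} belongs to no face")
        fid = int(fids[0])
        bary = (self.faces[fid] == vid).astype(float)
        return SurfacePoint(fid, bary)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


# -- I/O -------------------------------------------------------------------


def read_mesh(path, fmt: str | None = None, triangulate: bool = True) -> TriangleMesh:
    """Read an OBJ or PLY surface; texture and color payloads are ignored.

    Quads (and higher polygons) are fan-triangulated unless
    ``triangulate=False``, in which case they raise ``MeshError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise MeshError(f"unsupported mesh format: {fmt!r}")
    if not triangulate and _has_nontriangular_faces(path, fmt):
        raise MeshError(f"{path.name}: non-triangular faces with triangulation disabled")
    if fmt == "obj":
        _check_obj_indices(path)
    loaded = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    return TriangleMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))


def _has_nontriangular_faces(path: Path, fmt: str) -> bool:
    if fmt == "obj":
        with open(path) as fh:
            for line in fh:
                if line.startswith("f ") and len(line.split()) - 1 > 3:
                    return True
        return False
    # ascii PLY: face rows start with the vertex count
    with open(path, "rb") as fh:
        header = fh.read(2048).decode("ascii", errors="ignore")
    if "binary" in header:
        return False  # binary PLY checked post hoc by trimesh triangulation
    in_body = False
    with open(path) as fh:
        n_vert = n_face = 0
        for line in fh:
            if not in_body:
                if line.startswith("element vertex"):
                    n_vert = int(line.split()[-1])
                elif line.startswith("element face"):
                    n_face = int(line.split()[-1])
                elif line.startswith("end_header"):
                    in_body = True
                    skip = n_vert
                continue
            if skip > 0:
                skip -= 1
                continue
            if n_face <= 0:
                break
            n_face -= 1
            if int(line.split()[0]) != 3:
                return True
    return False


def _check_obj_indices(path: Path):
    n_vert = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("v "):
                n_vert += 1
            elif line.startswith("f "):
                for token in line.split()[1:]:
                    idx = int(token.split("/")[0])
                    if idx > n_vert or idx == 0 or idx < -n_vert:
                        raise MeshError(
                            f"{path.name}:{lineno}: face references vertex {idx} "
                            f"of {n_vert}"
                        )


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None,
               vertex_scalars=None, colormap: str = "viridis") -> Path:
    """Write OBJ or ASCII PLY; optional per-vertex scalars become PLY colors.

    When scalars are given, values are mapped through ``colormap`` to
    ``red/green/blue`` uchar vertex properties and the raw values are written
    to a sidecar CSV ``<path>.scalars.csv`` with columns ``vertex_id,value``.
    NaN scalars render as neutral gray.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise MeshError(f"unsupported mesh format: {fmt!r}")
    tm = mesh.to_trimesh()
    if vertex_scalars is not None:
        scalars = np.asarray(vertex_scalars, dtype=float)
        if scalars.shape != (mesh.n_vertices,):
            raise MeshError(
                f"vertex_scalars length {scalars.shape} != n_vertices {mesh.n_vertices}"
            )
        if fmt != "ply":
            raise MeshError("per-vertex colors require PLY output")
        tm.visual.vertex_colors = _scalars_to_colors(scalars, colormap)
        side = path.with_suffix(path.suffix + ".scalars.csv")
        with open(side, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vertex_id", "value"])
            for i, v in enumerate(scalars):
                w.writerow([i, repr(float(v))])
    data = tm.export(file_type=fmt, encoding="ascii") if fmt == "ply" else tm.export(file_type="obj")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def _scalars_to_colors(scalars: np.ndarray, colormap: str) -> np.ndarray:
    import matplotlib
    from matplotlib import colors as mcolors

    finite = np.isfinite(scalars)
    lo = scalars[finite].min() if finite.any() else 0.0
    hi = scalars[finite].max() if finite.any() else 1.0
    norm = mcolors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    rgba = matplotlib.colormaps[colormap](norm(np.where(finite, scalars, lo)))
    out = (rgba * 255).astype(np.uint8)
    out[~finite] = (128, 128, 128, 255)
    return out


# -- rigid alignment -------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-12)
                and np.allclose(self.translation, 0.0, atol=1e-12))


def _kabsch(moving_pts: np.ndarray, fixed_pts: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation (no scaling)."""
    mc = moving_pts.mean(axis=0)
    fc = fixed_pts.mean(axis=0)
    H = (moving_pts - mc).T @ (fixed_pts - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return RigidTransform(R, t)


def align_from_fiducials(moving: TriangleMesh, fixed_points, moving_points):
    """Rigidly pose ``moving`` so 3 fiducials best match their fixed twins.

    This is the common-orientation step driven by manually located outer eye
    corners and nasion; high accuracy is not needed because a full ICP
    refinement follows.

    Returns ``(transform, transformed_mesh, rmsd)``.
    """
    fixed_pts = np.asarray(fixed_points, dtype=float)
    moving_pts = np.asarray(moving_points, dtype=float)
    if fixed_pts.shape != (3, 3) or moving_pts.shape != (3, 3):
        raise ValueError("exactly 3 fiducial point pairs are required")
    for pts in (fixed_pts, moving_pts):
        area2 = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        scale = max(np.ptp(pts), 1.0)
        if area2 < 1e-12 * scale**2:
            raise ValueError("fiducial points are collinear; rotation is degenerate")
    tf = _kabsch(moving_pts, fixed_pts)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(moving_pts) - fixed_pts) ** 2, axis=1))))
    return tf, moving.transformed(tf.rotation, tf.translation), rmsd


def icp_align(moving: TriangleMesh, reference: TriangleMesh,
              max_iters: int = 50, tol: float = 1e-6):
    """Point-to-point ICP onto a reference mesh.

    Nearest-vertex matching followed by a rigid Kabsch update per iteration;
    stops when the matched-point RMSD improves by less than
    ``tol * bounding-box diagonal`` of the reference.  Only improving updates
    are accepted, so the RMSD trace is non-increasing.

    Returns ``(transform, transformed_mesh, rmsd_trace)``.
    """
    if moving.n_vertices == 0 or reference.n_vertices == 0:
        raise MeshError("ICP requires non-empty meshes")
    scale = reference.bounding_box_diagonal() or 1.0
    tree = reference.kdtree()
    R = np.eye(3)
    t = np.zeros(3)
    pts = moving.vertices.copy()
    d, idx = tree.query(pts)
    rmsd = float(np.sqrt(np.mean(d**2)))
    trace = [rmsd]
    for _ in range(max_iters):
        step = _kabsch(pts, reference.vertices[idx])
        new_pts = step.apply(pts)
        d_new, idx_new = tree.query(new_pts)
        rmsd_new = float(np.sqrt(np.mean(d_new**2)))
        if rmsd_new > rmsd + 1e-15:
            break
        pts, idx = new_pts, idx_new
        R = step.rotation @ R
        t = step.rotation @ t + step.translation
        improved = rmsd - rmsd_new
        rmsd = rmsd_new
        trace.append(rmsd)
        if improved < tol * scale:
            break
    tf = RigidTransform(R, t)
    return tf, moving.transformed(R, t), trace
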