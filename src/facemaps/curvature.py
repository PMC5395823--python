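"""Principal-curvature estimation and curvature indices at surface landmarks.

At each landmark the shape operator is fitted by least squares from finite
differences of vertex unit normals against tangent-plane displacements over
a metric neighborhood (``dN ~ S dX`` in a local tangent basis).  Its
eigenvalues are the principal curvatures, signed so convex-outward regions
are positive: a nose tip has positive mean curvature, an eye socket a
negative one.  Four scalar indices condense the pair (Kmax, Kmin):

    MC = (Kmax + Kmin) / 2            mean curvature       [1/length]
    GC = Kmax * Kmin                  Gaussian curvature    [1/length^2]
    CU = sqrt((Kmax^2 + Kmin^2) / 2)  curvedness            [1/length]
    SI = (2/pi) atan((Kmax + Kmin) / (Kmax - Kmin))  shape index  [-1, 1]

CU measures how bent the surface is irrespective of shape; SI is the
scale-free shape descriptor separating cups (-1), saddles (0), ridges (0.5)
and domes (+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import SurfacePoint, TriangleMesh

__all__ = [
    "CurvatureProfile",
    "estimate_principal_curvatures",
    "curvature_indices",
    "curvature_maps",
    "default_curvature_radius",
    "INDEX_NAMES",
]

INDEX_NAMES = ("MC", "GC", "CU", "SI")


@dataclass(frozen=True)
class CurvatureProfile:
    """Principal curvatures and the four derived indices at one point."""

    k_max: float
    k_min: float
    MC: float
    GC: float
    CU: float
    SI: float

    def __post_init__(self):
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")


def default_curvature_radius(mean_surface_area: float, n_landmarks: int) -> float:
    """Neighborhood radius of about two mean landmark spacings."""
    return 2.0 * math.sqrt(mean_surface_area / (math.pi * max(n_landmarks, 1)))


def estimate_principal_curvatures(mesh: TriangleMesh, point: SurfacePoint,
                                  radius: float):
    """Principal curvatures (k_max, k_min) and directions at a surface point.

    Fits the 2x2 symmetric shape operator S to the finite differences of
    vertex unit normals over all mesh vertices within Euclidean ``radius``
    of the point, in the tangent basis of the point's interpolated normal.
    With outward-oriented normals a sphere of radius r yields +1/r.

    Returns ``(k_max, k_min, dir_max, dir_min)`` with directions as 3D unit
    vectors in the tangent plane.
    """
    p = point.position(mesh)
    tri = mesh.faces[point.face]
    vn = mesh.vertex_normals()
    n0 = point.bary @ vn[tri]
    n0 = n0 / np.linalg.norm(n0)
    idx = mesh.kdtree().query_ball_point(p, radius)
    if len(idx) < 5:
        # near a boundary or on a coarse mesh the metric ball can run dry;
        # fall back to the 6 nearest vertices
        if mesh.n_vertices < 6:
            raise ValueError(
                f"only {len(idx)} vertices within radius {radius}; need >= 5")
        _, idx = mesh.kdtree().query(p, k=6)
    idx = np.asarray(idx)
    # tangent basis at the point
    t1 = np.cross(n0, [1.0, 0.0, 0.0])
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(n0, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n0, t1)
    dX = mesh.vertices[idx] - p
    dN = vn[idx] - n0
    x = np.c_[dX @ t1, dX @ t2]                     # (k, 2)
    y = np.c_[dN @ t1, dN @ t2]                     # (k, 2)
    # symmetric S with unknowns (s11, s12, s22): y ~ S x
    A = np.zeros((2 * len(idx), 3))
    A[0::2, 0] = x[:, 0]
    A[0::2, 1] = x[:, 1]
    A[1::2, 1] = x[:, 0]
    A[1::2, 2] = x[:, 1]
    b = y.reshape(-1)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    S = np.array([[coef[0], coef[1]], [coef[1], coef[2]]])
    lam, vecs = np.linalg.eigh(S)                   # ascending
    k_min, k_max = float(lam[0]), float(lam[1])
    dir_min = vecs[0, 0] * t1 + vecs[1, 0] * t2
    dir_max = vecs[0, 1] * t1 + vecs[1, 1] * t2
    return k_max, k_min, dir_max, dir_min


def curvature_indices(k_max: float, k_min: float,
                      umbilic_tol: float = 1e-9) -> CurvatureProfile:
    """The four curvature indices from a principal-curvature pair.

    At umbilic points (k_max == k_min) the shape index is taken as the sign
    of the mean curvature (+1 dome / -1 cup), and 0 when the point is flat.
    """
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    mc = 0.5 * (k_max + k_min)
    gc = k_max * k_min
    cu = math.sqrt(0.5 * (k_max**2 + k_min**2))
    scale = max(abs(k_max), abs(k_min), 1.0)
    if abs(k_max - k_min) < umbilic_tol * scale:
        si = float(np.sign(mc))
    else:
        si = (2.0 / math.pi) * math.atan((k_max + k_min) / (k_max - k_min))
    return CurvatureProfile(k_max=k_max, k_min=k_min, MC=mc, GC=gc, CU=cu, SI=si)


def landmark_curvatures(mesh: TriangleMesh, landmarks, radius: float) -> pd.DataFrame:
    """CurvatureProfile fields for every landmark of one mesh (rows =
    landmark index)."""
    rows = []
    for p in landmarks:
        k_max, k_min, _, _ = estimate_principal_curvatures(mesh, p, radius)
        prof = curvature_indices(k_max, k_min)
        rows.append({"k_max": prof.k_max, "k_min": prof.k_min,
                     "MC": prof.MC, "GC": prof.GC, "CU": prof.CU, "SI": prof.SI})
    return pd.DataFrame(rows)


def curvature_maps(meshes, landmark_sets, radius: float,
                   subject_ids=None, pairs: pd.DataFrame | None = None):
    """Subjects x landmarks matrix of each curvature index, with summaries.

    Returns ``(matrices, summaries)``: ``matrices[index]`` is a DataFrame
    (rows = subjects, columns = landmark ids); ``summaries[index]`` holds the
    landmark-wise mean and variance, plus — when a pair table with columns
    ``pair_id, zygosity, subject1, subject2`` is given — the MZ and DZ mean
    and variance of absolute within-pair differences.
    """
    if subject_ids is None:
        subject_ids = list(range(len(meshes)))
    if len(subject_ids) != len(meshes) or len(landmark_sets) != len(meshes):
        raise ValueError("meshes, landmark_sets and subject_ids must align")
    per_subject = {name: [] for name in INDEX_NAMES}
    for mesh, lms in zip(meshes, landmark_sets):
        df = landmark_curvatures(mesh, lms, radius)
        for name in INDEX_NAMES:
            per_subject[name].append(df[name].to_numpy())
    matrices = {
        name: pd.DataFrame(np.vstack(vals), index=subject_ids)
        for name, vals in per_subject.items()
    }
    summaries = {}
    for name, mat in matrices.items():
        s = pd.DataFrame({
            "mean": mat.mean(axis=0),
            "variance": mat.var(axis=0, ddof=1) if len(mat) > 1 else 0.0,
        })
        if pairs is not None:
            for col in ("pair_id", "zygosity", "subject1", "subject2"):
                if col not in pairs.columns:
                    raise ValueError(f"pair table lacks column {col!r}")
            known = set(subject_ids)
            for zyg in ("MZ", "DZ"):
                grp = pairs[pairs["zygosity"] == zyg]
                missing = (set(grp["subject1"]) | set(grp["subject2"])) - known
                if missing:
                    raise ValueError(f"pair table references unknown subjects {missing}")
                if not len(grp):
                    continue
                diffs = np.abs(mat.loc[grp["subject1"]].to_numpy()
                               - mat.loc[grp["subject2"]].to_numpy())
                s[f"{zyg}_absdiff_mean"] = diffs.mean(axis=0)
                s[f"{zyg}_absdiff_var"] = (diffs.var(axis=0, ddof=1)
                                           if len(diffs) > 1 else 0.0)
        summaries[name] = s
    return matrices, summaries
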