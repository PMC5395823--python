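"""Scalar facial phenotypes: fiducial distances and sparse-PCA regional traits.

Two families of traits are built on the dense corresponding landmarks.

Distance traits use a small set of named fiducial landmarks (glabella,
nasion, pronasale, ...) located once on the average face and propagated to
every subject through the landmark correspondence.  Each trait is either
the straight-line (Euclidean) or the on-surface (geodesic) distance
between a fiducial pair — nose width, zygomatic width and so on.

Regional traits are data-driven: sparse principal components of the
subjects x landmarks matrix of a curvature index.  Sparsity (an L1-norm
bound on the unit-norm loading vector) confines each component to a
spatially coherent facial region; the loadings visualized on the average
face form an "Eigenface map" delineating that region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesic import GeodesicSolver
from .mesh import SurfacePoint, TriangleMesh

__all__ = [
    "FIDUCIAL_LABELS",
    "DEFAULT_TRAIT_PAIRS",
    "FiducialMap",
    "RegionalTrait",
    "pick_fiducials",
    "distance_traits",
    "regress_out_age",
    "sparse_pca",
    "eigenface_map",
]

#: the 17 named fiducial landmarks (L/R = subject's left/right)
FIDUCIAL_LABELS = (
    "g", "n", "prn", "sn", "gn",
    "alL", "alR", "exL", "exR", "enL", "enR",
    "zyL", "zyR", "chL", "chR", "goL", "goR",
)

#: the ten standard distance phenotypes built from fiducial pairs
DEFAULT_TRAIT_PAIRS = (
    ("sn", "gn"),    # height of lower face
    ("g", "sn"),     # height of middle face
    ("n", "sn"),     # nose height
    ("sn", "prn"),   # nasal protrusion
    ("alL", "alR"),  # nose width
    ("exL", "exR"),  # intercanthal width
    ("enL", "enR"),  # biocular width
    ("zyL", "zyR"),  # zygomatic width
    ("goL", "goR"),  # mandible width
    ("chL", "chR"),  # mouth width
)


@dataclass(frozen=True)
class FiducialMap:
    """label -> landmark index on the corresponded landmark sets."""

    indices: dict

    def __post_init__(self):
        if len(set(self.indices.values())) < len(self.indices):
            import warnings

            warnings.warn("two fiducial labels share one landmark index",
                          stacklevel=2)

    def __getitem__(self, label: str) -> int:
        return self.indices[label]

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, label) -> bool:
        return label in self.indices


def pick_fiducials(average_landmarks: np.ndarray, picks: dict) -> FiducialMap:
    """Map each labelled 3D pick to the nearest average-face landmark.

    ``average_landmarks`` is the (M, 3) array of landmark positions on the
    average face; ``picks`` maps label -> 3D point (from visual inspection
    or a picks file).  Ties break to the lowest landmark index.  Through the
    index correspondence the fiducials are thereby located on every subject.
    """
    avg = np.asarray(average_landmarks, dtype=float)
    out = {}
    for label, pt in picks.items():
        d = np.linalg.norm(avg - np.asarray(pt, dtype=float), axis=1)
        out[label] = int(np.argmin(d))  # argmin returns the lowest tied index
    return FiducialMap(out)


def distance_traits(meshes, landmark_sets, fiducials: FiducialMap,
                    pairs=DEFAULT_TRAIT_PAIRS, mode: str = "euclidean",
                    subject_ids=None) -> pd.DataFrame:
    """Subjects x traits matrix of fiducial-pair distances.

    ``mode='euclidean'`` measures chords through space; ``mode='geodesic'``
    measures shortest on-surface paths (always >= the chord).  Trait columns
    are named ``"labelA-labelB"``.
    """
    if mode not in ("euclidean", "geodesic"):
        raise ValueError(f"unknown mode {mode!r}")
    for a, b in pairs:
        if a not in fiducials or b not in fiducials:
            raise ValueError(f"fiducial pair ({a}, {b}) not in the map")
    if subject_ids is None:
        subject_ids = list(range(len(meshes)))
    cols = {f"{a}-{b}": [] for a, b in pairs}
    for mesh, lms in zip(meshes, landmark_sets):
        solver = None
        if mode == "geodesic":
            if "geodesic_solver" not in mesh._cache:
                mesh._cache["geodesic_solver"] = GeodesicSolver(mesh)
            solver = mesh._cache["geodesic_solver"]
        for a, b in pairs:
            pa, pb = lms[fiducials[a]], lms[fiducials[b]]
            if mode == "euclidean":
                d = float(np.linalg.norm(pa.position(mesh) - pb.position(mesh)))
            else:
                d = solver.distance(pa, pb)
                if not np.isfinite(d):
                    raise ValueError(
                        f"fiducials {a} and {b} lie on disconnected components")
            cols[f"{a}-{b}"].append(d)
    return pd.DataFrame(cols, index=subject_ids)


def regress_out_age(trait_matrix, ages) -> pd.DataFrame:
    """Residualize every trait column on (intercept, age) by OLS.

    The residuals have exactly zero sample covariance with age, matching
    the pre-residualization route used for multivariate analyses where the
    covariate cannot sit inside the per-trait model.
    """
    X = np.asarray(trait_matrix, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if not np.isfinite(ages).all():
        raise ValueError("ages must be finite")
    if ages.std() == 0:
        raise ValueError("age is constant; the regression is degenerate")
    if len(ages) != len(X):
        raise ValueError("one age per subject required")
    D = np.c_[np.ones_like(ages), ages]
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    if isinstance(trait_matrix, pd.DataFrame):
        return pd.DataFrame(resid, index=trait_matrix.index,
                            columns=trait_matrix.columns)
    return pd.DataFrame(resid)


@dataclass(frozen=True)
class RegionalTrait:
    """One sparse component: unit-norm loadings over landmarks, per-subject
    scores and the fraction of total variance it explains."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: float

    def __post_init__(self):
        n = np.linalg.norm(self.loadings)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("loadings must have unit L2 norm")
        if not 0.0 <= self.explained_variance <= 1.0 + 1e-12:
            raise ValueError("explained variance must lie in [0, 1]")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.loadings))


def _soft_threshold(z: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - delta, 0.0)


def _l1_constrained_unit(z: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 vector maximizing z.w subject to ||w||_1 <= c: soft-threshold
    z with the smallest delta meeting the bound (bisection)."""
    def one_hot():
        w = np.zeros_like(z)
        i = int(np.argmax(np.abs(z)))
        w[i] = np.sign(z[i]) or 1.0
        return w

    nz = np.linalg.norm(z)
    if nz == 0:
        return one_hot()
    # ||w||_1 >= ||w||_2 with equality only for one-hot vectors
    if c <= 1.0 + 1e-12:
        return one_hot()
    w = z / nz
    if np.abs(w).sum() <= c:
        return w
    lo, hi = 0.0, np.abs(z).max()
    feasible = one_hot()
    for _ in range(100):
        delta = 0.5 * (lo + hi)
        w = _soft_threshold(z, delta)
        nw = np.linalg.norm(w)
        if nw == 0:
            hi = delta
            continue
        w = w / nw
        if np.abs(w).sum() > c:
            lo = delta
        else:
            hi = delta
            feasible = w
    return feasible


def sparse_pca(data, n_components: int, sparsity_bound: float,
               max_iter: int = 200, tol: float = 1e-9):
    """Sequential rank-one sparse principal components with deflation.

    Each component maximizes explained variance subject to ``||w||_2 = 1``
    and ``||w||_1 <= sparsity_bound`` (penalized matrix decomposition by
    alternating power iteration with an L1-ball projection), then the
    rank-one fit is subtracted.  ``sparsity_bound`` interpolates from 1
    (single landmark) to sqrt(M) (dense PCA).  ``data`` should be
    column-centered (e.g. age-residualized).

    Returns a list of ``RegionalTrait``.
    """
    X = np.asarray(data, dtype=float).copy()
    n, M = X.shape
    if not 1.0 <= sparsity_bound <= math.sqrt(M) + 1e-9:
        raise ValueError(
            f"sparsity bound must lie in [1, sqrt(M)={math.sqrt(M):.3f}]")
    total_var = float((X ** 2).sum()) / max(n - 1, 1)
    if total_var == 0:
        raise ValueError("data matrix has zero variance")
    out = []
    for k in range(n_components):
        # deterministic init: leading right singular direction
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        w = vt[0]
        for _ in range(max_iter):
            z = X.T @ (X @ w)
            w_new = _l1_constrained_unit(z, sparsity_bound)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        scores = X @ w
        ev = float(scores.var(ddof=1)) / total_var if n > 1 else 0.0
        out.append(RegionalTrait(loadings=w, scores=scores,
                                 explained_variance=ev))
        X = X - np.outer(scores, w)
    return out


def eigenface_map(trait: RegionalTrait, average_landmarks, mesh=None, *,
                  path=None, csv_path=None, colormap: str = "viridis"):
    """Absolute loadings of a regional trait painted on the average face.

    Zero loadings render neutral (lowest colormap entry); the map shows
    magnitude, so flipping the sign of the loadings leaves it unchanged.
    Optionally writes a colored PLY (needs ``mesh``) and a loadings CSV.
    Returns the per-landmark magnitude array.
    """
    avg = np.asarray(average_landmarks, dtype=float)
    if len(avg) != len(trait.loadings):
        raise ValueError("loadings and average landmarks must align")
    mags = np.abs(trait.loadings)
    if csv_path is not None:
        pd.DataFrame({
            "landmark_id": np.arange(len(mags)),
            "weight": trait.loadings,
            "magnitude": mags,
        }).to_csv(csv_path, index=False)
    if path is not None:
        if mesh is None:
            raise ValueError("writing a map PLY requires the average mesh")
        from scipy.spatial import cKDTree

        from .mesh import write_mesh

        _, nearest = cKDTree(avg).query(mesh.vertices)
        write_mesh(mesh, path, fmt="ply", vertex_scalars=mags[nearest],
                   colormap=colormap)
    return mags
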