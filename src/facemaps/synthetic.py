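"""Synthetic face-like surfaces and twin ensembles with known ACE structure.

Real twin-cohort facial scans cannot be redistributed, so every pipeline
stage is exercised on parametric stand-ins: an open "facial" surface built
from a subdivided icosphere scaled to an ellipsoid, radially displaced by
Gaussian bumps (nose/chin/brow analogues), with the back hemisphere removed
to create a boundary like a cropped facial scan.

Twin structure enters through the bump amplitudes.  For each pair a
standardized amplitude deviate is drawn as A = a*G + c*C + e*U with variance
shares a^2 + c^2 + e^2 = 1: G is the additive-genetic part (shared by MZ
co-twins, correlation 1/2 between DZ co-twins via G = (G_shared +
G_own)/sqrt(2)), C the common environment (always shared) and U the unique
environment (never shared).  MZ covariance is therefore a^2 + c^2 and DZ
covariance a^2/2 + c^2, the classical-twin identity the estimation stage
relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .mesh import TriangleMesh

__all__ = [
    "Bump",
    "FaceParams",
    "make_face_mesh",
    "simulate_twin_ensemble",
    "simulate_twin_traits",
    "DEFAULT_FACE",
]


@dataclass(frozen=True)
class Bump:
    """Gaussian radial bump: ``location`` on the unit sphere, angular
    ``width`` in radians, ``amplitude`` as a fraction of the local radius."""

    location: tuple[float, float, float]
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bump width must be > 0")


@dataclass(frozen=True)
class FaceParams:
    """Geometry of one synthetic face.

    ``semi_axes`` are the ellipsoid half-diameters (length units; defaults
    give a slightly tall, shallow face of diameter ~2).  ``noise_sd`` is
    i.i.d. Gaussian vertex jitter, mimicking scanner noise.
    """

    semi_axes: tuple[float, float, float] = (1.0, 1.2, 0.9)
    bumps: tuple[Bump, ...] = ()
    noise_sd: float = 0.0

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: a face-like default: nose-type bump on the front, brow-type bump above
DEFAULT_FACE = FaceParams(
    semi_axes=(1.0, 1.2, 0.9),
    bumps=(
        Bump(location=(0.0, -0.15, 1.0), width=0.30, amplitude=0.18),
        Bump(location=(0.0, 0.55, 1.0), width=0.35, amplitude=0.10),
    ),
    noise_sd=0.0,
)


def make_face_mesh(params: FaceParams, subdivisions: int = 4,
                   seed: int | None = None, crop: bool = True) -> TriangleMesh:
    """Build one synthetic facial surface.

    A subdivided icosphere is radially displaced by the Gaussian bumps,
    scaled to the ellipsoid, optionally cropped to the +z hemisphere (open
    surface with boundary) and jittered with seeded vertex noise.
    """
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float).copy()
    faces = np.asarray(ico.faces)
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    r = np.ones(len(verts))
    for bump in params.bumps:
        loc = np.asarray(bump.location, dtype=float)
        loc = loc / np.linalg.norm(loc)
        ang = np.arccos(np.clip(unit @ loc, -1.0, 1.0))
        r = r + bump.amplitude * np.exp(-0.5 * (ang / bump.width) ** 2)
    verts = unit * r[:, None] * np.asarray(params.semi_axes)
    if crop:
        keep_vert = verts[:, 2] > 0.0
        keep_face = keep_vert[faces].all(axis=1)
        faces = faces[keep_face]
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        verts = verts[used]
        faces = remap[faces]
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(scale=params.noise_sd, size=verts.shape)
    return TriangleMesh(verts, faces, orientation_axis=(0.0, 0.0, 1.0))


def _ace_deviates(a2: float, c2: float, e2: float, n_mz: int, n_dz: int,
                  rng: np.random.Generator):
    """Standardized per-twin ACE deviates; returns (mz, dz) arrays of shape
    (n, 2)."""
    if not math.isclose(a2 + c2 + e2, 1.0, abs_tol=1e-9):
        raise ValueError("variance shares a2 + c2 + e2 must sum to 1")
    if min(a2, c2, e2) < 0:
        raise ValueError("variance shares must be nonnegative")
    a, c, e = math.sqrt(a2), math.sqrt(c2), math.sqrt(e2)
    g_mz = rng.normal(size=(n_mz, 1))
    c_mz = rng.normal(size=(n_mz, 1))
    u_mz = rng.normal(size=(n_mz, 2))
    mz = a * g_mz + c * c_mz + e * u_mz
    g_sh = rng.normal(size=(n_dz, 1))
    g_own = rng.normal(size=(n_dz, 2))
    g_dz = (g_sh + g_own) / math.sqrt(2.0)   # genetic correlation exactly 1/2
    c_dz = rng.normal(size=(n_dz, 1))
    u_dz = rng.normal(size=(n_dz, 2))
    dz = a * g_dz + c * c_dz + e * u_dz
    return mz, dz


def simulate_twin_ensemble(base: FaceParams, heritable_spec, n_mz: int,
                           n_dz: int, *, amp_sd: float = 0.5,
                           ages=None, age_beta=None, subdivisions: int = 3,
                           seed: int = 0, build_meshes: bool = True):
    """Meshes for a twin cohort whose bump amplitudes follow ACE structure.

    ``heritable_spec`` maps bump index -> (a2, c2, e2) variance shares
    (unlisted bumps stay fixed).  Each affected bump's amplitude becomes
    ``base_amplitude * (1 + amp_sd * A)`` with A the standardized ACE
    deviate; ``amp_sd`` is the coefficient of variation of the bump size.
    Optional ``ages`` (per pair) with ``age_beta`` (per bump, amplitude per
    year) add a linear age trend shared by co-twins.

    Returns ``(meshes, truth)``: meshes ordered twin1, twin2 per pair (MZ
    pairs first), and a truth table with one row per subject.
    """
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair of each zygosity")
    rng = np.random.default_rng(seed)
    n_pairs = n_mz + n_dz
    if ages is None:
        ages = rng.uniform(40.0, 70.0, size=n_pairs)
    ages = np.asarray(ages, dtype=float)
    deviates = {}
    for b_idx, shares in heritable_spec.items():
        mz, dz = _ace_deviates(*shares, n_mz, n_dz, rng)
        deviates[b_idx] = np.vstack([mz, dz])        # (n_pairs, 2)
    meshes = []
    rows = []
    for p_idx in range(n_pairs):
        zyg = "MZ" if p_idx < n_mz else "DZ"
        for t_idx in range(2):
            bumps = []
            row = {"subject_id": 2 * p_idx + t_idx, "pair_id": p_idx,
                   "zygosity": zyg, "twin": t_idx + 1, "age": ages[p_idx]}
            for b_idx, bump in enumerate(base.bumps):
                amp = bump.amplitude
                if b_idx in deviates:
                    amp = amp * (1.0 + amp_sd * deviates[b_idx][p_idx, t_idx])
                if age_beta is not None and b_idx in age_beta:
                    amp = amp + age_beta[b_idx] * ages[p_idx]
                bumps.append(Bump(bump.location, bump.width, amp))
                row[f"bump{b_idx}_amplitude"] = amp
            mesh_seed = int(rng.integers(0, 2**31 - 1))
            if build_meshes:
                params = FaceParams(semi_axes=base.semi_axes,
                                    bumps=tuple(bumps), noise_sd=base.noise_sd)
                meshes.append(make_face_mesh(params, subdivisions=subdivisions,
                                             seed=mesh_seed))
            rows.append(row)
    return (meshes if build_meshes else None), pd.DataFrame(rows)


def simulate_twin_traits(n_mz: int, n_dz: int, a2: float, c2: float,
                         e2: float, *, age_beta: float = 0.0, mean: float = 0.0,
                         sd: float = 1.0, age_range=(40.0, 70.0),
                         seed: int = 0) -> pd.DataFrame:
    """Scalar twin-pair table drawn from the bivariate-normal ACE model.

    Trait = mean + age_beta * age + sd * A with A the standardized ACE
    deviate; co-twins share their age.  Returns the pair table with columns
    ``pair_id, zygosity, value_twin1, value_twin2, age_twin1, age_twin2``.
    """
    rng = np.random.default_rng(seed)
    mz, dz = _ace_deviates(a2, c2, e2, n_mz, n_dz, rng)
    vals = np.vstack([mz, dz]) * sd + mean
    ages = rng.uniform(*age_range, size=n_mz + n_dz)
    vals = vals + age_beta * ages[:, None]
    return pd.DataFrame({
        "pair_id": np.arange(n_mz + n_dz),
        "zygosity": ["MZ"] * n_mz + ["DZ"] * n_dz,
        "value_twin1": vals[:, 0],
        "value_twin2": vals[:, 1],
        "age_twin1": ages,
        "age_twin2": ages,
    })
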