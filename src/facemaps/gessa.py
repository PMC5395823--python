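"""Ensemble surface sampling: dense corresponding landmarks by entropy
optimization with geodesic geometry.

The optimizer places M landmarks on each of N surfaces and minimizes

    Q = H(Z) - sum_j H(P_j)

where ``H(Z)`` is the entropy of the landmark configurations viewed as
points in 3M-dimensional shape space under a Gaussian model (its descent
tightens cross-surface correspondence) and ``H(P_j)`` is the entropy of the
landmark distribution on surface j estimated with a geodesic-distance
Gaussian kernel (its ascent spreads landmarks uniformly).  All updates are
tangent vectors mapped back to the surface with the exponential map, so
landmarks never leave their mesh.  Optimization proceeds by iterative
doubling: one seed landmark per surface, then alternate gradient descent
and landmark splitting until the target count 2^L is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geodesic import GeodesicSolver
from .mesh import SurfacePoint, TangentVector, TriangleMesh

__all__ = [
    "EnsembleState",
    "surface_density",
    "uniformity_gradient",
    "shape_entropy",
    "correspondence_gradient",
    "gessa_step",
    "split_landmarks",
    "run_gessa",
    "validate_against_fiducials",
    "default_sigma",
]

#: geodesic kernel support: pairs farther than this many sigma are dropped
KERNEL_CUTOFF = 4.0
#: largest per-iteration shrink of a shape-space deviation mode
_CORR_SHRINK_CAP = 0.3
_GAUSS_FLOOR = 1e-300


def default_sigma(mean_surface_area: float, n_landmarks: int) -> float:
    """Kernel bandwidth matched to the mean inter-landmark spacing,
    ``sqrt(area / (pi M))``: each kernel covers about one landmark's share
    of the surface."""
    return math.sqrt(mean_surface_area / (math.pi * max(n_landmarks, 1)))


def surface_density(mesh: TriangleMesh, landmarks, i: int, sigma: float,
                    solver: GeodesicSolver | None = None) -> float:
    """Geodesic kernel density estimate at landmark i from its co-surface
    landmarks: ``(1/(M-1)) sum_k exp(-d_g^2 / 2 sigma^2) / (2 pi sigma^2)``.
    """
    M = len(landmarks)
    if M < 2:
        raise ValueError("surface density needs at least 2 landmarks")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    solver = solver or _mesh_solver(mesh)
    others = [landmarks[k] for k in range(M) if k != i]
    d = solver.distances([landmarks[i]], others,
                         limit=2 * KERNEL_CUTOFF * sigma)[0]
    w = np.exp(-np.square(d[np.isfinite(d)]) / (2 * sigma**2))
    return float(w.sum() / ((M - 1) * 2 * math.pi * sigma**2))


def uniformity_gradient(mesh: TriangleMesh, landmarks, i: int, sigma: float,
                        solver: GeodesicSolver | None = None) -> TangentVector:
    """Kernel-weighted mean log-map at landmark i, scaled by 1/sigma^2.

    Points toward the local mass of neighboring landmarks; the uniformity
    (entropy-ascent) update moves along its negative, repelling landmark i
    from its neighbors.  Returns the zero vector when every kernel weight
    underflows (isolated landmark).
    """
    M = len(landmarks)
    if M < 2:
        raise ValueError("uniformity gradient needs at least 2 landmarks")
    solver = solver or _mesh_solver(mesh)
    others = [landmarks[k] for k in range(M) if k != i]
    d, vecs = solver.log_maps(landmarks[i], others, limit=KERNEL_CUTOFF * sigma)
    finite = np.isfinite(d)
    if not finite.any():
        return TangentVector(landmarks[i], np.zeros(3))
    w = np.exp(-np.square(d[finite]) / (2 * sigma**2))
    if w.sum() <= 0:
        return TangentVector(landmarks[i], np.zeros(3))
    g = (w[:, None] * vecs[finite]).sum(axis=0) / (w.sum() * sigma**2)
    return TangentVector(landmarks[i], g)


def shape_entropy(shape_vectors: np.ndarray, alpha: float) -> float:
    """Gaussian shape-space entropy, additive constants dropped.

    ``H = 0.5 * sum_k log(lambda_k + alpha)`` over the 3M eigenvalues of the
    sample covariance of the N shape vectors, evaluated through the N x N
    dual Gram matrix; the 3M - N eigenvalues beyond the sample rank are
    exactly zero and contribute ``log(alpha)`` each.
    """
    Z = np.asarray(shape_vectors, dtype=float)
    N, D = Z.shape
    if N < 2:
        raise ValueError("shape entropy needs at least 2 surfaces")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    Y = Z - Z.mean(axis=0)
    gram = Y @ Y.T / (N - 1)
    lam = np.clip(np.linalg.eigvalsh(gram), 0.0, None)
    return float(0.5 * (np.log(lam + alpha).sum() + (D - N) * math.log(alpha)))


def correspondence_gradient(shape_vectors: np.ndarray, alpha: float,
                            face_normals: np.ndarray | None = None) -> np.ndarray:
    """Gradient of the shape-space entropy w.r.t. every landmark position,
    mean held fixed, computed in the N-dimensional dual space:

        G = Y ((Y^T Y)/(N-1) + alpha I)^{-1} / (N-1)

    with ``Y`` the 3M x N centered data matrix.  When ``face_normals``
    (N, M, 3) is given, each per-landmark 3-vector is projected onto its
    landmark's face plane.  Returns an (N, M, 3) array.
    """
    Z = np.asarray(shape_vectors, dtype=float)
    N, D = Z.shape
    if N < 2:
        raise ValueError("correspondence gradient needs at least 2 surfaces")
    M = D // 3
    Y = (Z - Z.mean(axis=0)).T                      # (3M, N)
    K = Y.T @ Y / (N - 1) + alpha * np.eye(N)
    G = Y @ np.linalg.solve(K, np.eye(N)) / (N - 1)  # (3M, N)
    out = G.T.reshape(N, M, 3)
    if face_normals is not None:
        out = out - (np.sum(out * face_normals, axis=2, keepdims=True)
                     * face_normals)
    return out


@dataclass
class EnsembleState:
    """N surfaces x M corresponding landmarks plus optimizer parameters.

    ``sigma`` is the geodesic kernel bandwidth (length units), ``gamma``
    the gradient-descent step (squared-length units, multiplying gradients
    of dimension 1/length), ``alpha`` the shape-covariance regularizer
    (squared-length units).  ``weight_corr`` scales the correspondence term
    of the cost relative to the uniformity term (1.0 = equal weight).
    """

    meshes: list[TriangleMesh]
    landmarks: list[list[SurfacePoint]]
    sigma: float
    gamma: float
    alpha: float
    level: int = 0
    weight_corr: float = 1.0
    solvers: list[GeodesicSolver] = field(default_factory=list)
    n_clipped: int = 0

    def __post_init__(self):
        if len({len(lm) for lm in self.landmarks}) > 1:
            raise ValueError("all surfaces must carry the same landmark count")
        if self.sigma <= 0 or self.gamma <= 0 or self.alpha <= 0:
            raise ValueError("sigma, gamma and alpha must all be > 0")
        if not self.solvers:
            self.solvers = [_mesh_solver(m) for m in self.meshes]

    @property
    def n_surfaces(self) -> int:
        return len(self.meshes)

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks[0])

    def shape_vectors(self) -> np.ndarray:
        """(N, 3M) matrix of concatenated landmark coordinates."""
        return np.array([
            np.concatenate([p.position(m) for p in lms])
            for m, lms in zip(self.meshes, self.landmarks)
        ])

    def landmark_normals(self) -> np.ndarray:
        """(N, M, 3) face unit normals under each landmark."""
        return np.array([
            m.face_normals()[[p.face for p in lms]]
            for m, lms in zip(self.meshes, self.landmarks)
        ])


def _mesh_solver(mesh: TriangleMesh, **kw) -> GeodesicSolver:
    if "geodesic_solver" not in mesh._cache:
        mesh._cache["geodesic_solver"] = GeodesicSolver(mesh, **kw)
    return mesh._cache["geodesic_solver"]


def _surface_terms(state: EnsembleState, j: int):
    """Per-surface kernel field: negative sampled entropy contribution and
    per-landmark uniformity gradients.  Returns (H_j, grads (M, 3)).

    Results are cached on the state (positions never mutate in place), so a
    cost evaluation and a subsequent gradient step share one geodesic pass.
    """
    cache = getattr(state, "_field_cache", None)
    if cache is None:
        cache = {}
        state._field_cache = cache
    if j in cache:
        return cache[j]
    out = _surface_terms_impl(state, j)
    cache[j] = out
    return out


def _surface_terms_impl(state: EnsembleState, j: int):
    lms = state.landmarks[j]
    M = len(lms)
    sigma = state.sigma
    if M < 2:
        return 0.0, np.zeros((M, 3))
    # raw graph distances suffice for the kernel weights (their few-percent
    # error is far below the bandwidth), and in-plane chord directions
    # approximate the initial geodesic direction well at kernel range
    D, nbr, vecs = state.solvers[j].pairwise_field(
        lms, KERNEL_CUTOFF * sigma, max_neighbors=24, chord_directions=True)
    grads = np.zeros((M, 3))
    logp = np.empty(M)
    norm = 2 * math.pi * sigma**2 * (M - 1)
    for i in range(M):
        if len(nbr[i]) == 0:
            logp[i] = math.log(_GAUSS_FLOOR)
            continue
        w = np.exp(-np.square(D[i, nbr[i]]) / (2 * sigma**2))
        sw = w.sum()
        logp[i] = math.log(max(sw / norm, _GAUSS_FLOOR))
        if sw > 0:
            grads[i] = (w[:, None] * vecs[i]).sum(axis=0) / (sw * sigma**2)
    H_j = float(-logp.mean())
    return H_j, grads


def ensemble_cost(state: EnsembleState) -> float:
    """Correspondence cost Q = w * H(Z) - sum_j H(P_j)."""
    Q = 0.0
    if state.n_surfaces >= 2:
        Q += state.weight_corr * shape_entropy(state.shape_vectors(), state.alpha)
    if state.n_landmarks >= 2:
        for j in range(state.n_surfaces):
            H_j, _ = _surface_terms(state, j)
            Q -= H_j
    return Q


def gessa_step(state: EnsembleState, backtrack: bool = True,
               max_backtracks: int = 4):
    """One gradient-descent step on Q for every landmark of every surface.

    The tangent update for landmark i of surface j is
    ``u = -gamma * (w * corr_grad + uniformity_grad)``, applied through the
    exponential map.  With ``backtrack=True`` the step is halved (up to
    ``max_backtracks`` times) whenever Q increases.  Returns
    ``(new_state, Q_after)``.
    """
    N, M = state.n_surfaces, state.n_landmarks
    # gradients at the current configuration
    corr_H = 0.0
    corr_step = np.zeros((N, M, 3))
    if N >= 2:
        Z = state.shape_vectors()
        corr_H = state.weight_corr * shape_entropy(Z, state.alpha)
        # preconditioned correspondence step: each covariance eigenmode of
        # the dual Gram matrix shrinks by min(gamma/(lambda+alpha), cap);
        # the raw gradient Y (K + alpha I)^{-1} would scale near-null modes
        # by gamma/alpha and diverge
        Y = (Z - Z.mean(axis=0)).T                     # (3M, N)
        K = Y.T @ Y / (N - 1) + state.alpha * np.eye(N)
        lam, Qe = np.linalg.eigh(K)
        shrink = np.minimum(state.gamma / lam, _CORR_SHRINK_CAP)
        step = Y @ (Qe * shrink) @ Qe.T                # (3M, N)
        corr_step = step.T.reshape(N, M, 3)
        normals = state.landmark_normals()
        corr_step = corr_step - (np.sum(corr_step * normals, axis=2,
                                        keepdims=True) * normals)
    unif = np.zeros((N, M, 3))
    H_before = 0.0
    if M >= 2:
        for j in range(N):
            H_j, g = _surface_terms(state, j)
            unif[j] = g
            H_before += H_j
    Q_before = corr_H - H_before

    scale = 1.0
    for attempt in range(max_backtracks + 1):
        new_landmarks = []
        clipped = 0
        for j in range(N):
            lj = []
            for i in range(M):
                u = -scale * (state.weight_corr * corr_step[j, i]
                              + state.gamma * unif[j, i])
                sp, was_clipped = state.solvers[j].exp_map(
                    state.landmarks[j][i], u, full_output=True)
                if was_clipped:
                    # an open boundary would otherwise absorb landmarks:
                    # shorten the step until it stays on the surface, and
                    # reject it rather than ride the rim
                    clipped += 1
                    for _ in range(3):
                        u = 0.5 * u
                        sp, was_clipped = state.solvers[j].exp_map(
                            state.landmarks[j][i], u, full_output=True)
                        if not was_clipped:
                            break
                    if was_clipped:
                        sp = state.landmarks[j][i]
                lj.append(sp)
            new_landmarks.append(lj)
        new_state = EnsembleState(
            meshes=state.meshes, landmarks=new_landmarks, sigma=state.sigma,
            gamma=state.gamma, alpha=state.alpha, level=state.level,
            weight_corr=state.weight_corr, solvers=state.solvers,
            n_clipped=state.n_clipped + clipped)
        Q_after = ensemble_cost(new_state)
        if not backtrack or Q_after <= Q_before + 1e-12 * max(abs(Q_before), 1.0):
            return new_state, Q_after
        scale *= 0.5
    # every halving increased the cost: keep the current configuration
    return state, Q_before


def split_landmarks(state: EnsembleState, epsilon: float = 0.5,
                    rng: np.random.Generator | None = None) -> EnsembleState:
    """Double the landmark count: each landmark spawns a twin offset by
    ``epsilon * sigma`` along a direction drawn once per landmark index and
    shared by every surface, so children stay in correspondence.  Child
    ordering: parent k -> children 2k (original), 2k+1 (offset).
    """
    rng = rng or np.random.default_rng()
    M = state.n_landmarks
    dirs = rng.normal(size=(M, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    new_landmarks = []
    for j in range(state.n_surfaces):
        normals = state.meshes[j].face_normals()
        lj = []
        for k in range(M):
            parent = state.landmarks[j][k]
            n = normals[parent.face]
            d = dirs[k] - (dirs[k] @ n) * n
            nd = np.linalg.norm(d)
            if nd < 1e-12:  # direction orthogonal to this face: pick in-plane
                tri = state.meshes[j].vertices[state.meshes[j].faces[parent.face]]
                d = tri[1] - tri[0]
                nd = np.linalg.norm(d)
            d = d / nd * (epsilon * state.sigma)
            child = state.solvers[j].exp_map(parent, d)
            lj.extend([parent, child])
        new_landmarks.append(lj)
    return EnsembleState(
        meshes=state.meshes, landmarks=new_landmarks, sigma=state.sigma,
        gamma=state.gamma, alpha=state.alpha, level=state.level + 1,
        weight_corr=state.weight_corr, solvers=state.solvers,
        n_clipped=state.n_clipped)


def _init_state(meshes, seed, gamma_scale, alpha_scale, weight_corr,
                steiner_per_edge):
    rng = np.random.default_rng(seed)
    solvers = [_mesh_solver(m, steiner_per_edge=steiner_per_edge) for m in meshes]
    landmarks = []
    for m in meshes:
        areas = m.face_areas()
        fid = int(rng.choice(len(areas), p=areas / areas.sum()))
        r1, r2 = rng.random(2)
        s = math.sqrt(r1)  # uniform in the triangle
        bary = np.array([1 - s, s * (1 - r2), s * r2])
        landmarks.append([SurfacePoint(fid, bary)])
    mean_area = float(np.mean([m.surface_area() for m in meshes]))
    sigma = default_sigma(mean_area, 1)
    state = EnsembleState(
        meshes=list(meshes), landmarks=landmarks, sigma=sigma,
        gamma=gamma_scale * sigma**2, alpha=1.0, level=0,
        weight_corr=weight_corr, solvers=solvers)
    return state, rng, mean_area


def _update_alpha(state: EnsembleState, alpha_scale: float):
    """alpha = alpha_scale * trace(cov) / 3M, floored for degenerate data."""
    Z = state.shape_vectors()
    Y = Z - Z.mean(axis=0)
    tr = float(np.sum(Y * Y)) / max(len(Z) - 1, 1)
    scale = max(m.bounding_box_diagonal() for m in state.meshes)
    state.alpha = max(alpha_scale * tr / Z.shape[1], 1e-12 * scale**2)


def run_gessa(meshes, M_target: int, *, gamma_scale: float = 0.1,
              alpha_scale: float = 1e-4, epsilon: float = 0.5,
              iters_per_level: int = 100, tol: float = 1e-6,
              seed: int = 0, weight_corr: float = 1.0,
              steiner_per_edge: int = 3, backtrack: bool = True):
    """Full doubling-schedule optimization to ``M_target`` landmarks.

    ``M_target`` must be a power of two (the splitting schedule doubles the
    count each round; 4096 landmarks = 12 rounds from a single seed point).
    ``iters_per_level`` may be a single int or a sequence giving the
    iteration budget of each level (last entry reused beyond its length);
    correspondence is mostly established at coarse levels and preserved by
    splitting, so a front-loaded schedule is cheap and effective.
    Returns ``(landmark_sets, log)`` with ``landmark_sets`` index-aligned
    across surfaces and ``log`` a per-level record of the cost trace.
    """
    L = M_target.bit_length() - 1
    if M_target <= 0 or 2**L != M_target:
        raise ValueError("M_target must be a power of two")
    if len(meshes) < 2:
        raise ValueError("an ensemble needs at least 2 meshes")
    if np.isscalar(iters_per_level):
        iters_schedule = [int(iters_per_level)]
    else:
        iters_schedule = [int(x) for x in iters_per_level]
    state, rng, mean_area = _init_state(
        meshes, seed, gamma_scale, alpha_scale, weight_corr, steiner_per_edge)
    log = []
    while True:
        state.sigma = default_sigma(mean_area, state.n_landmarks)
        state.gamma = gamma_scale * state.sigma**2
        _update_alpha(state, alpha_scale)
        trace = []
        stable = 0
        Q_prev = None
        n_iters = iters_schedule[min(state.level, len(iters_schedule) - 1)]
        for _ in range(n_iters):
            state, Q = gessa_step(state, backtrack=backtrack)
            trace.append(Q)
            if Q_prev is not None:
                stable = stable + 1 if abs(Q - Q_prev) < tol * max(abs(Q), 1e-12) else 0
                if stable >= 5:
                    break
            Q_prev = Q
        log.append({"level": state.level, "M": state.n_landmarks,
                    "sigma": state.sigma, "alpha": state.alpha,
                    "Q_trace": trace, "n_clipped": state.n_clipped})
        if state.n_landmarks >= M_target:
            break
        state = split_landmarks(state, epsilon=epsilon, rng=rng)
    return state.landmarks, log


def validate_against_fiducials(meshes, landmark_sets, groundtruth,
                               width_pair=("zyL", "zyR")):
    """Distance from each ground-truth label to its nearest generated
    landmark, averaged over surfaces, raw and width-normalized.

    ``groundtruth`` is a list (one dict per surface) of label -> 3D point.
    The width normalizer is the mean distance between the two
    ``width_pair`` labels.  Returns a dict label -> dict with keys
    ``mean, sd, mean_norm, sd_norm``.
    """
    import pandas as pd

    labels = set(groundtruth[0])
    for g in groundtruth:
        if set(g) != labels:
            raise ValueError("every surface must carry the same ground-truth labels")
    for lbl in width_pair:
        if lbl not in labels:
            raise ValueError(f"width label {lbl!r} missing from ground truth")
    widths = [np.linalg.norm(np.asarray(g[width_pair[0]]) - np.asarray(g[width_pair[1]]))
              for g in groundtruth]
    mean_width = float(np.mean(widths))
    rows = {}
    for lbl in sorted(labels):
        dists = []
        for mesh, lms, g in zip(meshes, landmark_sets, groundtruth):
            pts = np.array([p.position(mesh) for p in lms])
            dists.append(float(np.min(np.linalg.norm(pts - np.asarray(g[lbl]), axis=1))))
        dists = np.array(dists)
        rows[lbl] = {
            "mean": float(dists.mean()),
            "sd": float(dists.std(ddof=1)) if len(dists) > 1 else 0.0,
            "mean_norm": float(dists.mean() / mean_width),
            "sd_norm": (float(dists.std(ddof=1) / mean_width)
                        if len(dists) > 1 else 0.0),
        }
    return pd.DataFrame(rows).T
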