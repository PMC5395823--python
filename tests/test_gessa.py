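import math

import numpy as np
import pytest

from facemaps.gessa import (
    EnsembleState,
    correspondence_gradient,
    ensemble_cost,
    gessa_step,
    run_gessa,
    shape_entropy,
    split_landmarks,
    surface_density,
    uniformity_gradient,
    validate_against_fiducials,
)
from facemaps.mesh import SurfacePoint
from facemaps.synthetic import DEFAULT_FACE, make_face_mesh

from .conftest import grid_mesh, surface_point_at


@pytest.fixture(scope="module")
def kernel_plane():
    return grid_mesh(extent=2.0, n=9)


class TestSurfaceDensity:
    def test_two_points_at_sigma_separation(self, kernel_plane):
        sigma = 0.3
        a = surface_point_at(kernel_plane, 0.7, 1.0)
        b = surface_point_at(kernel_plane, 0.7 + sigma, 1.0)
        p = surface_density(kernel_plane, [a, b], 0, sigma)
        expected = math.exp(-0.5) / (2 * math.pi * sigma**2)
        assert abs(p - expected) < 1e-9 * expected

    def test_distant_neighbors_contribute_nothing(self, kernel_plane):
        sigma = 0.05
        a = surface_point_at(kernel_plane, 0.1, 0.1)
        b = surface_point_at(kernel_plane, 1.9, 1.9)  # >> 8 sigma away
        p = surface_density(kernel_plane, [a, b], 0, sigma)
        assert p < 1e-10 / (2 * math.pi * sigma**2)

    def test_coincident_pair(self, kernel_plane):
        sigma = 0.2
        a = surface_point_at(kernel_plane, 1.0, 1.0)
        p = surface_density(kernel_plane, [a, a], 0, sigma)
        assert abs(p - 1 / (2 * math.pi * sigma**2)) < 1e-12

    def test_single_landmark_rejected(self, kernel_plane):
        a = surface_point_at(kernel_plane, 1.0, 1.0)
        with pytest.raises(ValueError):
            surface_density(kernel_plane, [a], 0, 0.2)


class TestUniformityGradient:
    def test_two_landmarks_repel(self, kernel_plane):
        sigma = 0.3
        a = surface_point_at(kernel_plane, 0.7, 1.0)
        b = surface_point_at(kernel_plane, 1.1, 1.0)
        g = uniformity_gradient(kernel_plane, [a, b], 0, sigma)
        # g points toward the neighbor; the update direction -g repels
        d = g.vec / np.linalg.norm(g.vec)
        assert np.allclose(d, [1, 0, 0], atol=1e-9)

    def test_symmetric_ring_cancels(self, kernel_plane):
        sigma = 0.3
        c = surface_point_at(kernel_plane, 1.0, 1.0)
        ring = [surface_point_at(kernel_plane, 1.0 + 0.3 * np.cos(t),
                                 1.0 + 0.3 * np.sin(t))
                for t in np.linspace(0, 2 * np.pi, 7)[:-1]]
        g = uniformity_gradient(kernel_plane, [c] + ring, 0, sigma)
        assert np.linalg.norm(g.vec) < 1e-8 / sigma

    def test_matches_finite_difference_entropy_gradient(self, kernel_plane):
        """The analytic kernel gradient reproduces the FD gradient of the
        sampled entropy under the frozen-density approximation (only the
        p(x_i) term varies with x_i)."""
        sigma = 0.35
        rng = np.random.default_rng(11)
        coords = rng.uniform(0.5, 1.5, size=(6, 2))
        pts = [surface_point_at(kernel_plane, x, y) for x, y in coords]
        g = uniformity_gradient(kernel_plane, pts, 0, sigma)

        def log_p0(shift):
            moved = [surface_point_at(kernel_plane, coords[0, 0] + shift[0],
                                      coords[0, 1] + shift[1])] + pts[1:]
            return math.log(surface_density(kernel_plane, moved, 0, sigma))

        eps = 1e-5
        fd = np.array([
            (log_p0((eps, 0)) - log_p0((-eps, 0))) / (2 * eps),
            (log_p0((0, eps)) - log_p0((0, -eps))) / (2 * eps),
            0.0,
        ])
        # grad of log p at x_0 equals the kernel-weighted mean log-map / sigma^2
        assert np.linalg.norm(g.vec - fd) < 0.05 * np.linalg.norm(fd)


class TestShapeEntropy:
    def test_identical_vectors_floor(self):
        z = np.tile(np.arange(6.0), (3, 1))
        alpha = 0.25
        assert abs(shape_entropy(z, alpha) - 3.0 * math.log(alpha)) < 1e-12

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(4, 9))
        assert shape_entropy(z, 0.5) > shape_entropy(z, 0.1)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(3, 6))
        alpha = 0.37
        y = z - z.mean(axis=0)
        lam = np.clip(np.linalg.eigvalsh(y.T @ y / 2), 0, None)
        dense = 0.5 * np.log(lam + alpha).sum()
        assert abs(shape_entropy(z, alpha) - dense) < 1e-9


class TestCorrespondenceGradient:
    def test_identical_shapes_zero_gradient(self):
        z = np.tile(np.arange(6.0), (3, 1))
        g = correspondence_gradient(z, 0.1)
        assert np.abs(g).max() < 1e-12

    def test_projection_is_orthogonal_to_normals(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(3, 6))
        normals = rng.normal(size=(3, 2, 3))
        normals /= np.linalg.norm(normals, axis=2, keepdims=True)
        g = correspondence_gradient(z, 0.2, normals)
        dots = np.abs(np.sum(g * normals, axis=2))
        assert dots.max() < 1e-8

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(3, 6))
        alpha = 0.3
        g = correspondence_gradient(z, alpha).reshape(3, 6)
        eps = 1e-6
        fd = np.zeros_like(z)
        for j in range(3):
            for d in range(6):
                zp = z.copy(); zp[j, d] += eps
                zm = z.copy(); zm[j, d] -= eps
                fd[j, d] = (shape_entropy(zp, alpha) - shape_entropy(zm, alpha)) / (2 * eps)
        assert np.abs(g - fd).max() < 0.05 * np.abs(fd).max()


@pytest.fixture(scope="module")
def tiny_ensemble():
    meshes = [make_face_mesh(DEFAULT_FACE, subdivisions=2, seed=i) for i in range(3)]
    return meshes


class TestGessaStep:
    def test_identical_configuration_is_stationary(self, tiny_ensemble):
        mesh = tiny_ensemble[0]
        # one landmark per surface: no uniformity term, and with identical
        # copies the shape covariance is zero, so nothing moves at all
        single = [SurfacePoint(10, np.array([0.2, 0.3, 0.5]))]
        state = EnsembleState(meshes=[mesh] * 3, landmarks=[list(single)] * 3,
                              sigma=0.3, gamma=0.01, alpha=1e-3)
        new, _ = gessa_step(state, backtrack=False)
        for j in range(3):
            assert new.landmarks[j][0].face == single[0].face
            assert np.allclose(new.landmarks[j][0].bary, single[0].bary,
                               atol=1e-12)

    def test_identical_surfaces_stay_in_correspondence(self, tiny_ensemble):
        mesh = tiny_ensemble[0]
        lms = [SurfacePoint(10, np.array([0.2, 0.3, 0.5])),
               SurfacePoint(40, np.array([0.5, 0.25, 0.25]))]
        state = EnsembleState(meshes=[mesh] * 3, landmarks=[list(lms)] * 3,
                              sigma=0.3, gamma=0.01, alpha=1e-3)
        new, _ = gessa_step(state, backtrack=False)
        # the uniformity term moves points, but identically on every copy
        for j in range(1, 3):
            for i in range(2):
                assert new.landmarks[j][i].face == new.landmarks[0][i].face
                assert np.allclose(new.landmarks[j][i].bary,
                                   new.landmarks[0][i].bary, atol=1e-12)

    def test_single_surface_clustered_pair_separates(self, tiny_ensemble):
        mesh = tiny_ensemble[0]
        solver_sigma = 0.25
        a = SurfacePoint(10, np.array([0.4, 0.3, 0.3]))
        state = EnsembleState(meshes=[mesh], landmarks=[[a, a]],
                              sigma=solver_sigma, gamma=0.1 * solver_sigma**2,
                              alpha=1e-3)
        from facemaps.gessa import _mesh_solver

        d_before = 0.0
        new, _ = gessa_step(state, backtrack=False)
        solver = _mesh_solver(mesh)
        d_after = solver.distance(new.landmarks[0][0], new.landmarks[0][1])
        # coincident landmarks repel... a perfectly coincident pair has a
        # symmetric zero gradient, so start slightly offset instead
        b = SurfacePoint(10, np.array([0.38, 0.32, 0.30]))
        state = EnsembleState(meshes=[mesh], landmarks=[[a, b]],
                              sigma=solver_sigma, gamma=0.1 * solver_sigma**2,
                              alpha=1e-3)
        d_before = solver.distance(a, b)
        new, _ = gessa_step(state, backtrack=False)
        d_after = solver.distance(new.landmarks[0][0], new.landmarks[0][1])
        assert d_after > d_before

    def test_descent_with_backtracking(self, tiny_ensemble):
        rng = np.random.default_rng(9)
        landmarks = []
        for _ in tiny_ensemble:
            lms = []
            for _ in range(4):
                f = int(rng.integers(0, tiny_ensemble[0].n_faces))
                lms.append(SurfacePoint(f, rng.dirichlet([1, 1, 1])))
            landmarks.append(lms)
        sigma = 0.4
        state = EnsembleState(meshes=list(tiny_ensemble), landmarks=landmarks,
                              sigma=sigma, gamma=0.1 * sigma**2, alpha=1e-2)
        q_before = ensemble_cost(state)
        _, q_after = gessa_step(state, backtrack=True)
        assert q_after <= q_before + 1e-9 * max(abs(q_before), 1.0)


class TestSplitting:
    def test_counts_double_and_correspondence_kept(self, tiny_ensemble):
        rng = np.random.default_rng(10)
        landmarks = [[SurfacePoint(5, np.array([0.3, 0.3, 0.4]))]
                     for _ in tiny_ensemble]
        state = EnsembleState(meshes=list(tiny_ensemble), landmarks=landmarks,
                              sigma=0.3, gamma=0.01, alpha=1e-3)
        new = split_landmarks(state, epsilon=0.1, rng=rng)
        assert new.n_landmarks == 2
        for j in range(new.n_surfaces):
            parent = state.landmarks[j][0]
            assert new.landmarks[j][0].face == parent.face
            assert np.allclose(new.landmarks[j][0].bary, parent.bary)

    def test_offset_distance_is_epsilon_sigma(self, tiny_ensemble):
        from facemaps.gessa import _mesh_solver

        rng = np.random.default_rng(11)
        sigma = 0.3
        landmarks = [[SurfacePoint(5, np.array([0.3, 0.3, 0.4]))]
                     for _ in tiny_ensemble]
        state = EnsembleState(meshes=list(tiny_ensemble), landmarks=landmarks,
                              sigma=sigma, gamma=0.01, alpha=1e-3)
        new = split_landmarks(state, epsilon=0.1, rng=rng)
        for j, mesh in enumerate(tiny_ensemble):
            d = _mesh_solver(mesh).distance(new.landmarks[j][0], new.landmarks[j][1])
            assert abs(d - 0.1 * sigma) < 0.02 * sigma


class TestRunGessa:
    def test_non_power_of_two_rejected(self, tiny_ensemble):
        with pytest.raises(ValueError, match="power of two"):
            run_gessa(list(tiny_ensemble), 12, seed=0)

    def test_single_mesh_rejected(self, tiny_ensemble):
        with pytest.raises(ValueError, match="at least 2"):
            run_gessa([tiny_ensemble[0]], 4, seed=0)

    def test_deterministic_under_fixed_seed(self, tiny_ensemble):
        kw = dict(iters_per_level=2, seed=7, steiner_per_edge=2)
        lms1, _ = run_gessa(list(tiny_ensemble), 8, **kw)
        lms2, _ = run_gessa(list(tiny_ensemble), 8, **kw)
        for l1, l2 in zip(lms1, lms2):
            for p1, p2 in zip(l1, l2):
                assert p1.face == p2.face
                assert np.array_equal(p1.bary, p2.bary)

    def test_reaches_target_count_with_level_log(self, tiny_ensemble):
        lms, log = run_gessa(list(tiny_ensemble), 8, iters_per_level=1, seed=3,
                             steiner_per_edge=2)
        assert all(len(l) == 8 for l in lms)
        assert [entry["M"] for entry in log] == [1, 2, 4, 8]


class TestValidation:
    def test_perfect_landmarks_give_zero_error(self, tiny_ensemble):
        lms, _ = run_gessa(list(tiny_ensemble), 4, iters_per_level=1, seed=5,
                           steiner_per_edge=2)
        gts = []
        for mesh, lset in zip(tiny_ensemble, lms):
            gts.append({
                "zyL": lset[0].position(mesh),
                "zyR": lset[1].position(mesh),
                "prn": lset[2].position(mesh),
            })
        report = validate_against_fiducials(list(tiny_ensemble), lms, gts)
        assert float(report["mean"].max()) == 0.0
        assert float(report["sd"].max()) == 0.0

    def test_normalized_metrics_scale_invariant(self, tiny_ensemble):
        lms, _ = run_gessa(list(tiny_ensemble), 4, iters_per_level=1, seed=5,
                           steiner_per_edge=2)
        rng = np.random.default_rng(0)
        gts = []
        for mesh in tiny_ensemble:
            gts.append({lbl: rng.normal(size=3) * 0.5
                        for lbl in ("zyL", "zyR", "prn")})
        r1 = validate_against_fiducials(list(tiny_ensemble), lms, gts)
        from facemaps.mesh import TriangleMesh

        scaled_meshes = [TriangleMesh(m.vertices * 2.0, m.faces.copy())
                         for m in tiny_ensemble]
        gts2 = [{k: np.asarray(v) * 2.0 for k, v in g.items()} for g in gts]
        r2 = validate_against_fiducials(scaled_meshes, lms, gts2)
        assert np.allclose(r1["mean_norm"], r2["mean_norm"], rtol=1e-9)
        assert np.allclose(r1["sd_norm"], r2["sd_norm"], rtol=1e-9)
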