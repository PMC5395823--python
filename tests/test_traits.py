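import numpy as np
import pandas as pd
import pytest

from facemaps.mesh import SurfacePoint, TriangleMesh
from facemaps.traits import (
    DEFAULT_TRAIT_PAIRS,
    FIDUCIAL_LABELS,
    RegionalTrait,
    distance_traits,
    eigenface_map,
    pick_fiducials,
    regress_out_age,
    sparse_pca,
)

from .conftest import grid_mesh


class TestPickFiducials:
    def test_exact_pick_returns_that_landmark(self):
        rng = np.random.default_rng(0)
        avg = rng.normal(size=(20, 3))
        fm = pick_fiducials(avg, {"prn": avg[7]})
        assert fm["prn"] == 7

    def test_equidistant_tie_breaks_to_lowest_index(self):
        avg = np.array([[0, 0, 0], [2, 0, 0], [1, 5, 0]], dtype=float)
        fm = pick_fiducials(avg, {"g": [1.0, 0.0, 0.0]})
        assert fm["g"] == 0

    def test_seventeen_labels(self):
        rng = np.random.default_rng(1)
        avg = rng.normal(size=(64, 3))
        picks = {lbl: avg[i] for i, lbl in enumerate(FIDUCIAL_LABELS)}
        fm = pick_fiducials(avg, picks)
        assert len(fm) == 17

    def test_duplicate_assignment_warns(self):
        avg = np.array([[0, 0, 0], [5, 5, 5]], dtype=float)
        with pytest.warns(UserWarning, match="share"):
            pick_fiducials(avg, {"a": [0.1, 0, 0], "b": [0, 0.1, 0]})


@pytest.fixture(scope="module")
def flat_cohort():
    """Three flat-grid subjects with landmarks at all 17 fiducials."""
    rng = np.random.default_rng(2)
    meshes = [grid_mesh(extent=2.0, n=9) for _ in range(3)]
    lms = []
    from .conftest import random_surface_point

    for mesh in meshes:
        lms.append([random_surface_point(mesh, rng) for _ in range(17)])
    avg = np.mean([[p.position(m) for p in l] for m, l in zip(meshes, lms)],
                  axis=0)
    fid = pick_fiducials(avg, {lbl: avg[i] for i, lbl in enumerate(FIDUCIAL_LABELS)})
    return meshes, lms, fid


class TestDistanceTraits:
    def test_default_pairs_yield_ten_traits(self, flat_cohort):
        meshes, lms, fid = flat_cohort
        mat = distance_traits(meshes, lms, fid, mode="euclidean")
        assert mat.shape == (3, 10)
        assert list(mat.columns) == [f"{a}-{b}" for a, b in DEFAULT_TRAIT_PAIRS]

    def test_flat_surface_euclidean_equals_geodesic(self, flat_cohort):
        meshes, lms, fid = flat_cohort
        edt = distance_traits(meshes, lms, fid, mode="euclidean")
        gdt = distance_traits(meshes, lms, fid, mode="geodesic")
        assert np.allclose(edt.to_numpy(), gdt.to_numpy(), atol=1e-6)

    def test_chord_bound_on_curved_surface(self):
        from facemaps.synthetic import DEFAULT_FACE, make_face_mesh
        from .conftest import random_surface_point

        rng = np.random.default_rng(3)
        meshes = [make_face_mesh(DEFAULT_FACE, subdivisions=2, seed=i)
                  for i in range(2)]
        lms = [[random_surface_point(m, rng) for _ in range(17)] for m in meshes]
        avg = np.mean([[p.position(m) for p in l] for m, l in zip(meshes, lms)],
                      axis=0)
        fid = pick_fiducials(avg, {lbl: avg[i]
                                   for i, lbl in enumerate(FIDUCIAL_LABELS)})
        edt = distance_traits(meshes, lms, fid, mode="euclidean")
        gdt = distance_traits(meshes, lms, fid, mode="geodesic")
        assert np.all(edt.to_numpy() <= gdt.to_numpy() + 1e-9)

    def test_rigid_invariance_and_scale_equivariance(self, flat_cohort):
        meshes, lms, fid = flat_cohort
        base = distance_traits(meshes, lms, fid, mode="euclidean")
        t = np.radians(25)
        R = np.array([[np.cos(t), -np.sin(t), 0],
                      [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
        moved = [m.transformed(R, np.array([3.0, -1.0, 2.0])) for m in meshes]
        assert np.allclose(
            distance_traits(moved, lms, fid, mode="euclidean").to_numpy(),
            base.to_numpy(), atol=1e-9)
        scaled = [TriangleMesh(m.vertices * 3.0, m.faces.copy()) for m in meshes]
        assert np.allclose(
            distance_traits(scaled, lms, fid, mode="euclidean").to_numpy(),
            base.to_numpy() * 3.0, atol=1e-9)

    def test_missing_label_rejected(self, flat_cohort):
        meshes, lms, _ = flat_cohort
        from facemaps.traits import FiducialMap

        small = FiducialMap({"g": 0})
        with pytest.raises(ValueError, match="not in the map"):
            distance_traits(meshes, lms, small)


class TestRegressOutAge:
    def test_residuals_uncorrelated_with_age(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(40, 70, 50)
        traits = np.c_[2 * ages + rng.normal(size=50), rng.normal(size=50)]
        resid = regress_out_age(traits, ages)
        r = np.corrcoef(resid.iloc[:, 0], ages)[0, 1]
        assert abs(r) < 1e-9

    def test_age_independent_trait_is_centered(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(40, 70, 50)
        trait = np.full(50, 3.5)
        resid = regress_out_age(trait[:, None], ages)
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-12)

    def test_matches_closed_form_ols(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 6.0])
        D = np.c_[np.ones(4), ages]
        expected = y - D @ np.linalg.solve(D.T @ D, D.T @ y)
        got = regress_out_age(y[:, None], ages).to_numpy().ravel()
        assert np.allclose(got, expected, atol=1e-12)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_out_age(np.ones((4, 1)), np.full(4, 50.0))


class TestSparsePCA:
    def _data(self, seed=0, n=40, m=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, m))
        return X - X.mean(axis=0)

    def test_max_bound_recovers_dense_pca(self):
        X = self._data()
        comp = sparse_pca(X, 1, np.sqrt(X.shape[1]))[0]
        _, _, vt = np.linalg.svd(X)
        assert abs(comp.loadings @ vt[0]) > 0.999

    def test_unit_bound_gives_single_nonzero(self):
        X = self._data()
        comp = sparse_pca(X, 1, 1.0)[0]
        assert comp.n_nonzero == 1

    def test_cumulative_variance_reaches_one(self):
        X = self._data(n=30, m=8)
        comps = sparse_pca(X, 8, np.sqrt(8))
        evs = [c.explained_variance for c in comps]
        assert all(ev >= -1e-12 for ev in evs)
        assert abs(sum(evs) - 1.0) < 1e-6

    def test_sparsity_monotone_in_bound(self):
        X = self._data()
        bounds = [np.sqrt(12), 2.5, 1.8, 1.2, 1.0]
        nnz = [sparse_pca(X, 1, b)[0].n_nonzero for b in bounds]
        assert all(a >= b for a, b in zip(nnz[:-1], nnz[1:]))

    def test_out_of_range_bound_rejected(self):
        X = self._data()
        with pytest.raises(ValueError, match="sparsity bound"):
            sparse_pca(X, 1, 0.5)
        with pytest.raises(ValueError, match="sparsity bound"):
            sparse_pca(X, 1, 10.0)


class TestEigenfaceMap:
    def test_single_nonzero_loading_lights_one_landmark(self):
        w = np.zeros(10)
        w[3] = 1.0
        trait = RegionalTrait(loadings=w, scores=np.zeros(5),
                              explained_variance=0.5)
        mags = eigenface_map(trait, np.random.default_rng(0).normal(size=(10, 3)))
        assert np.count_nonzero(mags) == 1 and mags[3] == 1.0

    def test_sign_flip_leaves_map_unchanged(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=10)
        w /= np.linalg.norm(w)
        avg = rng.normal(size=(10, 3))
        t1 = RegionalTrait(loadings=w, scores=np.zeros(5), explained_variance=0.5)
        t2 = RegionalTrait(loadings=-w, scores=np.zeros(5), explained_variance=0.5)
        assert np.allclose(eigenface_map(t1, avg), eigenface_map(t2, avg))

    def test_planted_cluster_concentrates_loadings(self):
        """Correlated block of landmarks (a planted region) dominates the
        first sparse component."""
        rng = np.random.default_rng(7)
        n, m = 200, 20
        shared = rng.normal(size=(n, 1))
        X = rng.normal(size=(n, m)) * 0.3
        X[:, :5] += shared  # planted cluster on landmarks 0..4
        X = X - X.mean(axis=0)
        comp = sparse_pca(X, 1, 2.0)[0]
        avg = rng.normal(size=(m, 3))
        mags = eigenface_map(comp, avg)
        inside = mags[:5].sum()
        outside = mags[5:].sum()
        assert inside > 5 * outside

    def test_length_mismatch_rejected(self):
        w = np.zeros(10)
        w[0] = 1.0
        trait = RegionalTrait(loadings=w, scores=np.zeros(5),
                              explained_variance=0.1)
        with pytest.raises(ValueError, match="align"):
            eigenface_map(trait, np.zeros((8, 3)))
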