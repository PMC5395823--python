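import numpy as np
import pandas as pd
import pytest

from facemaps.heritability import (
    TwinPairData,
    TwinSEM,
    TwinSEMResults,
    ae_vs_e_test,
    goodness_of_fit,
    heritability_map,
    mass_univariate,
    select_model,
)
from facemaps.synthetic import simulate_twin_traits


class TestTwinPairData:
    def test_invalid_zygosity_names_row_and_column(self):
        df = simulate_twin_traits(3, 3, 0.5, 0.0, 0.5, seed=0)
        df.loc[2, "zygosity"] = "XZ"
        with pytest.raises(ValueError, match=r"row 2.*zygosity.*'XZ'"):
            TwinPairData(df)

    def test_duplicate_pair_ids_rejected(self):
        df = simulate_twin_traits(3, 3, 0.5, 0.0, 0.5, seed=0)
        df.loc[1, "pair_id"] = 0
        with pytest.raises(ValueError, match="unique"):
            TwinPairData(df)

    def test_nonfinite_values_rejected(self):
        df = simulate_twin_traits(3, 3, 0.5, 0.0, 0.5, seed=0)
        df.loc[0, "value_twin1"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            TwinPairData(df)


class TestResultsObject:
    def test_h2_formula_and_aic(self):
        res = TwinSEMResults(model="AE", params={"a": 1.0, "e": 1.0, "mu": 0.0},
                             llf=-100.0, n_params=3, nobs_pairs=50,
                             use_age=False)
        assert res.h2 == pytest.approx(0.5)
        assert res.aic == pytest.approx(-2 * -100.0 + 2 * 3)

    def test_summary_mentions_model_and_h2(self):
        df = simulate_twin_traits(50, 50, 0.5, 0.0, 0.5, seed=1)
        res = TwinSEM(df, "AE").fit()
        text = res.summary()
        assert "AE" in text and "h2" in text and "AIC" in text


class TestStructuredFits:
    def test_e_model_matches_closed_form(self):
        df = simulate_twin_traits(100, 100, 0.0, 0.0, 1.0, seed=2)
        fit = TwinSEM(df, "E").fit(compute_se=False)
        x = np.concatenate([df.value_twin1, df.value_twin2])
        v = x.var()
        ll = -0.5 * len(x) * (np.log(2 * np.pi * v) + 1)
        assert fit.llf == pytest.approx(ll, abs=1e-6)

    def test_parameter_recovery_large_sample(self):
        df = simulate_twin_traits(5000, 5000, 0.7, 0.0, 0.3, seed=3)
        fit = TwinSEM(df, "AE").fit(compute_se=False)
        assert abs(fit.h2 - 0.7) < 0.03

    def test_loglik_nesting(self):
        df = simulate_twin_traits(300, 300, 0.5, 0.1, 0.4, seed=4)
        data = TwinPairData(df)
        ll = {m: TwinSEM(data, m).fit(compute_se=False).llf
              for m in ("SAT", "ACE", "AE", "E")}
        tol = 1e-6 * abs(ll["SAT"])
        assert ll["SAT"] >= ll["ACE"] - tol
        assert ll["ACE"] >= ll["AE"] - tol
        assert ll["AE"] >= ll["E"] - tol

    def test_h2_invariant_to_affine_trait_rescaling(self):
        df = simulate_twin_traits(200, 200, 0.6, 0.0, 0.4, seed=5)
        h_raw = TwinSEM(df, "AE").fit(compute_se=False).h2
        df2 = df.copy()
        for col in ("value_twin1", "value_twin2"):
            df2[col] = df2[col] * 3.7 + 11.0
        h_scaled = TwinSEM(df2, "AE").fit(compute_se=False).h2
        assert abs(h_raw - h_scaled) < 1e-6

    def test_age_slope_recovered(self):
        df = simulate_twin_traits(500, 500, 0.5, 0.0, 0.5, age_beta=0.05, seed=6)
        fit = TwinSEM(df, "AE", use_age=True).fit(compute_se=False)
        assert fit.params["beta_age"] == pytest.approx(0.05, abs=0.01)

    def test_standard_errors_finite_in_interior(self):
        df = simulate_twin_traits(500, 500, 0.5, 0.0, 0.5, seed=7)
        fit = TwinSEM(df, "AE").fit()
        assert np.isfinite(fit.bse["a"]) and fit.bse["a"] > 0
        assert np.isfinite(fit.h2_se) and fit.h2_se > 0

    def test_too_few_pairs_rejected(self):
        df = simulate_twin_traits(2, 1, 0.5, 0.0, 0.5, seed=8)
        with pytest.raises(ValueError, match="at least 2"):
            TwinSEM(df, "AE")


class TestSaturatedModel:
    def test_parameter_count(self):
        df = simulate_twin_traits(50, 50, 0.5, 0.0, 0.5, seed=9)
        assert TwinSEM(df, "SAT").fit(compute_se=False).n_params == 10
        assert TwinSEM(df, "SAT", use_age=True).fit(compute_se=False).n_params == 11

    def test_moment_matched_data_lets_ace_attain_saturated(self):
        """When both zygosity groups share identical exchangeable moments,
        the ACE structure reproduces the saturated fit exactly."""
        rng = np.random.default_rng(10)
        base = rng.normal(size=(40, 2))
        sym = np.vstack([base, base[:, ::-1]])  # exchangeable by construction
        vals = np.vstack([sym, sym])            # identical for MZ and DZ
        n = len(sym)
        df = pd.DataFrame({
            "pair_id": np.arange(2 * n),
            "zygosity": ["MZ"] * n + ["DZ"] * n,
            "value_twin1": vals[:, 0],
            "value_twin2": vals[:, 1],
        })
        # exchangeable + equal across zygosity -> cov_mz = cov_dz, met by a=0
        ace = TwinSEM(df, "ACE").fit(n_starts=6, compute_se=False)
        sat = TwinSEM(df, "SAT").fit(compute_se=False)
        assert ace.llf == pytest.approx(sat.llf, abs=1e-4)


class TestGoodnessOfFit:
    def test_saturated_vs_itself(self):
        df = simulate_twin_traits(50, 50, 0.5, 0.0, 0.5, seed=11)
        sat = TwinSEM(df, "SAT").fit(compute_se=False)
        stat, dfree, p = goodness_of_fit(sat, sat)
        assert stat == 0.0 and p == 1.0

    def test_statistic_nonnegative(self):
        for seed in range(5):
            df = simulate_twin_traits(80, 80, 0.4, 0.1, 0.5, seed=seed)
            sel = select_model(df, compute_se=False)
            assert sel.gof_stat >= 0.0

    def test_calibration_under_true_ae(self):
        """Under a true AE model the gof test should pass (p > 0.05) about
        95% of the time (small replicate count; the full-scale calibration
        runs in the acceptance suite)."""
        passed = 0
        n = 60
        for s in range(n):
            df = simulate_twin_traits(200, 200, 0.5, 0.0, 0.5, seed=2000 + s)
            fae = TwinSEM(df, "AE").fit(n_starts=2, compute_se=False)
            fsat = TwinSEM(df, "SAT").fit(compute_se=False)
            _, _, p = goodness_of_fit(fae, fsat)
            passed += p > 0.05
        assert passed / n > 0.85


class TestModelSelection:
    def test_winner_is_structured(self):
        df = simulate_twin_traits(100, 100, 0.6, 0.0, 0.4, seed=12)
        sel = select_model(df, compute_se=False)
        assert sel.best.model in ("ACE", "AE", "E")

    def test_ae_truth_mostly_selects_ae(self):
        wins = 0
        n = 30
        for s in range(n):
            df = simulate_twin_traits(300, 300, 0.6, 0.0, 0.4, seed=3000 + s)
            sel = select_model(df, n_starts=2, compute_se=False)
            wins += sel.best.model == "AE"
        assert wins / n > 0.7

    def test_null_data_prefers_e_within_two_aic(self):
        """With h2 = 0 the AE model adds one noise parameter; its AIC should
        not beat E by more than the 2-unit parameter penalty on average."""
        deltas = []
        for s in range(30):
            df = simulate_twin_traits(200, 200, 0.0, 0.0, 1.0, seed=4000 + s)
            fits = select_model(df, n_starts=2, compute_se=False).fits
            deltas.append(fits["E"].aic - fits["AE"].aic)
        assert np.mean(deltas) < 2.0


class TestZeroHeritabilityTest:
    def test_boundary_p_value_halved(self):
        df = simulate_twin_traits(100, 100, 0.5, 0.0, 0.5, seed=13)
        stat, p_b, p_naive, _, _ = ae_vs_e_test(df)
        assert stat > 0
        assert p_b == pytest.approx(0.5 * p_naive)

    def test_null_statistic_gives_p_one(self):
        # engineered negative-correlation data drives a-hat to the boundary
        rng = np.random.default_rng(14)
        x = rng.normal(size=(200, 2))
        x[:, 1] = -0.5 * x[:, 0] + rng.normal(size=200)
        df = pd.DataFrame({
            "pair_id": np.arange(200),
            "zygosity": ["MZ"] * 100 + ["DZ"] * 100,
            "value_twin1": x[:, 0],
            "value_twin2": x[:, 1],
        })
        stat, p_b, _, fit_ae, _ = ae_vs_e_test(df)
        assert stat <= 1e-6
        assert p_b == 1.0


class TestMassUnivariate:
    def _cohort(self, seed=15):
        df = simulate_twin_traits(60, 60, 0.6, 0.0, 0.4, seed=seed)
        subjects = []
        values = []
        for r in df.itertuples():
            subjects += [f"s{r.pair_id}_1", f"s{r.pair_id}_2"]
            values += [r.value_twin1, r.value_twin2]
        mat = pd.DataFrame({"t1": values, "t2": values}, index=subjects)
        pairs = pd.DataFrame({
            "pair_id": df.pair_id,
            "zygosity": df.zygosity,
            "subject1": [f"s{p}_1" for p in df.pair_id],
            "subject2": [f"s{p}_2" for p in df.pair_id],
        })
        return mat, pairs

    def test_identical_traits_identical_rows(self):
        mat, pairs = self._cohort()
        res = mass_univariate(mat, pairs)
        assert len(res) == 2
        assert res.loc[0, "h2"] == pytest.approx(res.loc[1, "h2"])
        assert res.loc[0, "model"] == res.loc[1, "model"]

    def test_row_count_matches_trait_count(self):
        mat, pairs = self._cohort()
        wide = pd.concat([mat] * 3, axis=1)
        wide.columns = [f"c{i}" for i in range(6)]
        res = mass_univariate(wide, pairs)
        assert len(res) == 6

    def test_unknown_subject_rejected(self):
        mat, pairs = self._cohort()
        pairs.loc[0, "subject1"] = "ghost"
        with pytest.raises(ValueError, match="unknown subjects"):
            mass_univariate(mat, pairs)


class TestHeritabilityMap:
    def test_out_of_range_h2_rejected(self):
        from .conftest import grid_mesh

        mesh = grid_mesh(n=4)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            heritability_map([1.5], mesh, [[0, 0, 0]])

    def test_vertex_scalars_follow_nearest_landmark(self, tmp_path):
        from .conftest import grid_mesh

        mesh = grid_mesh(extent=2.0, n=5)
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 0.0]])
        h2 = np.array([0.0, 1.0])
        scalars = heritability_map(h2, mesh, pos, path=tmp_path / "map.ply",
                                   csv_path=tmp_path / "map.csv")
        assert scalars[0] == 0.0                      # corner near landmark 0
        assert scalars[-1] == 1.0                     # corner near landmark 1
        assert (tmp_path / "map.ply").exists()
        assert len(pd.read_csv(tmp_path / "map.csv")) == 2

    def test_gof_mask_hides_failing_landmarks(self):
        from .conftest import grid_mesh

        mesh = grid_mesh(extent=2.0, n=5)
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 0.0]])
        scalars = heritability_map([0.8, 0.9], mesh, pos,
                                   gof_p=[0.01, 0.5], mask_failing=True)
        assert np.isnan(scalars[0])
        assert scalars[-1] == 0.9
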