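"""Group-level inference: ANCOVA, MANOVA, TFCE, permutation tests, power."""

import numpy as np
import pandas as pd
import pytest

from rewardrs.permutation import one_sample_perm_test, permutation_group_test
from rewardrs.stats import (AncovaResult, PowerQuery, ancova_group,
                            f_test_power, leave_one_roi_out_manova,
                            solve_detectable_f)
from rewardrs.tfce import TfceParams, tfce


class TestAncova:
    def test_identical_groups_give_near_zero_f(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        g = ["AN"] * 4 + ["CON"] * 4
        c = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        res = ancova_group(y, g, c)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 8)
        g = np.array(["AN"] * 4 + ["CON"] * 4)
        c = rng.normal(10, 2, 8)
        res = ancova_group(y, g, c)
        # explicit matrix-algebra oracle
        X = np.column_stack([np.ones(8), (g == "CON").astype(float), c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss_full = np.sum((y - X @ beta) ** 2)
        Xr = X[:, [0, 2]]
        br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
        rss_red = np.sum((y - Xr @ br) ** 2)
        F_oracle = (rss_red - rss_full) / (rss_full / 5)
        assert res.F == pytest.approx(F_oracle)
        assert res.eta_sq == pytest.approx(
            (rss_red - rss_full) / np.sum((y - y.mean()) ** 2))

    def test_f_equals_squared_t_statistic(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(0, 1, 20),
                           "g": ["AN"] * 10 + ["CON"] * 10,
                           "c": rng.normal(14, 3, 20)})
        res = ancova_group(df["y"], df["g"], df["c"])
        fit = smf.ols("y ~ C(g) + c", df).fit()
        assert res.F == pytest.approx(float(fit.tvalues.iloc[1]) ** 2)
        assert res.p == pytest.approx(float(fit.pvalues.iloc[1]))

    def test_covariate_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 16)
        g = ["AN"] * 8 + ["CON"] * 8
        c = rng.normal(10, 2, 16)
        a = ancova_group(y, g, c)
        b = ancova_group(y, g, 5.0 * c - 3.0)
        assert a.F == pytest.approx(b.F)

    def test_collinear_covariate_raises(self):
        g = ["AN"] * 4 + ["CON"] * 4
        c = np.array([1.0] * 4 + [2.0] * 4)  # duplicates the indicator
        with pytest.raises(ValueError, match="collinear"):
            ancova_group(np.arange(8.0), g, c)

    def test_group_effect_detected_when_simulated(self):
        # cohort-level power check at the summary level: a reliability
        # gap between groups must be flagged in most replicates
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            an = rng.normal(0.12, 0.05, 25)
            con = rng.normal(0.20, 0.05, 22)
            y = np.concatenate([an, con])
            g = ["AN"] * 25 + ["CON"] * 22
            c = np.concatenate([rng.normal(14, 4, 25),
                                rng.normal(18, 1.5, 22)])
            if ancova_group(y, g, c).p < 0.05:
                hits += 1
        assert hits >= 15

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0.15, 0.05, 47)
            g = ["AN"] * 25 + ["CON"] * 22
            c = rng.normal(16, 3, 47)
            if ancova_group(y, g, c).p < 0.05:
                hits += 1
        # binomial 99% envelope around 0.05 for 200 draws
        assert 0.01 <= hits / n_rep <= 0.10


class TestManova:
    def test_identical_distributions_give_lambda_one(self):
        # both groups hold byte-identical data and covariates: the group
        # indicator explains nothing, so H = 0 and Lambda = 1
        rng = np.random.default_rng(20)
        half = rng.normal(0, 1, (6, 3))
        Y = pd.DataFrame(np.vstack([half, half]), columns=["a", "b", "c"])
        g = ["AN"] * 6 + ["CON"] * 6
        c = np.tile(rng.normal(14, 2, 6), 2)
        res = leave_one_roi_out_manova(Y, g, c)
        for r in res:
            assert r.wilks_lambda == pytest.approx(1.0, abs=1e-10)
            assert r.F == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_wilks(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(5)
        n = 24
        g = np.array(["AN"] * 12 + ["CON"] * 12)
        c = rng.normal(14, 3, n)
        Y = rng.normal(0, 1, (n, 3)) + (g == "CON")[:, None] * 0.7
        roi = pd.DataFrame(Y, columns=["r1", "r2", "r3"])
        res = leave_one_roi_out_manova(roi, g, c)
        for r in res:
            kept = [col for col in roi.columns if col != r.omitted_roi]
            df = roi[kept].assign(g=g, c=c)
            mv = MANOVA.from_formula(f"{kept[0]} + {kept[1]} ~ C(g) + c",
                                     data=df).mv_test()
            tab = mv.results["C(g)"]["stat"]
            assert r.wilks_lambda == pytest.approx(
                float(tab.loc["Wilks' lambda", "Value"]), abs=1e-10)
            assert r.p == pytest.approx(
                float(tab.loc["Wilks' lambda", "Pr > F"]), abs=1e-10)

    def test_single_retained_roi_reduces_to_ancova(self):
        rng = np.random.default_rng(6)
        n = 20
        g = np.array(["AN"] * 10 + ["CON"] * 10)
        c = rng.normal(14, 3, n)
        roi = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        res = leave_one_roi_out_manova(roi, g, c)
        for r in res:
            kept = "b" if r.omitted_roi == "a" else "a"
            uni = ancova_group(roi[kept], g, c)
            assert r.F == pytest.approx(uni.F)
            assert r.p == pytest.approx(uni.p)


class TestTfce:
    def test_zero_map_stays_zero(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        assert np.all(tfce(np.zeros((5, 5, 5)), mask) == 0)

    def test_single_voxel_discrete_integral(self):
        m = np.zeros((7, 7, 7))
        m[3, 3, 3] = 2.0
        out = tfce(m, np.ones((7, 7, 7), dtype=bool), TfceParams())
        dh = 2.0 / 100
        oracle = sum((1 ** 0.5) * (k * dh) ** 2 * dh for k in range(1, 101))
        assert out[3, 3, 3] == pytest.approx(oracle)
        # close to the continuous-integral limit h^3/3
        assert out[3, 3, 3] == pytest.approx(2.0 ** 3 / 3, rel=0.05)

    def test_uniform_blob_closed_form(self):
        m = np.zeros((8, 8, 8))
        m[2:5, 2:5, 2:5] = 1.5  # 27-voxel cube, all at height 1.5
        mask = np.ones((8, 8, 8), dtype=bool)
        params = TfceParams()
        out = tfce(m, mask, params)
        dh = 1.5 / 100
        oracle = (27 ** 0.5) * sum((k * dh) ** 2 * dh for k in range(1, 101))
        assert np.allclose(out[2:5, 2:5, 2:5], oracle)

    def test_negative_values_enhanced_separately(self):
        m = np.zeros((7, 7, 7))
        m[1, 1, 1] = 2.0
        m[5, 5, 5] = -2.0
        out = tfce(m, np.ones((7, 7, 7), dtype=bool),
                   TfceParams(dh=0.02))
        assert out[1, 1, 1] > 0
        assert out[5, 5, 5] == pytest.approx(-out[1, 1, 1])

    def test_monotonicity_in_input(self):
        rng = np.random.default_rng(7)
        mask = np.ones((6, 6, 6), dtype=bool)
        a = np.abs(rng.normal(0, 1, (6, 6, 6)))
        b = a + np.abs(rng.normal(0, 0.5, (6, 6, 6)))
        params = TfceParams(dh=0.05)
        assert np.all(tfce(b, mask, params) - tfce(a, mask, params) >= -1e-12)

    def test_height_power_scaling_single_voxel(self):
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 1.0
        mask = np.ones((5, 5, 5), dtype=bool)
        out1 = tfce(m, mask, TfceParams())[2, 2, 2]
        out2 = tfce(3.0 * m, mask, TfceParams())[2, 2, 2]
        # with dh scaling with the max, output scales as c^(H+1)
        assert out2 / out1 == pytest.approx(3.0 ** 3, rel=1e-6)


def _null_maps(rng, n, shape):
    return [rng.normal(0, 1, shape) for _ in range(n)]


class TestPermutation:
    def test_degenerate_identical_maps_give_fwe_one_everywhere(self):
        # every subject carries the same map: the group contrast is
        # exactly zero, the null is degenerate, and no voxel can reach
        # significance
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (5, 5, 5))
        maps = [base.copy() for _ in range(6)]
        mask = np.ones((5, 5, 5), dtype=bool)
        g = ["A", "B"] * 3
        res = permutation_group_test(maps, g, rng.normal(0, 1, 6), mask,
                                     n_perm=100, seed=0,
                                     tfce_params=TfceParams(n_steps=20))
        assert np.all(res.fwe_p_map[mask] == 1.0)

    def test_fwe_floor_respected(self):
        rng = np.random.default_rng(9)
        mask = np.ones((4, 4, 4), dtype=bool)
        maps = [rng.normal(0, 1, (4, 4, 4)) + 5.0 for _ in range(8)]
        res = one_sample_perm_test(maps, rng.normal(0, 1, 8), mask,
                                   n_perm=200, seed=1,
                                   tfce_params=TfceParams(n_steps=20))
        assert res.fwe_p_map[mask].min() >= 1 / 201

    def test_strong_effect_detected_one_sample(self):
        rng = np.random.default_rng(10)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        effect = np.zeros((6, 6, 6))
        effect[2:4, 2:4, 2:4] = 1.5
        maps = [effect + rng.normal(0, 0.5, (6, 6, 6)) for _ in range(12)]
        res = one_sample_perm_test(maps, rng.normal(0, 1, 12), mask,
                                   n_perm=300, seed=2,
                                   tfce_params=TfceParams(n_steps=30))
        assert res.significant(0.05)[2:4, 2:4, 2:4].any()

    def test_group_difference_detected(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        effect = np.zeros((6, 6, 6))
        effect[2:4, 2:4, 2:4] = 1.2
        maps = ([effect + rng.normal(0, 0.4, (6, 6, 6)) for _ in range(10)]
                + [rng.normal(0, 0.4, (6, 6, 6)) for _ in range(10)])
        g = ["A"] * 10 + ["B"] * 10
        res = permutation_group_test(maps, g, rng.normal(0, 1, 20), mask,
                                     n_perm=300, seed=3,
                                     tfce_params=TfceParams(n_steps=30))
        assert res.significant(0.05)[2:4, 2:4, 2:4].any()

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(12)
        mask = np.ones((4, 4, 4), dtype=bool)
        maps = _null_maps(rng, 10, (4, 4, 4))
        g = ["A"] * 5 + ["B"] * 5
        cov = rng.normal(0, 1, 10)
        a = permutation_group_test(maps, g, cov, mask, 100, seed=7,
                                   tfce_params=TfceParams(n_steps=10))
        b = permutation_group_test(maps, g, cov, mask, 100, seed=7,
                                   tfce_params=TfceParams(n_steps=10))
        assert np.array_equal(a.fwe_p_map, b.fwe_p_map)

    def test_cluster_table_reports_significant_blob(self):
        from rewardrs.permutation import cluster_table

        rng = np.random.default_rng(14)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        effect = np.zeros((6, 6, 6))
        effect[2:4, 2:4, 2:4] = 1.5
        maps = [effect + rng.normal(0, 0.4, (6, 6, 6)) for _ in range(12)]
        res = one_sample_perm_test(maps, rng.normal(0, 1, 12), mask,
                                   n_perm=300, seed=4,
                                   tfce_params=TfceParams(n_steps=30))
        table = cluster_table(res, 0.05)
        assert len(table) >= 1
        top = table.iloc[0]
        assert top["size_voxels"] >= 1
        assert 2 <= top["peak_x"] <= 3
        assert top["fwe_p_min"] <= 0.05

    def test_too_many_permutations_warns(self, caplog):
        rng = np.random.default_rng(13)
        mask = np.ones((3, 3, 3), dtype=bool)
        maps = _null_maps(rng, 6, (3, 3, 3))
        with caplog.at_level("WARNING"):
            permutation_group_test(maps, ["A"] * 3 + ["B"] * 3,
                                   rng.normal(0, 1, 6), mask, 100, seed=0,
                                   tfce_params=TfceParams(n_steps=5))
        assert "distinct" in caplog.text


class TestPower:
    def test_study_design_detectable_effect(self):
        f = solve_detectable_f(PowerQuery(alpha=0.05, power=0.80,
                                          n_total=47, n_groups=2,
                                          n_covariates=1))
        assert round(f, 2) == 0.42

    def test_zero_effect_power_is_alpha(self):
        q = PowerQuery()
        assert f_test_power(0.0, q) == pytest.approx(q.alpha)

    def test_power_monotone_in_f_and_saturates(self):
        q = PowerQuery()
        fs = np.linspace(0.05, 0.9, 15)
        powers = [f_test_power(f, q) for f in fs]
        assert np.all(np.diff(powers) > 0)
        assert f_test_power(2.0, q) > 0.999

    def test_roundtrip_with_solver(self):
        for target in (0.5, 0.8, 0.9):
            q = PowerQuery(power=target)
            f = solve_detectable_f(q)
            assert f_test_power(f, q) == pytest.approx(target, abs=1e-4)

    def test_large_df_normal_approximation_limit(self):
        # df2 -> inf: lambda -> (z_{1-a/2} + z_{power})^2 ~ 7.849
        from scipy.stats import norm

        q = PowerQuery(n_total=100000)
        f = solve_detectable_f(q)
        lam = f ** 2 * q.n_total
        z_lam = (norm.isf(0.025) + norm.isf(0.2)) ** 2
        assert lam == pytest.approx(z_lam, rel=0.01)
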