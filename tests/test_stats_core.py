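import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from _oracles import bh_reference, hommel_reference
from apmsnet import stats_core as sc


def make_matrix(values, groups):
    cols = [r for runs in groups.values() for r in runs]
    return pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))], columns=cols)


class TestMissingness:
    GROUPS = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([np.nan, np.nan, np.nan, 1, 2, 3], {"A": "MNAR", "B": "complete"}),
            ([np.nan, np.nan, 1, 1, 2, 3], {"A": "MAR", "B": "complete"}),
            ([1, 2, 3, 4, 5, 6], {"A": "complete", "B": "complete"}),
            ([np.nan, np.nan, np.nan, np.nan, np.nan, np.nan], {"A": "MAR", "B": "MAR"}),
        ],
        ids=["all-missing-elsewhere-observed", "partial", "complete", "never-observed"],
    )
    def test_classification_rule(self, row, expected):
        X = make_matrix([row], self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        for g, lab in expected.items():
            assert labels.loc["P0", g] == lab


class TestImpute:
    GROUPS = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}

    def test_zero_floor_uses_global_observed_minimum(self):
        X = make_matrix(
            [[np.nan, np.nan, np.nan, 5, 6, 7], [2, 3, 4, 5, 6, 7]], self.GROUPS
        )
        labels = sc.classify_missingness(X, self.GROUPS)
        out = sc.impute(X, labels, self.GROUPS, strategy_mnar="zero_floor")
        assert (out.loc["P0", ["a1", "a2", "a3"]] == 2.0).all()

    def test_complete_matrix_is_identity(self):
        X = make_matrix([[1, 2, 3, 4, 5, 6], [7, 8, 9, 1, 2, 3]], self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        for mar, mnar in itertools.product(["knn", "minprob"], ["zero_floor", "ppca"]):
            out = sc.impute(X, labels, self.GROUPS, strategy_mar=mar, strategy_mnar=mnar)
            pd.testing.assert_frame_equal(out, X)

    def test_observed_cells_untouched_and_no_missing_left(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 1, size=(30, 6))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        X = make_matrix(vals, self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        out = sc.impute(X, labels, self.GROUPS)
        assert not out.isna().any().any()
        obs = ~X.isna()
        assert np.array_equal(out.to_numpy()[obs.to_numpy()], X.to_numpy()[obs.to_numpy()])

    def test_knn_with_too_few_neighbours_falls_back_with_warning(self):
        X = make_matrix([[1, 2, 3, 4, 5, np.nan], [1, 2, 3, 4, 5, 6]], self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        with pytest.warns(UserWarning, match="column medians"):
            out = sc.impute(X, labels, self.GROUPS, strategy_mar="knn", k=10)
        assert out.loc["P0", "b3"] == 6.0

    def test_minprob_draw_distribution_and_reproducibility(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, size=(5000, 6))
        miss = rng.random(vals.shape) < 0.3
        vals_m = np.where(miss, np.nan, vals)
        X = make_matrix(vals_m, self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        out1 = sc.impute(X, labels, self.GROUPS, strategy_mar="minprob", seed=5)
        out2 = sc.impute(X, labels, self.GROUPS, strategy_mar="minprob", seed=5)
        pd.testing.assert_frame_equal(out1, out2)
        drawn = out1.to_numpy()[miss & ~np.isnan(out1.to_numpy())]
        col = X["a1"]
        q01 = col.dropna().quantile(0.01)
        # draws should centre near the low quantile with the run SD scale
        imputed_a1 = out1.loc[X["a1"].isna(), "a1"]
        assert imputed_a1.mean() == pytest.approx(q01, abs=0.15)
        assert imputed_a1.std() == pytest.approx(1.0, abs=0.15)

    def test_ppca_recovers_low_rank_structure(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 6))
        M = 20 + u @ v
        miss = rng.random(M.shape) < 0.15
        X = make_matrix(np.where(miss, np.nan, M), self.GROUPS)
        labels = sc.classify_missingness(X, self.GROUPS)
        out = sc.impute(X, labels, self.GROUPS, strategy_mar="knn", strategy_mnar="ppca")
        filled = out.to_numpy()[miss]
        truth = M[miss]
        assert np.abs(filled - truth).mean() < 1.0


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        res = sc.moderated_t(a, b, d0=0.0)
        t_ref, p_ref = sps.ttest_ind(a, b)
        assert res.t_mod == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.df_total == len(a) + len(b) - 2

    def test_equal_means_give_zero_logfc_large_p(self):
        a = np.array([5.0, 5.1, 4.9, 5.0])
        res = sc.moderated_t(a, a, d0=0.0)
        assert res.log_fc == 0.0
        assert res.p == pytest.approx(1.0)

    def test_prior_fit_recovers_true_hyperparameters(self):
        rng = np.random.default_rng(4)
        n, df = 5000, 6
        d0_true, s0_true = 5.0, 2.0
        sig2 = d0_true * s0_true / rng.chisquare(d0_true, n)
        s2 = sig2 * rng.chisquare(df, n) / df
        d0, s0 = sc.fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.15)

    def test_type_one_error_on_heteroscedastic_null(self):
        rng = np.random.default_rng(5)
        n, na = 2000, 4
        sig2 = 4.0 * 1.0 / rng.chisquare(4.0, n)
        A = rng.normal(0, np.sqrt(sig2)[:, None], (n, na))
        B = rng.normal(0, np.sqrt(sig2)[:, None], (n, na))
        res = sc.moderated_t_table(pd.DataFrame(A), pd.DataFrame(B))
        rate = float((res["p"] < 0.05).mean())
        assert 0.04 <= rate <= 0.06


class TestMultipleTesting:
    def test_bh_hand_stepup_example(self):
        out = sc.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("adjust", [sc.adjust_bh, sc.adjust_hommel])
    def test_single_p_is_identity(self, adjust):
        assert adjust(np.array([0.37]))[0] == 0.37

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
    def test_bh_matches_definitional_reference(self, p):
        p = np.asarray(p)
        assert np.allclose(sc.adjust_bh(p), bh_reference(p), atol=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
    def test_hommel_matches_closed_testing_reference(self, p):
        p = np.asarray(p)
        assert np.allclose(sc.adjust_hommel(p), hommel_reference(p), atol=1e-12)

    def test_hommel_dominates_bonferroni(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(2, 20))
            bonf = np.minimum(p * len(p), 1.0)
            assert (sc.adjust_hommel(p) <= bonf + 1e-12).all()


class TestFactorialAnova:
    def make_long(self, rng, effects=None, n_rep=3, sigma=1.0):
        effects = effects or {}
        rows = []
        for a, b, c in itertools.product("xy", "pqr", "mn"):
            for _ in range(n_rep):
                val = rng.normal(0, sigma)
                val += effects.get("fa", {}).get(a, 0.0)
                val += effects.get("fb", {}).get(b, 0.0)
                val += effects.get("fc", {}).get(c, 0.0)
                rows.append(dict(fa=a, fb=b, fc=c, value=val))
        return pd.DataFrame(rows)

    def test_matches_statsmodels_type2_on_unbalanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        df = self.make_long(rng, {"fa": {"x": 1.0}}).drop(index=[0, 1, 5, 9, 20])
        res = sc.factorial_anova(df, ["fa", "fb", "fc"])
        fit = smf.ols("value ~ C(fa)*C(fb)*C(fc)", df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert np.allclose(res.table["sum_sq"], ref["sum_sq"].to_numpy()[:-1])
        assert np.allclose(res.table["F"], ref["F"].to_numpy()[:-1], equal_nan=True)

    def test_type2_equals_type1_on_balanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        df = self.make_long(rng)
        res = sc.factorial_anova(df, ["fa", "fb", "fc"])
        fit = smf.ols("value ~ C(fa)*C(fb)*C(fc)", df).fit()
        ref1 = sm.stats.anova_lm(fit, typ=1)
        assert np.allclose(res.table["sum_sq"], ref1["sum_sq"].to_numpy()[:-1])

    def test_one_factor_equals_classical_oneway_f(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        df = pd.DataFrame(
            {"g": np.repeat(list("abc"), 8), "value": np.concatenate(groups)}
        )
        res = sc.factorial_anova(df, ["g"])
        F_ref, p_ref = sps.f_oneway(*groups)
        assert res.table.loc["g", "F"] == pytest.approx(F_ref)
        assert res.table.loc["g", "p"] == pytest.approx(p_ref)

    def test_zero_noise_balanced_design_flagged_degenerate(self):
        rows = [
            dict(fa=a, fb=b, value={"x": 1.0, "y": 2.0}[a] + {"p": 0.0, "q": 1.0}[b])
            for a, b in itertools.product("xy", "pq")
            for _ in range(3)
        ]
        res = sc.factorial_anova(pd.DataFrame(rows), ["fa", "fb"])
        assert res.degenerate
        assert any("degenerate" in n for n in res.notes)

    def test_single_factor_effect_recovered_over_seeds(self):
        hits_a, hits_other = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df = self.make_long(rng, {"fa": {"x": 2.0}}, sigma=0.8)
            res = sc.factorial_anova(df, ["fa", "fb", "fc"])
            if res.table.loc["fa", "p"] < 0.01:
                hits_a += 1
            others = res.table.drop(index="fa")["p"]
            hits_other += int((others < 0.01).sum())
        assert hits_a == 20
        assert hits_other <= 10  # ~1% of 120 other effect tests

    def test_aliased_interaction_dropped_with_note(self):
        # concentration 'none' only under 'unstim': interaction aliased
        rows = []
        rng = np.random.default_rng(10)
        for cu, co in [("unstim", "none"), ("DMOG", "20"), ("DMOG", "200")]:
            for _ in range(4):
                rows.append(dict(cu=cu, co=co, value=rng.normal()))
        res = sc.factorial_anova(pd.DataFrame(rows), ["cu", "co"])
        assert any("aliased" in n for n in res.notes)
        assert "cu:co" not in res.table.index


class TestTukey:
    def one_way(self, groups, labels="abc"):
        df = pd.DataFrame(
            {
                "g": np.repeat(list(labels[: len(groups)]), [len(g) for g in groups]),
                "value": np.concatenate(groups),
            }
        )
        return sc.factorial_anova(df, ["g"])

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 6), rng.normal(2, 1, 6), rng.normal(0, 1, 6)]
        tab = sc.tukey_hsd(self.one_way(groups), "g")
        ref = sps.tukey_hsd(*groups)
        got = dict(zip(zip(tab["level_a"], tab["level_b"]), tab["p"]))
        assert got[("a", "b")] == pytest.approx(ref.pvalue[0, 1], abs=1e-9)
        assert got[("a", "c")] == pytest.approx(ref.pvalue[0, 2], abs=1e-9)
        assert got[("b", "c")] == pytest.approx(ref.pvalue[1, 2], abs=1e-9)

    def test_identical_levels_give_zero_diff_large_p(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, 6)
        tab = sc.tukey_hsd(self.one_way([base, base.copy()], "ab"), "g")
        assert tab.loc[0, "diff"] == 0.0
        assert tab.loc[0, "p"] > 0.99

    def test_five_sigma_shift_detected_on_both_comparisons(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(5, 1, 6)]
        tab = sc.tukey_hsd(self.one_way(groups), "g")
        sig = tab[tab["p"] < 0.05]
        pairs = set(zip(sig["level_a"], sig["level_b"]))
        assert ("a", "c") in pairs and ("b", "c") in pairs
        assert ("a", "b") not in pairs

    def test_ci_coverage_at_nominal_level(self):
        rng = np.random.default_rng(14)
        true_diff = 1.5
        cover = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 6), rng.normal(true_diff, 1, 6)]
            tab = sc.tukey_hsd(self.one_way(groups, "ab"), "g")
            lo, hi = tab.loc[0, "ci_low"], tab.loc[0, "ci_high"]
            if lo <= -true_diff <= hi or lo <= true_diff <= hi:
                cover += 1
        assert cover / n_sim >= 0.90
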