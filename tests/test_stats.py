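import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from popcaim.stats import (
    mixed_anova, oneway_anova, paired_t_holm, rm_oneway_anova, ryan_posthoc,
)


def make_balanced(n_groups=4, n_per_group=8, n_times=4, seed=0, effects=None):
    """Long-format balanced split-plot dataset."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for s in range(n_per_group):
            subj_eff = rng.normal(0, 0.5)
            for t in range(n_times):
                mu = 0.0 if effects is None else effects[g][t]
                rows.append(dict(
                    animal=f"g{g}s{s}", paradigm=f"G{g}", time_point=f"t{t}",
                    value=mu + subj_eff + rng.normal(0, 1),
                ))
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Textbook correction-factor sums-of-squares computation, written
    independently of the implementation (raw totals, not means)."""
    y = df["value"].to_numpy()
    N = len(y)
    cf = y.sum() ** 2 / N
    ss_total = (y ** 2).sum() - cf

    def ss_of(groupcols):
        agg = df.groupby(groupcols)["value"].agg(["sum", "count"])
        return ((agg["sum"] ** 2) / agg["count"]).sum() - cf

    ss_g = ss_of("paradigm")
    ss_t = ss_of("time_point")
    ss_subj_tot = ss_of("animal")               # subjects + groups
    ss_cells = ss_of(["paradigm", "time_point"])
    ss_subj = ss_subj_tot - ss_g
    ss_inter = ss_cells - ss_g - ss_t
    ss_resid = ss_total - ss_subj_tot - ss_t - ss_inter

    g = df["paradigm"].nunique()
    t = df["time_point"].nunique()
    n = df["animal"].nunique() // g
    f_g = (ss_g / (g - 1)) / (ss_subj / (g * (n - 1)))
    f_t = (ss_t / (t - 1)) / (ss_resid / (g * (n - 1) * (t - 1)))
    f_i = (ss_inter / ((g - 1) * (t - 1))) / (ss_resid / (g * (n - 1) * (t - 1)))
    return dict(ss_g=ss_g, ss_t=ss_t, ss_inter=ss_inter, ss_subj=ss_subj,
                ss_resid=ss_resid, ss_total=ss_total, f_g=f_g, f_t=f_t, f_i=f_i)


class TestMixedAnova:
    def test_canonical_design_degrees_of_freedom(self):
        tab = mixed_anova(make_balanced()).set_index("effect")
        assert (tab.loc["paradigm", ["df_num", "df_den"]] == [3, 28]).all()
        assert (tab.loc["time_point", ["df_num", "df_den"]] == [3, 84]).all()
        assert (tab.loc["interaction", ["df_num", "df_den"]] == [9, 84]).all()

    def test_all_equal_measurements_give_zero_f(self):
        df = make_balanced(seed=1)
        df["value"] = 5.0
        tab = mixed_anova(df).set_index("effect")
        assert (tab.loc[["paradigm", "time_point", "interaction"], "F"] == 0).all()
        assert (tab.loc[["paradigm", "time_point", "interaction"], "p"] == 1).all()

    def test_ss_decomposition_sums_to_total(self):
        for seed in range(5):
            tab = mixed_anova(make_balanced(seed=seed)).set_index("effect")
            parts = tab.loc[["paradigm", "time_point", "interaction",
                             "subjects_within_groups", "residual"], "ss"].sum()
            assert parts == pytest.approx(tab.loc["total", "ss"], abs=1e-9)

    def test_f_values_match_correction_factor_oracle(self):
        for seed in range(50):
            df = make_balanced(n_groups=3, n_per_group=5, n_times=4, seed=seed)
            tab = mixed_anova(df).set_index("effect")
            want = anova_ss_oracle(df)
            assert tab.loc["paradigm", "F"] == pytest.approx(want["f_g"], abs=1e-8)
            assert tab.loc["time_point", "F"] == pytest.approx(want["f_t"], abs=1e-8)
            assert tab.loc["interaction", "F"] == pytest.approx(want["f_i"], abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = make_balanced(seed=3)
        tab = mixed_anova(df).set_index("effect")
        ref = pingouin.mixed_anova(data=df, dv="value", within="time_point",
                                   subject="animal", between="paradigm").set_index("Source")
        assert tab.loc["paradigm", "F"] == pytest.approx(ref.loc["paradigm", "F"])
        assert tab.loc["time_point", "F"] == pytest.approx(ref.loc["time_point", "F"])
        assert tab.loc["interaction", "F"] == pytest.approx(ref.loc["Interaction", "F"])

    def test_unbalanced_designs_raise(self):
        df = make_balanced()
        with pytest.raises(ValueError):
            mixed_anova(df.iloc[:-1])  # missing one cell
        df2 = make_balanced()
        df2.loc[df2.index[-1], "value"] = np.nan
        with pytest.raises(ValueError):
            mixed_anova(df2)
        # unequal group sizes
        df3 = make_balanced()
        df3 = df3[~((df3["paradigm"] == "G0") & (df3["animal"] == "g0s0"))]
        with pytest.raises(ValueError):
            mixed_anova(df3)

    def test_gg_correction_reported_and_conservative(self):
        effects = [[0.0, 0.5, 1.0, 1.5]] * 4  # real time effect so F > 1
        df = make_balanced(seed=9, effects=effects)
        tab = mixed_anova(df, gg_correction=True).set_index("effect")
        eps = tab.loc["time_point", "gg_eps"]
        assert 1 / 3 <= eps <= 1.0
        assert tab.loc["time_point", "F"] > 1
        # with F > 1, shrinking both df makes the test more conservative
        assert tab.loc["time_point", "p_gg"] >= tab.loc["time_point", "p"] - 1e-12


class TestOnewayAnova:
    def test_four_by_eight_df(self):
        rng = np.random.default_rng(0)
        res = oneway_anova([rng.normal(0, 1, 8) for _ in range(4)])
        assert res["df"] == (3, 28)

    def test_identical_groups_f_zero(self):
        res = oneway_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res["F"] == 0.0

    def test_hand_sums_of_squares(self):
        # groups (1,2) and (3,4): SS_between = 4, SS_within = 1, F = 8
        res = oneway_anova([[1.0, 2.0], [3.0, 4.0]])
        assert res["F"] == pytest.approx(8.0)
        assert res["df"] == (1, 2)
        assert res["p"] == pytest.approx(sps.f.sf(8.0, 1, 2))

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0], [2.0, 3.0]])


class TestRmOnewayAnova:
    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, (8, 4)) + rng.normal(0, 1, (8, 1))
        res = rm_oneway_anova(y)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 4),
            "level": np.tile(np.arange(4), 8),
            "value": y.ravel(),
        })
        ref = AnovaRM(long, "value", "subject", within=["level"]).fit()
        assert res["F"] == pytest.approx(ref.anova_table["F Value"].iloc[0])
        assert res["df"] == (3, 21)


class TestRyanPosthoc:
    def test_two_levels_single_comparison_at_alpha(self):
        res = ryan_posthoc([0.0, 1.0], 8, 1.0, 14, alpha=0.05)
        assert len(res.table) == 1
        assert res.table["nominal_level"].iloc[0] == pytest.approx(0.05)

    def test_nominal_levels_follow_formula_k4(self):
        res = ryan_posthoc([0.0, 1.0, 2.0, 3.0], 8, 1.0, 28, alpha=0.05)
        by_span = res.table.groupby("span_r")["nominal_level"].unique()
        assert by_span[2][0] == pytest.approx(2 * 0.05 / 4)        # 0.025
        assert by_span[3][0] == pytest.approx(2 * 0.05 / (4 * 2))  # 0.0125
        assert by_span[4][0] == pytest.approx(2 * 0.05 / (4 * 3))  # 0.00833...

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ryan_posthoc([1.0], 8, 1.0, 10)
        with pytest.raises(ValueError):
            ryan_posthoc([1.0, 2.0], 8, 0.0, 10)

    @staticmethod
    def _sim_groups(seed, k=4, n=8, shift=0.0):
        rng = np.random.default_rng(seed)
        groups = rng.normal(0, 1, (k, n))
        groups[-1] += shift
        return groups

    def test_closure_no_isolated_rejection_inside_accepted_span(self):
        for seed in range(50):
            groups = self._sim_groups(seed, shift=1.0)
            means = groups.mean(axis=1)
            msw = groups.var(axis=1, ddof=1).mean()
            res = ryan_posthoc(means, groups.shape[1], msw,
                               groups.size - groups.shape[0])
            tab = res.table
            order = np.argsort(means)
            rank = {lbl: r for r, lbl in enumerate(order)}
            sig = {tuple(sorted((rank[a], rank[b]))): s
                   for a, b, s in zip(tab["level_i"], tab["level_j"],
                                      tab["significant"])}
            for (a, b), s in sig.items():
                if s:
                    enclosing = [(a2, b2) for (a2, b2) in sig
                                 if a2 <= a and b2 >= b and (a2, b2) != (a, b)]
                    assert all(sig[e] for e in enclosing)

    def test_between_bonferroni_and_unadjusted(self):
        """Ryan rejections contain all Bonferroni-all-pairs rejections and are
        contained in the unadjusted rejections."""
        for seed in range(50):
            groups = self._sim_groups(seed, shift=1.5)
            k, n = groups.shape
            means = groups.mean(axis=1)
            msw = groups.var(axis=1, ddof=1).mean()
            dfe = groups.size - k
            res = ryan_posthoc(means, n, msw, dfe)
            m = k * (k - 1) / 2
            se = np.sqrt(msw * 2 / n)
            for _, row in res.table.iterrows():
                p = 2 * sps.t.sf(abs(row["mean_diff"]) / se, dfe)
                if p < 0.05 / m:       # Bonferroni rejects
                    assert row["significant"]
                if not (p < 0.05):     # unadjusted accepts
                    assert not row["significant"]

    def test_complete_null_fwer_controlled(self):
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            groups = self._sim_groups(seed)
            means = groups.mean(axis=1)
            msw = groups.var(axis=1, ddof=1).mean()
            res = ryan_posthoc(means, groups.shape[1], msw,
                               groups.size - groups.shape[0])
            hits += res.table["significant"].any()
        fwer = hits / n_rep
        assert fwer <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_regw_levels_variant(self):
        res = ryan_posthoc([0.0, 1.0, 2.0, 3.0], 8, 1.0, 28, alpha=0.05,
                           level_formula="regw")
        by_span = res.table.groupby("span_r")["nominal_level"].unique()
        assert by_span[2][0] == pytest.approx(1 - 0.95 ** (2 / 4))
        assert by_span[3][0] == pytest.approx(0.05)
        assert by_span[4][0] == pytest.approx(0.05)


def holm_oracle(ps):
    """Hand step-down Holm adjustment with monotonicity."""
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * ps[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


class TestPairedTHolm:
    def test_adjustment_matches_hand_oracle(self):
        rng = np.random.default_rng(8)
        comps = [(rng.normal(0, 1, 10), rng.normal(d, 1, 10))
                 for d in (0.0, 0.5, 1.0, 1.5)]
        tab = paired_t_holm(comps)
        np.testing.assert_allclose(tab["p_holm"],
                                   holm_oracle(tab["p_raw"].to_numpy()),
                                   atol=1e-12)

    def test_hand_stepdown_values(self):
        # raw (0.01, 0.03, 0.04) -> (0.03, 0.06, 0.06)
        np.testing.assert_allclose(holm_oracle([0.01, 0.03, 0.04]),
                                   [0.03, 0.06, 0.06])
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(
            multipletests([0.01, 0.03, 0.04], method="holm")[1],
            [0.03, 0.06, 0.06])

    def test_single_comparison_unchanged(self):
        x = np.array([1.0, 2.0, 3.0, 2.5])
        y = np.array([0.5, 2.5, 2.0, 3.5])
        tab = paired_t_holm([(x, y)])
        assert tab["p_holm"].iloc[0] == pytest.approx(tab["p_raw"].iloc[0])

    def test_identical_pairs_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0])
        tab = paired_t_holm([(x, x.copy())])
        assert tab["t"].iloc[0] == 0.0
        assert tab["p_raw"].iloc[0] == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        comps = [(rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)) for _ in range(4)]
        fwd = paired_t_holm(comps)["p_holm"].to_numpy()
        rev = paired_t_holm(comps[::-1])["p_holm"].to_numpy()
        np.testing.assert_allclose(rev[::-1], fwd, atol=1e-12)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            paired_t_holm([(np.zeros(4), np.zeros(5))])
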