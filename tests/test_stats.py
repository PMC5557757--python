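"""Statistical battery: printed-value anchors, moment-matched and
library oracles, and the split-plot / FDR invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from psytact.stats import (bh_fdr, bonferroni_pairwise, mann_whitney,
                           mixed_anova, mwu_z_from_u, pearson_p_from_r,
                           pearson_test, pooled_t_test, t_test)


class TestPooledT:
    def test_sensation_threshold_summary_statistics(self):
        # group summaries (ASD vs TD, μA): the classic pooled t
        res = pooled_t_test(8.262, 1.563, 20, 8.375, 1.505, 19)
        assert res.df == 37
        assert abs(res.t) == pytest.approx(0.231, abs=0.005)
        assert res.cohens_d == pytest.approx(0.07, abs=0.005)

    def test_pain_threshold_summary_statistics(self):
        res = pooled_t_test(57.235, 41.927, 20, 47.814, 22.422, 19)
        assert res.df == 37
        assert abs(res.t) == pytest.approx(0.868, abs=0.005)
        assert res.cohens_d == pytest.approx(0.28, abs=0.005)

    def test_identical_groups_give_zero(self):
        res = pooled_t_test(3.0, 1.0, 10, 3.0, 1.0, 10)
        assert res.t == 0.0
        assert res.cohens_d == 0.0

    def test_sign_follows_second_minus_first(self):
        assert pooled_t_test(1.0, 1.0, 10, 2.0, 1.0, 10).t > 0
        assert pooled_t_test(2.0, 1.0, 10, 1.0, 1.0, 10).t < 0

    def test_zero_pooled_sd(self):
        assert pooled_t_test(2.0, 0.0, 5, 2.0, 0.0, 5).t == 0.0
        with pytest.raises(ValueError, match="pooled"):
            pooled_t_test(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_matches_raw_data_t_on_moment_matched_samples(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            n1, n2 = rng.integers(3, 30, 2)
            x = rng.normal(size=n1)
            x = (x - x.mean()) / x.std(ddof=1) * s1 + m1
            y = rng.normal(size=n2)
            y = (y - y.mean()) / y.std(ddof=1) * s2 + m2
            ours = pooled_t_test(m1, s1, n1, m2, s2, n2)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert abs(ours.t) == pytest.approx(abs(ref.statistic), abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            raw = t_test(x, y)
            assert raw.t == pytest.approx(ours.t, abs=1e-10)


def _toy_2x2():
    # 4 subjects x 2 levels; sums of squares computed by hand:
    # SS_group = 6.125 (err 10.25), SS_level = 3.125, SS_inter = 1.125,
    # SS_err_within = 0.25
    rows = []
    data = {"s1": ("A", (2.0, 4.0)), "s2": ("A", (4.0, 6.0)),
            "s3": ("B", (1.0, 1.0)), "s4": ("B", (3.0, 4.0))}
    for subj, (grp, vals) in data.items():
        for lvl, v in zip(("L1", "L2"), vals):
            rows.append({"subject": subj, "grp": grp, "level": lvl, "y": v})
    return pd.DataFrame(rows)


def _random_mixed(rng, n1=16, n2=15, k=3):
    rows = []
    for grp, n in (("A", n1), ("B", n2)):
        for s in range(n):
            sid = f"{grp}{s:02d}"
            subj_eff = rng.normal(0, 1)
            for lvl in range(k):
                rows.append({"subject": sid, "grp": grp, "level": f"l{lvl}",
                             "y": rng.normal(lvl + (0.4 if grp == "A" else 0), 1)
                             + subj_eff})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_by_hand_2x2_sums_of_squares(self):
        res = mixed_anova(_toy_2x2(), dv="y", within="level",
                          subject="subject", between="grp")
        assert res.between.ss == pytest.approx(6.125)
        assert res.between.ss_error == pytest.approx(10.25)
        assert res.within.ss == pytest.approx(3.125)
        assert res.interaction.ss == pytest.approx(1.125)
        assert res.within.ss_error == pytest.approx(0.25)
        assert res.between.F == pytest.approx(6.125 / 5.125)
        assert res.within.F == pytest.approx(25.0)
        assert res.interaction.F == pytest.approx(9.0)
        assert res.between.partial_eta_sq == pytest.approx(6.125 / 16.375)
        assert res.within.partial_eta_sq == pytest.approx(3.125 / 3.375)
        assert res.interaction.partial_eta_sq == pytest.approx(1.125 / 1.375)

    def test_between_dfs_match_group_sizes(self, rng):
        res = mixed_anova(_random_mixed(rng, 16, 15, 2), dv="y", within="level",
                          subject="subject", between="grp")
        assert (res.between.df_num, res.between.df_den) == (1, 29)
        assert (res.within.df_num, res.within.df_den) == (1, 29)

    def test_duplicated_groups_give_zero_between_F(self, rng):
        df = _random_mixed(rng, 10, 10, 3)
        a = df[df["grp"] == "A"].copy()
        b = a.copy()
        b["grp"] = "B"
        b["subject"] = "B_" + b["subject"]
        dup = pd.concat([a, b], ignore_index=True)
        res = mixed_anova(dup, dv="y", within="level",
                          subject="subject", between="grp")
        assert res.between.F == pytest.approx(0.0, abs=1e-20)

    def test_ss_partition_identity_on_random_data(self, rng):
        for _ in range(10):
            df = _random_mixed(rng, int(rng.integers(3, 12)),
                               int(rng.integers(3, 12)), int(rng.integers(2, 5)))
            res = mixed_anova(df, dv="y", within="level",
                              subject="subject", between="grp")
            top = res.ss_between_subjects + res.ss_within_subjects
            assert abs(top - res.ss_total) <= 1e-9 * res.ss_total
            within_parts = (res.within.ss + res.interaction.ss
                            + res.within.ss_error)
            assert abs(within_parts - res.ss_within_subjects) \
                <= 1e-9 * max(res.ss_within_subjects, 1.0)
            for e in res.effects.values():
                assert 0.0 <= e.partial_eta_sq <= 1.0

    def test_matches_pingouin_on_unbalanced_data(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _random_mixed(rng, 16, 15, 3)
        ours = mixed_anova(df, dv="y", within="level",
                           subject="subject", between="grp")
        ref = pg.mixed_anova(data=df, dv="y", within="level",
                             subject="subject", between="grp")
        ref = ref.set_index("Source")
        assert ours.between.F == pytest.approx(ref.loc["grp", "F"])
        assert ours.within.F == pytest.approx(ref.loc["level", "F"])
        assert ours.interaction.F == pytest.approx(ref.loc["Interaction", "F"])
        assert ours.between.partial_eta_sq == pytest.approx(ref.loc["grp", "np2"])
        assert ours.within.p == pytest.approx(ref.loc["level", "p_unc"])

    def test_missing_cell_is_error_naming_subject_and_level(self, rng):
        df = _random_mixed(rng, 4, 4, 3)
        df = df[~((df["subject"] == "A01") & (df["level"] == "l2"))]
        with pytest.raises(ValueError, match="A01.*l2"):
            mixed_anova(df, dv="y", within="level",
                        subject="subject", between="grp")


class TestBonferroni:
    def test_two_levels_no_adjustment(self, rng):
        df = _random_mixed(rng, 6, 6, 2)
        out = bonferroni_pairwise(df, dv="y", within="level", subject="subject")
        assert len(out) == 1
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p_raw"])

    def test_three_levels_factor_three_capped_at_one(self, rng):
        df = _random_mixed(rng, 6, 6, 3)
        out = bonferroni_pairwise(df, dv="y", within="level", subject="subject")
        assert len(out) == 3
        for _, row in out.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 3))

    def test_raw_p_matches_scipy_paired_t(self, rng):
        df = _random_mixed(rng, 6, 6, 3)
        wide = df.pivot_table(index="subject", columns="level", values="y")
        out = bonferroni_pairwise(df, dv="y", within="level", subject="subject")
        row = out[(out["level_a"] == "l0") & (out["level_b"] == "l1")].iloc[0]
        ref = sps.ttest_rel(wide["l0"], wide["l1"])
        assert row["p_raw"] == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def test_printed_u_reproduces_z(self):
        # U = 164.5 with groups of 16 and 15, no tie information
        z = mwu_z_from_u(164.5, 16, 15)
        assert z == pytest.approx(1.765, rel=0.005)
        z_weak = mwu_z_from_u(113.5, 16, 15)
        assert abs(z_weak) == pytest.approx(0.260, rel=0.015)

    def test_null_center_gives_zero_z(self):
        assert mwu_z_from_u(120.0, 16, 15) == 0.0

    def test_u_plus_u_prime_is_n1_n2(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=rng.integers(2, 20)).astype(float)
            y = rng.integers(0, 5, size=rng.integers(2, 20)).astype(float)
            res = mann_whitney(x, y)
            assert res.U + res.U_other == pytest.approx(len(x) * len(y))

    def test_matches_scipy_asymptotic(self, rng):
        x = rng.normal(0.3, 1, 18)
        y = rng.normal(0.0, 1, 14)
        res = mann_whitney(x, y, tie_correction=True, continuity=False)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_p_close_to_exact_at_small_n(self):
        # at n = 4 + 4 the continuity-corrected normal approximation sits
        # close to the exact enumeration p
        x = [1.0, 3.0, 5.0, 7.0]
        y = [2.0, 4.0, 6.0, 8.0]
        ours = mann_whitney(x, y, continuity=True)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert abs(ours.p - exact.pvalue) < 0.05

    def test_tie_correction_shrinks_variance(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0]
        y = [1.0, 2.0, 2.0, 3.0, 3.0]
        with_tc = mann_whitney(x, y, tie_correction=True)
        without = mann_whitney(x, y, tie_correction=False)
        assert abs(with_tc.z) >= abs(without.z)


class TestPearson:
    def test_printed_r_gives_printed_p(self):
        assert pearson_p_from_r(0.558, 31) == pytest.approx(0.001, abs=0.0005)

    def test_zero_r_gives_p_one(self):
        assert pearson_p_from_r(0.0, 25) == pytest.approx(1.0)

    @given(st.floats(-0.99, 0.99), st.integers(4, 200))
    def test_symmetric_in_sign(self, r, n):
        assert pearson_p_from_r(r, n) == pytest.approx(pearson_p_from_r(-r, n))

    def test_matches_scipy(self, rng):
        x = rng.normal(size=25)
        y = x * 0.5 + rng.normal(size=25)
        ours = pearson_test(x, y)
        ref = sps.pearsonr(x, y)
        assert ours.r == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_t_transform_p_close_to_permutation_p(self, rng):
        x = rng.normal(size=12)
        y = x * 0.8 + rng.normal(size=12) * 0.8
        ours = pearson_test(x, y)
        r_obs = abs(ours.r)
        perm = sum(abs(np.corrcoef(rng.permutation(x), y)[0, 1]) >= r_obs
                   for _ in range(4000)) / 4000
        assert abs(ours.p - perm) < 0.03


def step_up_oracle(p_values, Q):
    """Literal brute-force application of the strict step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    cutoff = None
    for rank, i in enumerate(order, start=1):
        if p_values[i] < Q * rank / m:
            cutoff = p_values[i]
    return [cutoff is not None and p <= cutoff for p in p_values]


class TestBhFdr:
    def test_single_small_p_significant(self):
        out = bh_fdr([0.01], Q=0.05)
        assert out.loc[0, "q"] == pytest.approx(0.05)
        assert out.loc[0, "significant"]

    def test_q_values_at_printed_ranks(self):
        # 14 tests: rank 1 -> 0.004, rank 5 -> 0.018 at the printed precision
        ps = np.linspace(0.0005, 0.9, 14)
        out = bh_fdr(ps, Q=0.05)
        q = out.sort_values("rank")["q"].to_numpy()
        assert round(q[0], 3) == 0.004
        assert round(q[4], 3) == 0.018

    def test_published_aasp_pattern(self):
        # 8 tests; the two smallest pass, borderline ones do not
        ps = [0.009, 0.010, 0.058, 0.068, 0.12, 0.2, 0.5, 0.9]
        out = bh_fdr(ps, Q=0.05)
        assert list(out["significant"]) == step_up_oracle(ps, 0.05)
        assert list(out["significant"])[:2] == [True, True]
        assert not any(out["significant"][2:])

    def test_strict_inequality_at_exact_equality(self):
        # p exactly equal to its critical value is NOT significant
        out = bh_fdr([0.05], Q=0.05)
        assert not out.loc[0, "significant"]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_oracle(self, ps):
        out = bh_fdr(ps, Q=0.05)
        assert list(out["significant"]) == step_up_oracle(ps, 0.05)

    @given(st.lists(st.floats(0.0001, 1.0), min_size=2, max_size=20),
           st.integers(0, 1000))
    def test_invariant_to_input_order(self, ps, seed):
        perm = list(np.random.default_rng(seed).permutation(len(ps)))
        out1 = bh_fdr(ps, Q=0.05)
        out2 = bh_fdr([ps[i] for i in perm], Q=0.05)
        assert [list(out1["significant"])[i] for i in perm] \
            == list(out2["significant"])

    def test_monotone_in_Q(self, rng):
        ps = rng.uniform(0, 0.2, 15)
        low = bh_fdr(ps, Q=0.01)["significant"]
        high = bh_fdr(ps, Q=0.10)["significant"]
        assert all(h or not l for l, h in zip(low, high))

    def test_matches_statsmodels_on_random_p(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(20):
            ps = rng.uniform(0, 1, 25)
            ours = bh_fdr(ps, Q=0.05)["significant"].to_numpy()
            ref = sm.multipletests(ps, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    def test_ties_share_decision(self):
        ps = [0.01, 0.01, 0.9]
        out = bh_fdr(ps, Q=0.05)
        assert list(out["significant"]) == [True, True, False]

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
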