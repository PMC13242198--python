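"""Mixed ANOVA, t-tests, p adjustment, cluster permutation, McNemar,
sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

import tacsattn as ta
from tacsattn.errors import (ConfigurationError, DataError, InferenceError)

# --------------------------------------------------------------------------
# Brute-force ANOVA oracle: explicit loops over cell means, no shared code
# --------------------------------------------------------------------------

def brute_force_mixed_anova(df, dv, subject, between, w1, w2):
    """Full SS decomposition computed from cell means with plain loops."""
    groups = sorted(df[between].unique())
    l1 = sorted(df[w1].unique())
    l2 = sorted(df[w2].unique())
    subjects = sorted(df[subject].unique())
    gmap = {s: df[df[subject] == s][between].iloc[0] for s in subjects}
    n = len(subjects) // len(groups)

    def cell(**kw):
        sub = df
        for col, val in kw.items():
            sub = sub[sub[col] == val]
        return sub[dv].to_numpy()

    grand = df[dv].mean()
    a, b, g, N = len(l1), len(l2), len(groups), len(subjects)
    ss = {}
    ss["G"] = sum(n * a * b * (cell(**{between: gr}).mean() - grand) ** 2
                  for gr in groups)
    ss["S"] = sum(a * b * (cell(**{subject: s}).mean()
                           - cell(**{between: gmap[s]}).mean()) ** 2
                  for s in subjects)
    ss["A"] = sum(N * b * (cell(**{w1: i}).mean() - grand) ** 2 for i in l1)
    ss["AG"] = sum(n * b * (cell(**{between: gr, w1: i}).mean()
                            - cell(**{between: gr}).mean()
                            - cell(**{w1: i}).mean() + grand) ** 2
                   for gr in groups for i in l1)
    ss["AS"] = sum(b * (cell(**{subject: s, w1: i}).mean()
                        - cell(**{subject: s}).mean()
                        - cell(**{between: gmap[s], w1: i}).mean()
                        + cell(**{between: gmap[s]}).mean()) ** 2
                   for s in subjects for i in l1)
    ss["B"] = sum(N * a * (cell(**{w2: j}).mean() - grand) ** 2 for j in l2)
    ss["BG"] = sum(n * a * (cell(**{between: gr, w2: j}).mean()
                            - cell(**{between: gr}).mean()
                            - cell(**{w2: j}).mean() + grand) ** 2
                   for gr in groups for j in l2)
    ss["BS"] = sum(a * (cell(**{subject: s, w2: j}).mean()
                        - cell(**{subject: s}).mean()
                        - cell(**{between: gmap[s], w2: j}).mean()
                        + cell(**{between: gmap[s]}).mean()) ** 2
                   for s in subjects for j in l2)
    ss["AB"] = sum(N * (cell(**{w1: i, w2: j}).mean()
                        - cell(**{w1: i}).mean() - cell(**{w2: j}).mean()
                        + grand) ** 2 for i in l1 for j in l2)
    ss["ABG"] = sum(n * (cell(**{between: gr, w1: i, w2: j}).mean()
                         - cell(**{between: gr, w1: i}).mean()
                         - cell(**{between: gr, w2: j}).mean()
                         - cell(**{w1: i, w2: j}).mean()
                         + cell(**{between: gr}).mean()
                         + cell(**{w1: i}).mean() + cell(**{w2: j}).mean()
                         - grand) ** 2
                    for gr in groups for i in l1 for j in l2)
    ss_total = float(((df[dv] - grand) ** 2).sum())
    ss["ABS"] = ss_total - sum(ss.values())
    return ss, ss_total


def _make_rt_fixture(seed=0, effect=25.0, n=9):
    """Balanced 2 x 2 x 4 subject-mean table with a group x time effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(("sham", "active")):
        for s in range(n):
            subj = f"{group}{s}"
            base = 350 + rng.normal(0, 30)
            for session in ("pre", "post"):
                for ti, tt in enumerate(ta.taskgen.TRIAL_TYPES):
                    mu = base + 20 * ti
                    if session == "post" and group == "active":
                        mu -= effect
                    rows.append((subj, group, session, tt,
                                 mu + rng.normal(0, 10)))
    return pd.DataFrame(rows, columns=["subject", "group", "session",
                                       "trial_type", "mean_rt_ms"])


class TestMixedAnova:
    def test_constant_response_gives_zero_f(self):
        df = _make_rt_fixture(0)
        df["mean_rt_ms"] = 5.0
        tab = ta.mixed_anova(df, "mean_rt_ms", "subject", "group",
                             ["session", "trial_type"])
        assert (tab["F"] == 0).all()
        assert (tab["p"] == 1).all()

    def test_matches_brute_force_oracle(self):
        df = _make_rt_fixture(1)
        tab = ta.mixed_anova(df, "mean_rt_ms", "subject", "group",
                             ["session", "trial_type"]).set_index("effect")
        ss, ss_total = brute_force_mixed_anova(
            df, "mean_rt_ms", "subject", "group", "session", "trial_type")
        pairs = [("group", "G", "S"), ("session", "A", "AS"),
                 ("group:session", "AG", "AS"),
                 ("trial_type", "B", "BS"),
                 ("group:trial_type", "BG", "BS"),
                 ("session:trial_type", "AB", "ABS"),
                 ("group:session:trial_type", "ABG", "ABS")]
        dfs = {"G": (1, 16), "A": (1, 16), "AG": (1, 16), "B": (3, 48),
               "BG": (3, 48), "AB": (3, 48), "ABG": (3, 48)}
        for effect, key, err in pairs:
            df_num, df_den = dfs[key]
            f_oracle = (ss[key] / df_num) / (ss[err] / df_den)
            assert tab.loc[effect, "F"] == pytest.approx(f_oracle, abs=1e-8)
            assert tab.loc[effect, "df_num"] == df_num
            assert tab.loc[effect, "df_den"] == df_den
            eta = ss[key] / (ss[key] + ss[err])
            assert tab.loc[effect, "partial_eta_sq"] == \
                pytest.approx(eta, abs=1e-10)

    def test_ss_decomposition_sums_to_total(self):
        df = _make_rt_fixture(2)
        tab = ta.mixed_anova(df, "mean_rt_ms", "subject", "group",
                             ["session", "trial_type"])
        pieces = tab.set_index("effect")["ss"]
        ss_sg = tab.attrs["ss_subjects_within_groups"]
        ss_asg, ss_bsg, ss_absg = tab.attrs["ss_residuals"]
        total = pieces.sum() + ss_sg + ss_asg + ss_bsg + ss_absg
        assert total == pytest.approx(tab.attrs["ss_total"], abs=1e-8)

    def test_single_within_factor_matches_pingouin(self):
        """Independent cross-check of the group x time case."""
        pingouin = pytest.importorskip("pingouin")
        df = (_make_rt_fixture(3).groupby(
            ["subject", "group", "session"], observed=True)["mean_rt_ms"]
            .mean().reset_index())
        ours = ta.mixed_anova(df, "mean_rt_ms", "subject", "group",
                              ["session"]).set_index("effect")
        theirs = pingouin.mixed_anova(df, dv="mean_rt_ms",
                                      within="session", subject="subject",
                                      between="group").set_index("Source")
        assert ours.loc["group", "F"] == \
            pytest.approx(theirs.loc["group", "F"], rel=1e-6)
        assert ours.loc["session", "F"] == \
            pytest.approx(theirs.loc["session", "F"], rel=1e-6)
        assert ours.loc["group:session", "F"] == \
            pytest.approx(theirs.loc["Interaction", "F"], rel=1e-6)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 500
        for r in range(reps):
            df = _make_rt_fixture(seed=1000 + r, effect=0.0, n=6)
            tab = ta.mixed_anova(df, "mean_rt_ms", "subject", "group",
                                 ["session", "trial_type"])
            p = tab.set_index("effect").loc["group:session", "p"]
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_design_errors(self):
        df = _make_rt_fixture(5)
        with pytest.raises(DataError):
            ta.mixed_anova(df.iloc[:-1], "mean_rt_ms", "subject", "group",
                           ["session", "trial_type"])
        solo = df[df["subject"].isin(["sham0", "active0"])]
        with pytest.raises(InferenceError):
            ta.mixed_anova(solo, "mean_rt_ms", "subject", "group",
                           ["session", "trial_type"])


class TestTTest:
    def test_identical_paired_samples(self):
        res = ta.ttest(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]),
                       mode="paired")
        assert res.t == 0.0 and res.p == 1.0 and res.cohen_d == 0.0

    def test_hand_worked_independent_fixture(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 5.0, 4.0, 6.0])
        # textbook formulas by hand
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * 0.5)
        res = ta.ttest(a, b, mode="independent")
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 6
        from scipy import stats as sps
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 6),
                                      abs=1e-12)
        assert res.cohen_d == pytest.approx(
            (a.mean() - b.mean()) / np.sqrt(sp2), abs=1e-12)

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(9), rng.standard_normal(9) + 0.5
        res = ta.ttest(a, b, mode="independent")
        ref = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        res = ta.ttest(a, b, mode="paired")
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)

    def test_power_at_large_effect(self):
        """d = 2 with n = 9/group: noncentral-t power says ~0.97+."""
        rng = np.random.default_rng(7)
        hits = sum(ta.ttest(rng.standard_normal(9) + 2.0,
                            rng.standard_normal(9),
                            mode="independent").p < 0.05
                   for _ in range(1000))
        assert hits / 1000 >= 0.95

    def test_zero_variance_zero_difference_convention(self):
        res = ta.ttest(np.ones(5), np.ones(5), mode="independent")
        assert res.t == 0.0 and res.p == 1.0


class TestAdjustPvalues:
    def test_holm_hand_worked(self):
        got = ta.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "holm")
        assert np.allclose(got, [0.04, 0.06, 0.06, 0.06])

    def test_bonferroni_with_family_size(self):
        assert ta.adjust_pvalues([0.02], "bonferroni", m=4) == \
            pytest.approx([0.08])

    def test_bh_hand_worked(self):
        got = ta.adjust_pvalues([0.01, 0.04], "bh_fdr", m=2)
        assert np.allclose(got, [0.02, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 20)
        for ours, theirs in [("bonferroni", "bonferroni"),
                             ("holm", "holm"), ("bh_fdr", "fdr_bh")]:
            got = ta.adjust_pvalues(p, ours)
            ref = multipletests(p, method=theirs)[1]
            assert np.allclose(got, ref)

    def test_order_invariants(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 15)
        holm = ta.adjust_pvalues(p, "holm")
        bonf = ta.adjust_pvalues(p, "bonferroni")
        bh = ta.adjust_pvalues(p, "bh_fdr")
        assert (holm >= p - 1e-15).all()
        assert (bh <= bonf + 1e-15).all()
        assert (holm <= bonf + 1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            ta.adjust_pvalues([0.5, 1.2], "holm")
        with pytest.raises(ConfigurationError):
            ta.adjust_pvalues([0.1, 0.2], "holm", m=1)


@pytest.fixture(scope="module")
def adjacency():
    return ta.build_adjacency()


LABELS = list(ta.CHANNELS_32)


class TestClusterPermutation:
    def test_single_supra_electrode_forms_no_cluster(self, adjacency):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((9, 32)) * 0.1
        b = rng.standard_normal((9, 32)) * 0.1
        a[:, LABELS.index("Cz")] += 10.0  # huge but isolated effect
        # neutralize Cz neighborhood so nothing else crosses threshold
        res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                     design="paired", n_perm=200, seed=0)
        assert all("Cz" not in c.electrodes or len(c.electrodes) >= 2
                   for c in res.clusters)
        assert not any(len(c.electrodes) < 2 for c in res.clusters)

    def test_planted_three_electrode_effect_detected(self, adjacency):
        """A d ~ 2 effect on three mutually adjacent electrodes is found
        in >= 90% of simulated experiments."""
        rng = np.random.default_rng(11)
        planted = ("O1", "PO3", "P3")
        idx = [LABELS.index(c) for c in planted]
        found = 0
        reps = 200
        for r in range(reps):
            a = rng.standard_normal((9, 32))
            b = rng.standard_normal((9, 32))
            a[:, idx] += 2.0
            res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                         design="paired", n_perm=200,
                                         seed=500 + r)
            sig = [c for c in res.clusters if c.p_perm < 0.05]
            if any(len(set(c.electrodes) & set(planted)) >= 2 for c in sig):
                found += 1
        assert found / reps >= 0.90

    def test_familywise_error_under_null(self, adjacency):
        rng = np.random.default_rng(12)
        false_pos = 0
        reps = 300
        for r in range(reps):
            a = rng.standard_normal((9, 32))
            b = rng.standard_normal((9, 32))
            res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                         design="paired", n_perm=200,
                                         seed=900 + r)
            false_pos += any(c.p_perm < 0.05 for c in res.clusters)
        assert false_pos / reps <= 0.07

    def test_independent_design_runs_and_detects(self, adjacency):
        rng = np.random.default_rng(13)
        planted = ("O1", "PO3", "P3")
        idx = [LABELS.index(c) for c in planted]
        a = rng.standard_normal((9, 32))
        b = rng.standard_normal((9, 32))
        a[:, idx] += 2.5
        res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                     design="independent", n_perm=500,
                                     seed=1)
        sig = [c for c in res.clusters if c.p_perm < 0.05]
        assert any(len(set(c.electrodes) & set(planted)) >= 2 for c in sig)

    def test_relabeling_invariance(self, adjacency):
        """A left-right mirror of the montage is a graph automorphism, so
        cluster p-values are unchanged after consistent relabeling."""
        mirror = {}
        for lab in LABELS:
            if lab.endswith("z"):
                mirror[lab] = lab
            else:
                head = lab.rstrip("0123456789")
                num = int(lab[len(head):])
                partner = num - 1 if num % 2 == 0 else num + 1
                mirror[lab] = f"{head}{partner}"
        rng = np.random.default_rng(14)
        a = rng.standard_normal((9, 32))
        b = rng.standard_normal((9, 32))
        a[:, [LABELS.index(c) for c in ("O1", "PO3", "P3")]] += 1.5
        res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                     design="paired", n_perm=300, seed=2)
        mirrored_labels = [mirror[l] for l in LABELS]
        res_m = ta.cluster_permutation(a, b, adjacency, mirrored_labels,
                                       design="paired", n_perm=300, seed=2)
        assert sorted(round(c.p_perm, 12) for c in res.clusters) == \
            sorted(round(c.p_perm, 12) for c in res_m.clusters)

    def test_pvalue_bounds_and_contracts(self, adjacency):
        rng = np.random.default_rng(15)
        a = rng.standard_normal((9, 32)) + 3.0
        b = rng.standard_normal((9, 32))
        res = ta.cluster_permutation(a, b, adjacency, LABELS,
                                     design="paired", n_perm=100, seed=3)
        for c in res.clusters:
            assert 1 / 101 <= c.p_perm <= 1.0
            assert len(c.electrodes) >= 2
        with pytest.raises(DataError):
            ta.cluster_permutation(a, b, adjacency, ["nope"] * 32,
                                   design="paired")
        with pytest.warns(UserWarning):
            ta.cluster_permutation(a, b, adjacency, LABELS,
                                   design="paired", n_perm=50, seed=4)


class TestMcNemar:
    def test_blinding_table_statistic(self):
        chi_sq, p = ta.mcnemar_cc((2, 6))
        assert chi_sq == pytest.approx(1.125, abs=1e-12)
        assert p == pytest.approx(0.289, abs=0.001)

    def test_symmetry_and_floor(self):
        assert ta.mcnemar_cc((6, 2))[0] == ta.mcnemar_cc((2, 6))[0]
        chi_sq, p = ta.mcnemar_cc((4, 4))
        assert chi_sq == 0.0 and p == 1.0
        chi_sq, _ = ta.mcnemar_cc((4, 5))  # |b-c| = 1 floors to zero
        assert chi_sq == 0.0

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(InferenceError):
            ta.mcnemar_cc((0, 0))

    def test_accepts_contingency_table(self):
        table = ta.generate_blinding_table(counts=(7, 2, 6, 3))
        assert ta.mcnemar_cc(table)[0] == pytest.approx(1.125)


class TestSensitivity:
    def test_printed_design_values(self):
        assert ta.min_detectable_d(9, alpha=0.05).d_min == \
            pytest.approx(1.41, abs=0.01)
        assert ta.min_detectable_d(9, alpha=0.0125).d_min == \
            pytest.approx(1.75, abs=0.01)

    def test_round_trip_power(self):
        for n, alpha in [(9, 0.05), (9, 0.0125), (20, 0.01)]:
            sol = ta.min_detectable_d(n, alpha=alpha)
            assert ta.two_sample_power(sol.d_min, n, alpha) == \
                pytest.approx(0.80, abs=1e-4)

    def test_large_n_normal_approximation(self):
        from scipy import stats as sps
        n = 10000
        sol = ta.min_detectable_d(n, alpha=0.05, power=0.80)
        approx = (sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) * np.sqrt(2 / n)
        assert sol.d_min == pytest.approx(approx, rel=0.01)

    def test_matches_statsmodels_solver(self):
        from statsmodels.stats.power import TTestIndPower
        ref = TTestIndPower().solve_power(nobs1=9, alpha=0.05, power=0.80,
                                          ratio=1.0, alternative="two-sided")
        assert ta.min_detectable_d(9).d_min == pytest.approx(ref, abs=1e-4)

    def test_monotonicities(self):
        d_small_n = ta.min_detectable_d(6).d_min
        d_big_n = ta.min_detectable_d(30).d_min
        assert d_big_n < d_small_n
        assert ta.min_detectable_d(9, power=0.9).d_min > \
            ta.min_detectable_d(9, power=0.8).d_min
        assert ta.min_detectable_d(9, alpha=0.01).d_min > \
            ta.min_detectable_d(9, alpha=0.05).d_min

    def test_infeasible_requests_rejected(self):
        with pytest.raises(ConfigurationError):
            ta.min_detectable_d(9, alpha=0.5, power=0.4)
        with pytest.raises(InferenceError):
            ta.min_detectable_d(1)
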