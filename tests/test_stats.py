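"""Mixed ANOVA, sphericity machinery, planned contrasts and simple tests."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from femgpipe import stats as fst
from femgpipe.types import EMOTIONS
from conftest import make_binned_frame


def _random_y(rng, n_per_group=4, E=6, T=6, subj_sd=1.0):
    n = 2 * n_per_group
    subj = rng.normal(0, subj_sd, size=(n, 1, 1))
    return subj + rng.standard_normal((n, E, T))


def brute_force_anova(y, n_per_group):
    """Independent cell-means oracle: explicit loops over marginal means."""
    n, E, T = y.shape
    k = 2
    g_of = [0 if i < n_per_group else 1 for i in range(n)]
    grand = y.mean()
    ss = {}
    m_g = [np.mean([y[i] for i in range(n) if g_of[i] == g]) for g in range(k)]
    ss["Group"] = n_per_group * E * T * sum((m - grand) ** 2 for m in m_g)
    m_s = [y[i].mean() for i in range(n)]
    ss["S"] = E * T * sum((m_s[i] - m_g[g_of[i]]) ** 2 for i in range(n))
    m_e = [y[:, e, :].mean() for e in range(E)]
    ss["Emotion"] = n * T * sum((m - grand) ** 2 for m in m_e)
    m_ge = [[np.mean([y[i, e, :] for i in range(n) if g_of[i] == g]) for e in range(E)]
            for g in range(k)]
    ss["EmotionxGroup"] = n_per_group * T * sum(
        (m_ge[g][e] - m_g[g] - m_e[e] + grand) ** 2 for g in range(k) for e in range(E))
    m_se = [[y[i, e, :].mean() for e in range(E)] for i in range(n)]
    ss["ES"] = T * sum((m_se[i][e] - m_s[i] - m_ge[g_of[i]][e] + m_g[g_of[i]]) ** 2
                       for i in range(n) for e in range(E))
    m_t = [y[:, :, t].mean() for t in range(T)]
    ss["Time"] = n * E * sum((m - grand) ** 2 for m in m_t)
    m_gt = [[np.mean([y[i, :, t] for i in range(n) if g_of[i] == g]) for t in range(T)]
            for g in range(k)]
    ss["TimexGroup"] = n_per_group * E * sum(
        (m_gt[g][t] - m_g[g] - m_t[t] + grand) ** 2 for g in range(k) for t in range(T))
    m_st = [[y[i, :, t].mean() for t in range(T)] for i in range(n)]
    ss["TS"] = E * sum((m_st[i][t] - m_s[i] - m_gt[g_of[i]][t] + m_g[g_of[i]]) ** 2
                       for i in range(n) for t in range(T))
    m_et = [[y[:, e, t].mean() for t in range(T)] for e in range(E)]
    ss["EmotionxTime"] = n * sum((m_et[e][t] - m_e[e] - m_t[t] + grand) ** 2
                                 for e in range(E) for t in range(T))
    m_get = [[[np.mean([y[i, e, t] for i in range(n) if g_of[i] == g])
               for t in range(T)] for e in range(E)] for g in range(k)]
    ss["EmotionxTimexGroup"] = n_per_group * sum(
        (m_get[g][e][t] - m_ge[g][e] - m_gt[g][t] - m_et[e][t]
         + m_g[g] + m_e[e] + m_t[t] - grand) ** 2
        for g in range(k) for e in range(E) for t in range(T))
    ss_total = ((y - grand) ** 2).sum()
    ss["ETS"] = ss_total - sum(ss.values())
    return ss


class TestMixedAnova:
    def test_all_ss_match_first_principles_oracle(self):
        rng = np.random.default_rng(0)
        y = _random_y(rng, n_per_group=2)
        res = fst.mixed_anova(make_binned_frame(y, 2))
        oracle = brute_force_anova(y, 2)
        # effect SS recovered from the table as MS * df (GG cancels)
        tab = res.table.set_index("effect")
        for name, key in [("Group", "Group"), ("Emotion", "Emotion"),
                          ("Emotion x Group", "EmotionxGroup"),
                          ("Time", "Time"), ("Time x Group", "TimexGroup"),
                          ("Emotion x Time", "EmotionxTime"),
                          ("Emotion x Time x Group", "EmotionxTimexGroup")]:
            got = tab.loc[name, "MS"] * tab.loc[name, "df"]
            assert got == pytest.approx(oracle[key], rel=1e-9), name
        assert res.strata["between"].ss_err == pytest.approx(oracle["S"], rel=1e-9)
        assert res.strata["emotion"].ss_err == pytest.approx(oracle["ES"], rel=1e-9)
        assert res.strata["time"].ss_err == pytest.approx(oracle["TS"], rel=1e-9)
        assert res.strata["emotion_x_time"].ss_err == pytest.approx(oracle["ETS"], rel=1e-9)

    def test_ss_decomposition_is_complete(self):
        rng = np.random.default_rng(1)
        y = _random_y(rng, n_per_group=5)
        res = fst.mixed_anova(make_binned_frame(y, 5))
        tab = res.table
        eff = tab[tab["F"].notna()]
        ss_effects = float((eff["MS"] * eff["df"]).sum())
        ss_errors = sum(s.ss_err for s in res.strata.values())
        ss_total = ((y - y.mean()) ** 2).sum()
        assert ss_effects + ss_errors == pytest.approx(ss_total, rel=1e-8)

    def test_identical_group_cell_means_give_zero_group_f(self):
        rng = np.random.default_rng(2)
        half = rng.standard_normal((4, 6, 6))
        y = np.concatenate([half, half])  # mirrored groups
        res = fst.mixed_anova(make_binned_frame(y, 4))
        assert res.table.set_index("effect").loc["Group", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_f_invariant_to_shift_and_scale(self):
        rng = np.random.default_rng(3)
        y = _random_y(rng, n_per_group=4)
        f0 = fst.mixed_anova(make_binned_frame(y, 4)).table["F"].to_numpy()
        f1 = fst.mixed_anova(make_binned_frame(y + 100.0, 4)).table["F"].to_numpy()
        f2 = fst.mixed_anova(make_binned_frame(y * 7.0, 4)).table["F"].to_numpy()
        assert np.allclose(f0, f1, rtol=1e-8, equal_nan=True)
        assert np.allclose(f0, f2, rtol=1e-8, equal_nan=True)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(4)
        y = _random_y(rng, n_per_group=3)
        frame = make_binned_frame(y, 3)
        frame = frame[frame["participant"] != "P000"]
        with pytest.raises(ValueError, match="balanced"):
            fst.mixed_anova(frame)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_agreement_with_pingouin_on_marginalized_designs(self, seed):
        # pingouin's mixed ANOVA handles one within factor; averaging a
        # balanced design over the other within factor leaves the
        # remaining strata's F tests unchanged, giving an independent
        # cross-check of Group, Emotion and Emotion x Group (and Time).
        rng = np.random.default_rng(seed)
        y = _random_y(rng, n_per_group=6)
        res = fst.mixed_anova(make_binned_frame(y, 6))
        tab = res.table.set_index("effect")

        for axis, factor in ((2, "Emotion"), (1, "Time")):
            avg = y.mean(axis=axis)
            long = []
            for i in range(12):
                for j in range(6):
                    long.append((f"P{i:03d}", "hnssi" if i < 6 else "control",
                                 j, avg[i, j]))
            df = pd.DataFrame(long, columns=["subject", "group", "level", "value"])
            pgt = pg.mixed_anova(df, dv="value", within="level",
                                 subject="subject", between="group").set_index("Source")
            # uncorrected F values; undo any GG df correction in our table
            s = res.strata[factor.lower()]
            factor_f = tab.loc[factor, "F"]
            inter_f = tab.loc[f"{factor} x Group", "F"]
            assert factor_f == pytest.approx(pgt.loc["level", "F"], abs=1e-6)
            assert inter_f == pytest.approx(pgt.loc["Interaction", "F"], abs=1e-6)
            assert tab.loc["Group", "F"] == pytest.approx(pgt.loc["group", "F"], abs=1e-6)
            assert s.df_err == pytest.approx(pgt.loc["level", "DF2"])


class TestSphericity:
    def test_compound_symmetry_satisfies_sphericity(self):
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 3.0, size=(40, 1))
        X = subj + rng.standard_normal((40, 6))
        res = fst.mauchly_test(X)
        assert res.W > 0.5
        assert res.pval > 0.2
        assert res.epsilon > 0.8

    def test_two_conditions_vacuously_spherical(self):
        rng = np.random.default_rng(6)
        res = fst.mauchly_test(rng.standard_normal((10, 2)))
        assert res.W == 1.0 and res.epsilon == 1.0 and res.pval == 1.0

    def test_matches_pingouin_w_chi2_and_epsilon(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 6)) @ rng.standard_normal((6, 6))
        mine = fst.mauchly_test(X)
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(6)])
        df["subject"] = range(10)
        long = df.melt(id_vars="subject", var_name="cond", value_name="y")
        ref = pg.sphericity(long, dv="y", within="cond", subject="subject")
        assert mine.W == pytest.approx(ref.W, rel=1e-9)
        assert mine.chi2 == pytest.approx(ref.chi2, rel=1e-9)
        assert mine.df == ref.dof
        eps_ref = pg.epsilon(long, dv="y", within="cond", subject="subject",
                             correction="gg")
        assert mine.epsilon == pytest.approx(eps_ref, rel=1e-9)

    def test_singular_covariance_reports_w_zero(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 6))  # fewer subjects than conditions
        with pytest.warns(UserWarning, match="singular"):
            res = fst.mauchly_test(X)
        assert res.W == 0.0


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        cov = 0.4 * np.ones((6, 6)) + 0.6 * np.eye(6)
        assert fst.gg_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_covariance_hits_lower_bound(self):
        v = np.arange(1.0, 7.0)[:, None]
        cov = v @ v.T
        assert fst.gg_epsilon(cov) == pytest.approx(1.0 / 5.0, rel=1e-6)

    def test_matches_direct_eigenvalue_formula(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((6, 6))
        cov = A @ A.T
        C = fst.orthonormal_contrasts(6)
        lam = np.linalg.eigvalsh(C.T @ cov @ C)
        expected = lam.sum() ** 2 / (5 * (lam**2).sum())
        assert fst.gg_epsilon(cov) == pytest.approx(expected, rel=1e-10)


class TestPlannedContrast:
    def test_null_contrast_is_zero(self):
        rng = np.random.default_rng(10)
        half = rng.standard_normal((4, 6, 6))
        y = np.concatenate([half, half])
        res = fst.mixed_anova(make_binned_frame(y, 4))
        c = fst.planned_group_contrast(res, "anger")
        assert c.F == pytest.approx(0.0, abs=1e-18)
        assert c.r == pytest.approx(0.0, abs=1e-9)

    def test_r_f_round_trip(self):
        rng = np.random.default_rng(11)
        y = _random_y(rng, n_per_group=5)
        res = fst.mixed_anova(make_binned_frame(y, 5))
        for emo in EMOTIONS:
            c = fst.planned_group_contrast(res, emo)
            back = c.df_err * c.r**2 / (1.0 - c.r**2)
            assert back == pytest.approx(c.F, rel=1e-9)
            assert c.df_err == res.strata["emotion_x_time"].df_err_eff

    def test_unknown_emotion_rejected(self):
        rng = np.random.default_rng(12)
        res = fst.mixed_anova(make_binned_frame(_random_y(rng), 4))
        with pytest.raises(ValueError):
            fst.planned_group_contrast(res, "boredom")

    def test_type_one_error_calibrated_on_null_binned_data(self):
        # no group effect, iid cells: the anger contrast should reject at
        # the nominal 5% rate
        rng = np.random.default_rng(2024)
        n_sims, rej = 400, 0
        for _ in range(n_sims):
            y = rng.standard_normal((12, 6, 6))
            res = fst.mixed_anova(make_binned_frame(y, 6))
            rej += fst.planned_group_contrast(res, "anger").p < 0.05
        assert 0.03 <= rej / n_sims <= 0.07


class TestSimpleTests:
    def test_perfect_linear_correlation(self):
        x = np.arange(10.0)
        res = fst.pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_two_tailed_p_from_r_at_n30(self):
        assert round(fst.correlation_pvalue(0.375, 30), 2) == 0.04
        assert round(fst.correlation_pvalue(-0.361, 30), 2) == 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fst.pearson_correlation(np.ones(10), np.arange(10.0))

    def test_identical_samples_t_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = fst.independent_t_test(a, a.copy())
        assert res.t == 0.0 and res.p == 1.0

    def test_t_matches_textbook_formula(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.4
        res = fst.independent_t_test(a, b)
        sp = np.sqrt(((11 * a.var(ddof=1)) + (14 * b.var(ddof=1))) / 25)
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 12 + 1 / 15))
        assert res.t == pytest.approx(expected, rel=1e-12)
        assert res.df == 25

    def test_p_formatting(self):
        assert fst.format_p(0.0004) == "<0.001"
        assert fst.format_p(0.0492) == "0.049"
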