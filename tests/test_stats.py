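"""ANOVA layer: one-way, mixed repeated-measures, GG epsilon, pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sct

from stresslab.stats import (
    bonferroni_pairwise,
    gg_epsilon,
    mixed_rm_anova,
    oneway_anova,
)


# ---------------------------------------------------------------------------
# loop-based enumeration oracle for the mixed design (independent of the
# vectorized implementation: every sum of squares written out cell by cell)


def brute_force_mixed(df, dv, subject, between, w1, w2=None):
    subs = sorted(df[subject].unique())
    groups = {s: df[df[subject] == s][between].iloc[0] for s in subs}
    glev = sorted(set(groups.values()))
    b_lev = sorted(df[w1].unique())
    c_lev = sorted(df[w2].unique()) if w2 else [None]

    def cell(s, j, k):
        sel = (df[subject] == s) & (df[w1] == j)
        if w2:
            sel &= (df[w2] == k)
        return float(df[sel][dv].iloc[0])

    Y = {(s, j, k): cell(s, j, k) for s in subs for j in b_lev for k in c_lev}
    n = len(subs) // len(glev)
    b, c, N = len(b_lev), len(c_lev), len(subs)
    gm = np.mean(list(Y.values()))

    def m_subj(s):
        return np.mean([Y[s, j, k] for j in b_lev for k in c_lev])

    def m_group(g):
        return np.mean([Y[s, j, k] for s in subs if groups[s] == g
                        for j in b_lev for k in c_lev])

    def m_w1(j):
        return np.mean([Y[s, j, k] for s in subs for k in c_lev])

    def m_gw1(g, j):
        return np.mean([Y[s, j, k] for s in subs if groups[s] == g for k in c_lev])

    def m_sw1(s, j):
        return np.mean([Y[s, j, k] for k in c_lev])

    ss = {}
    ss_total = sum((v - gm) ** 2 for v in Y.values())
    ss_subj = b * c * sum((m_subj(s) - gm) ** 2 for s in subs)
    ss[between] = n * b * c * sum((m_group(g) - gm) ** 2 for g in glev)
    ss["s(a)"] = ss_subj - ss[between]
    ss[w1] = N * c * sum((m_w1(j) - gm) ** 2 for j in b_lev)
    ss[f"{between}*{w1}"] = n * c * sum(
        (m_gw1(g, j) - m_group(g) - m_w1(j) + gm) ** 2 for g in glev for j in b_lev)
    ss["w1*s(a)"] = c * sum(
        (m_sw1(s, j) - m_subj(s) - m_gw1(groups[s], j) + m_group(groups[s])) ** 2
        for s in subs for j in b_lev)
    if w2 is None:
        return ss, ss_total

    def m_w2(k):
        return np.mean([Y[s, j, k] for s in subs for j in b_lev])

    def m_gw2(g, k):
        return np.mean([Y[s, j, k] for s in subs if groups[s] == g for j in b_lev])

    def m_sw2(s, k):
        return np.mean([Y[s, j, k] for j in b_lev])

    def m_w12(j, k):
        return np.mean([Y[s, j, k] for s in subs])

    def m_gw12(g, j, k):
        return np.mean([Y[s, j, k] for s in subs if groups[s] == g])

    ss[w2] = N * b * sum((m_w2(k) - gm) ** 2 for k in c_lev)
    ss[f"{between}*{w2}"] = n * b * sum(
        (m_gw2(g, k) - m_group(g) - m_w2(k) + gm) ** 2 for g in glev for k in c_lev)
    ss["w2*s(a)"] = b * sum(
        (m_sw2(s, k) - m_subj(s) - m_gw2(groups[s], k) + m_group(groups[s])) ** 2
        for s in subs for k in c_lev)
    ss[f"{w1}*{w2}"] = N * sum(
        (m_w12(j, k) - m_w1(j) - m_w2(k) + gm) ** 2 for j in b_lev for k in c_lev)
    ss[f"{between}*{w1}*{w2}"] = n * sum(
        (m_gw12(g, j, k) - m_gw1(g, j) - m_gw2(g, k) - m_w12(j, k)
         + m_group(g) + m_w1(j) + m_w2(k) - gm) ** 2
        for g in glev for j in b_lev for k in c_lev)
    ss["w12*s(a)"] = (ss_total - ss_subj - ss[w1] - ss[f"{between}*{w1}"]
                      - ss["w1*s(a)"] - ss[w2] - ss[f"{between}*{w2}"]
                      - ss["w2*s(a)"] - ss[f"{w1}*{w2}"]
                      - ss[f"{between}*{w1}*{w2}"])
    return ss, ss_total


def _long(rng, n_per_group, b, c=None, effect=None):
    rows = []
    for gi, g in enumerate(["g1", "g2"]):
        for s in range(n_per_group):
            sid = f"{g}s{s}"
            intercept = rng.normal(0, 1)
            for j in range(b):
                for k in range(c) if c else [None]:
                    val = intercept + rng.normal(0, 1)
                    if effect:
                        val += effect(gi, j, k)
                    row = {"participant_id": sid, "group": g, "w1": f"b{j}",
                           "value": val}
                    if c:
                        row["w2"] = f"c{k}"
                    rows.append(row)
    return pd.DataFrame(rows)


class TestOneWay:
    def test_hand_computed_sums_of_squares(self):
        res = oneway_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert res.df == (1, 4)
        assert res.eta_sq == pytest.approx(13.5 / 17.5, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        a, b, c = rng.standard_normal((3, 15))
        res = oneway_anova({"a": a, "b": b + 0.5, "c": c})
        F, p = sct.f_oneway(a, b + 0.5, c)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_identical_means_give_zero_F(self):
        res = oneway_anova({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert res.F == 0.0

    def test_zero_within_variance_flagged_infinite(self):
        res = oneway_anova({"a": [1, 1, 1], "b": [2, 2, 2]})
        assert np.isinf(res.F) and res.p == 0.0 and res.degenerate

    def test_input_validation(self):
        with pytest.raises(ValueError):
            oneway_anova({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            oneway_anova({"a": [1], "b": [2, 3]})


class TestGGEpsilon:
    def test_two_levels_always_one(self, rng):
        A = rng.standard_normal((2, 2))
        assert gg_epsilon(A @ A.T + np.eye(2)) == 1.0

    def test_compound_symmetry_gives_one(self):
        k, s2, rho = 5, 2.0, 0.6
        S = s2 * (rho * np.ones((k, k)) + (1 - rho) * np.eye(k))
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_gives_lower_bound(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert gg_epsilon(np.outer(v, v)) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_singular_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="singular"):
            eps = gg_epsilon(np.zeros((4, 4)))
        assert eps == pytest.approx(1.0 / 3.0)

    def test_estimated_epsilon_near_one_under_cs(self, rng):
        k, n = 4, 120
        X = rng.standard_normal((n, 1)) + 0.8 * rng.standard_normal((n, k))
        assert gg_epsilon(np.cov(X.T)) > 0.9


class TestMixedAnova:
    def test_one_within_matches_bruteforce(self, rng):
        df = _long(rng, n_per_group=4, b=3)
        res = mixed_rm_anova(df, "value", "participant_id", "group", "w1")
        ss, ss_total = brute_force_mixed(df, "value", "participant_id", "group", "w1")
        t = res.table.set_index("effect")
        for eff, key in [("group", "group"), ("w1", "w1"), ("group*w1", "group*w1")]:
            assert t.loc[eff, "ss"] == pytest.approx(ss[key], abs=1e-8)
        # error strata
        assert t.loc["group", "ms_error"] * t.loc["group", "df2"] == \
            pytest.approx(ss["s(a)"], abs=1e-8)
        assert t.loc["w1", "ms_error"] * t.loc["w1", "df2"] == \
            pytest.approx(ss["w1*s(a)"], abs=1e-8)

    def test_two_within_toy_matches_bruteforce(self, rng):
        df = _long(rng, n_per_group=3, b=2, c=3)
        res = mixed_rm_anova(df, "value", "participant_id", "group", ["w1", "w2"])
        ss, ss_total = brute_force_mixed(df, "value", "participant_id", "group",
                                         "w1", "w2")
        t = res.table.set_index("effect")
        for eff in ("group", "w1", "group*w1", "w2", "group*w2", "w1*w2",
                    "group*w1*w2"):
            assert t.loc[eff, "ss"] == pytest.approx(ss[eff], abs=1e-8), eff
        assert t.loc["w1*w2", "ms_error"] * t.loc["w1*w2", "df2"] == \
            pytest.approx(ss["w12*s(a)"], abs=1e-8)
        # eta-squared identities
        for eff in ("group", "w1", "w1*w2"):
            assert t.loc[eff, "eta_sq"] == pytest.approx(ss[eff] / ss_total, abs=1e-10)

    def test_agrees_with_pingouin_one_within(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = _long(rng, n_per_group=8, b=5,
                   effect=lambda gi, j, k: 0.3 * gi * j)
        res = mixed_rm_anova(df, "value", "participant_id", "group", "w1")
        pg = pingouin.mixed_anova(data=df, dv="value", within="w1",
                                  subject="participant_id", between="group",
                                  correction=True).set_index("Source")
        t = res.table.set_index("effect")
        assert t.loc["group", "F"] == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert t.loc["w1", "F"] == pytest.approx(pg.loc["w1", "F"], rel=1e-6)
        assert t.loc["group*w1", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6)
        # epsilon: pingouin uses the total covariance, this package pools
        # within groups (the classical mixed-design convention); the two
        # coincide when the groups do not differ
        df0 = _long(np.random.default_rng(7), n_per_group=40, b=5)
        res0 = mixed_rm_anova(df0, "value", "participant_id", "group", "w1")
        pg0 = pingouin.mixed_anova(data=df0, dv="value", within="w1",
                                   subject="participant_id", between="group",
                                   correction=True).set_index("Source")
        assert res0.table.set_index("effect").loc["w1", "epsilon"] == \
            pytest.approx(float(pg0.loc["w1", "eps"]), rel=0.01)

    def test_constant_within_levels_give_zero_within_F(self, rng):
        rows = []
        for g in ("g1", "g2"):
            for s in range(4):
                v = rng.normal()
                for j in range(3):
                    rows.append({"participant_id": f"{g}{s}", "group": g,
                                 "w1": f"b{j}", "value": v})
        res = mixed_rm_anova(pd.DataFrame(rows), "value", "participant_id",
                             "group", "w1")
        t = res.table.set_index("effect")
        assert t.loc["w1", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_gg_correction_bounds_and_df(self, rng):
        df = _long(rng, n_per_group=6, b=4, c=5)
        res = mixed_rm_anova(df, "value", "participant_id", "group", ["w1", "w2"])
        t = res.table.set_index("effect")
        for eff, k in [("w1", 4), ("w2", 5)]:
            eps = t.loc[eff, "epsilon"]
            assert 1.0 / (k - 1) <= eps <= 1.0
            assert t.loc[eff, "df1_gg"] == pytest.approx(eps * t.loc[eff, "df1"])
        assert np.isnan(t.loc["group", "epsilon"])

    def test_unbalanced_rejected(self, rng):
        df = _long(rng, n_per_group=3, b=3)
        with pytest.raises(ValueError, match="missing within cells"):
            mixed_rm_anova(df.iloc[:-1], "value", "participant_id", "group", "w1")

    def test_duplicate_cell_rejected(self, rng):
        df = _long(rng, n_per_group=3, b=3)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="exactly once"):
            mixed_rm_anova(dup, "value", "participant_id", "group", "w1")

    def test_missing_value_rejected(self, rng):
        df = _long(rng, n_per_group=3, b=3)
        df.loc[0, "value"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            mixed_rm_anova(df, "value", "participant_id", "group", "w1")


class TestBonferroniPairwise:
    @staticmethod
    def _df(rng):
        return _long(rng, n_per_group=6, b=2)

    def test_single_contrast_unadjusted(self, rng):
        df = self._df(rng)
        out = bonferroni_pairwise(df, "value", "participant_id", [
            {"cell": {"w1": "b0"}, "factor": "group", "levels": ("g1", "g2"),
             "kind": "between"}])
        assert out.loc[0, "p_bonf"] == pytest.approx(out.loc[0, "p_raw"])

    def test_family_multiplication(self):
        # m = 10 contrasts, so p_adj = 10 * p_raw (capped at 1)
        rng = np.random.default_rng(0)
        df = _long(rng, n_per_group=8, b=5)
        contrasts = [{"cell": {"w1": f"b{j}"}, "factor": "group",
                      "levels": ("g1", "g2"), "kind": "between"} for j in range(5)]
        contrasts += [{"cell": {"group": "g1"}, "factor": "w1",
                       "levels": ("b0", f"b{j}"), "kind": "within"}
                      for j in range(1, 6) if j < 5] + [
                      {"cell": {"group": "g2"}, "factor": "w1",
                       "levels": ("b0", "b1"), "kind": "within"}]
        out = bonferroni_pairwise(df, "value", "participant_id", contrasts)
        assert len(out) == 10
        expected = np.minimum(1.0, 10 * out["p_raw"])
        assert np.allclose(out["p_bonf"], expected)

    def test_identical_paired_samples_p_one(self, rng):
        df = self._df(rng)
        df["value"] = df.groupby("participant_id")["value"].transform("mean")
        out = bonferroni_pairwise(df, "value", "participant_id", [
            {"cell": {"group": "g1"}, "factor": "w1", "levels": ("b0", "b1"),
             "kind": "within"}])
        assert out.loc[0, "mean_diff"] == pytest.approx(0.0)
        assert out.loc[0, "p_raw"] == 1.0

    def test_empty_cell_named_in_error(self, rng):
        df = self._df(rng)
        with pytest.raises(ValueError, match="empty cell"):
            bonferroni_pairwise(df, "value", "participant_id", [
                {"cell": {"w1": "nope"}, "factor": "group",
                 "levels": ("g1", "g2"), "kind": "between"}])
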