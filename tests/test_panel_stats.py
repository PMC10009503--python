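"""Paired tests, ANOVA post-hocs, letter displays, and regressions,
each checked against an independent closed-form or brute-force oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from povdyn import (anova_posthoc, asset_income_regression,
                    compact_letter_display, education_income_analysis,
                    mcnemar_paired, wilcoxon_strata_movement)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def _paired_status(b, c, a=30, d=30):
    """Paired booleans with given concordant/discordant cell counts."""
    s1 = [True] * a + [True] * b + [False] * c + [False] * d
    s2 = [True] * a + [False] * b + [True] * c + [False] * d
    return s1, s2


def binomial_two_sided(b, c):
    """Brute-force two-sided binomial tail for the exact McNemar test:
    P(X <= min(b,c)) + P(X >= max(b,c)) with X ~ Binom(b+c, 1/2)."""
    n = b + c
    k = min(b, c)
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    p = sum(pmf[: k + 1]) + sum(pmf[n - k:])
    return min(p, 1.0)


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        res = mcnemar_paired(*_paired_status(b=5, c=5), exact=False)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_closed_form(self):
        res = mcnemar_paired(*_paired_status(b=30, c=12), exact=False)
        assert res.statistic == pytest.approx((30 - 12) ** 2 / 42)

    def test_chi2_matches_b10_c2(self):
        res = mcnemar_paired(*_paired_status(b=10, c=2), exact=False)
        assert res.statistic == pytest.approx(64 / 12)
        assert res.p_value == pytest.approx(stats.chi2.sf(64 / 12, 1))

    def test_exact_variant_matches_binomial_tails(self):
        for b in range(0, 13):
            for c in range(0, 13 - b):
                if b + c == 0:
                    continue
                res = mcnemar_paired(*_paired_status(b=b, c=c), exact=True)
                assert res.p_value == pytest.approx(binomial_two_sided(b, c)), \
                    (b, c)

    def test_exact_selected_below_25_discordant(self):
        assert mcnemar_paired(*_paired_status(b=12, c=12)).test == \
            "mcnemar_exact"
        assert mcnemar_paired(*_paired_status(b=13, c=12)).test == \
            "mcnemar_chi2"

    def test_no_discordance_is_degenerate(self):
        res = mcnemar_paired([True, False], [True, False])
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

def wilcoxon_brute_force(diffs):
    """Full 2^n sign enumeration with average ranks; two-sided p for the
    statistic min(T+, T-)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
    hits = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        tp = ranks[np.array(signs) > 0].sum()
        if min(tp, total - tp) <= obs + 1e-12:
            hits += 1
    return hits / 2 ** len(d)


class TestWilcoxon:
    def test_perfectly_symmetric_movement_is_null(self):
        # mirrored moves: +1, -1, +2, -2 (and one stayer, dropped)
        codes1 = [1, 2, 1, 3, 2]
        codes2 = [2, 1, 3, 1, 2]
        res = wilcoxon_strata_movement(codes1, codes2)
        assert res.p_value == pytest.approx(1.0)

    def test_all_upward_movers_highly_significant(self):
        codes1 = [1] * 10 + [2] * 10
        codes2 = [2] * 10 + [3] * 10
        res = wilcoxon_strata_movement(codes1, codes2)
        assert res.p_value < 1e-3
        assert res.estimates["movement"] == {"up": 20, "down": 0}

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(12):
            n = int(rng.integers(5, 13))
            d = rng.choice([-2, -1, 1, 2], size=n)
            codes1 = np.full(n, 2)
            codes2 = codes1 + d
            res = wilcoxon_strata_movement(codes1, codes2)
            assert res.test == "wilcoxon_signed_rank_exact"
            assert res.p_value == pytest.approx(wilcoxon_brute_force(d)), d

    def test_no_movement_is_degenerate(self):
        res = wilcoxon_strata_movement([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0


# ---------------------------------------------------------------------------
# ANOVA + post-hoc letters
# ---------------------------------------------------------------------------

def anova_f_by_sums(samples):
    """Definitional F: between-group MS over within-group MS."""
    all_values = np.concatenate(samples)
    grand = all_values.mean()
    k = len(samples)
    n = len(all_values)
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestAnovaPosthoc:
    def test_identical_groups_share_one_letter(self):
        values = [5.0, 5.0, 5.0] * 3
        labels = ["a_grp"] * 3 + ["b_grp"] * 3 + ["c_grp"] * 3
        res = anova_posthoc(values, labels)
        assert set(res.letters.values()) == {"a"}
        assert res.degenerate

    def test_f_matches_definitional_sums_on_3x5_fixture(self):
        samples = [np.array([3.1, 4.2, 2.8, 3.9, 3.5]),
                   np.array([5.0, 5.5, 4.8, 6.1, 5.2]),
                   np.array([7.9, 8.3, 7.1, 8.8, 7.5])]
        values = np.concatenate(samples)
        labels = ["g1"] * 5 + ["g2"] * 5 + ["g3"] * 5
        res = anova_posthoc(values, labels, method="tukey_hsd")
        assert res.statistic == pytest.approx(anova_f_by_sums(samples))

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 12),
                                 rng.normal(2, 1, 10)])
        labels = np.array(["g1"] * 8 + ["g2"] * 12 + ["g3"] * 10)
        res = anova_posthoc(values, labels, method="tukey_hsd")
        sm = pairwise_tukeyhsd(values, labels, alpha=0.05)
        ours = res.pairwise.sort_values(["group1", "group2"])
        np.testing.assert_allclose(ours["p_value"].to_numpy(),
                                   sm.pvalues, atol=1e-6)

    def test_lsd_flags_at_least_what_tukey_flags(self):
        """Fisher LSD is less conservative than Tukey HSD on any dataset."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            k = int(rng.integers(3, 6))
            samples, labels = [], []
            for g in range(k):
                n = int(rng.integers(3, 12))
                samples.append(rng.normal(rng.normal(0, 1), 1, n))
                labels += [f"g{g}"] * n
            values = np.concatenate(samples)
            tukey = anova_posthoc(values, labels, method="tukey_hsd")
            lsd = anova_posthoc(values, labels, method="fisher_lsd")
            t_sig = {(r.group1, r.group2) for r in tukey.pairwise.itertuples()
                     if r.significant}
            l_sig = {(r.group1, r.group2) for r in lsd.pairwise.itertuples()
                     if r.significant}
            assert t_sig <= l_sig

    def test_letters_cover_every_group_and_match_significance(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(0.2, 1, 10),
                                 rng.normal(4, 1, 10)])
        labels = np.array(["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10)
        res = anova_posthoc(values, labels)
        assert all(res.letters[g] for g in res.groups)
        for row in res.pairwise.itertuples():
            shared = set(res.letters[row.group1].split(",")) & \
                set(res.letters[row.group2].split(","))
            assert bool(shared) == (not row.significant)


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        assert compact_letter_display(["x", "y", "z"], set()) == \
            {"x": "a", "y": "a", "z": "a"}

    def test_chain_structure(self):
        # A differs from C only: A=a, B=ab, C=b
        out = compact_letter_display(["A", "B", "C"], {("A", "C")})
        assert out == {"A": "a", "B": "a,b", "C": "b"}

    def test_all_pairs_differ(self):
        out = compact_letter_display(["A", "B", "C"],
                                     {("A", "B"), ("A", "C"), ("B", "C")})
        assert sorted(out.values()) == ["a", "b", "c"]


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

class TestRegression:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"land": rng.lognormal(0, 0.5, 50),
                          "tlu": rng.lognormal(0.5, 0.5, 50),
                          "off_farm": rng.lognormal(4, 1, 50)})
        y = 2.0 * X["land"]
        fit = asset_income_regression(y, X)
        assert fit.params["land"] == pytest.approx(2.0, abs=1e-6)
        assert fit.params["tlu"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["off_farm"] == pytest.approx(0.0, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(7)
        land = rng.lognormal(0, 0.5, 40)
        X = pd.DataFrame({"land": land, "land_twice": 2 * land,
                          "tlu": rng.lognormal(0, 0.5, 40)})
        with pytest.raises(ValueError, match="land"):
            asset_income_regression(rng.normal(0, 1, 40), X)

    def test_permuted_outcome_breaks_significance(self):
        rng = np.random.default_rng(8)
        n = 200
        X = pd.DataFrame({"land": rng.lognormal(0, 0.5, n),
                          "tlu": rng.lognormal(0.5, 0.6, n)})
        y = 400 * X["land"] + 150 * X["tlu"] + rng.normal(0, 300, n)
        assert asset_income_regression(y, X).pvalues["land"] < 1e-6
        p_perm = [asset_income_regression(rng.permutation(y.to_numpy()), X)
                  .pvalues["land"] for _ in range(50)]
        assert np.median(p_perm) > 0.05


class TestEducationIncome:
    def test_identical_distributions_do_not_separate(self):
        rng = np.random.default_rng(9)
        edu = np.repeat(["none", "primary", "secondary"], 40)
        # literally identical income distribution in every level
        income = np.tile(rng.normal(500, 100, 40), 3)
        res = education_income_analysis(edu, income, income)
        for key in ("farm_income", "off_farm_income"):
            assert len(set(res[key].letters.values())) == 1

    def test_designed_monotone_effect_separates_extremes(self):
        rng = np.random.default_rng(10)
        levels = ["none", "primary", "secondary", "post-secondary"]
        edu = np.repeat(levels, 100)
        offfarm = np.concatenate([
            rng.normal(mu, 150, 100) for mu in (100, 300, 600, 1000)])
        farm = rng.normal(500, 100, 400)
        res = education_income_analysis(edu, farm, offfarm)
        letters = res["off_farm_income"].letters
        assert not (set(letters["none"].split(","))
                    & set(letters["post-secondary"].split(",")))

    def test_single_level_skipped(self):
        res = education_income_analysis(["primary"] * 10,
                                        np.arange(10.0), np.arange(10.0))
        assert res["farm_income"] is None

    def test_invariant_to_order_preserving_relabel(self):
        rng = np.random.default_rng(11)
        edu = np.repeat(["1_low", "2_mid", "3_high"], 50)
        income = np.concatenate([rng.normal(mu, 50, 50)
                                 for mu in (100, 200, 400)])
        res1 = education_income_analysis(edu, income, income)
        relabel = {"1_low": "a_none", "2_mid": "b_primary",
                   "3_high": "c_secondary"}
        res2 = education_income_analysis(
            np.vectorize(relabel.get)(edu), income, income)
        assert res1["farm_income"].p_value == pytest.approx(
            res2["farm_income"].p_value)
        l1 = [res1["farm_income"].letters[g] for g in
              ("1_low", "2_mid", "3_high")]
        l2 = [res2["farm_income"].letters[g] for g in
              ("a_none", "b_primary", "c_secondary")]
        assert l1 == l2
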