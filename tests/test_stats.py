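"""Tests of the association battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qmripath import (
    association_report,
    categorical_assoc,
    cohort_summary,
    kruskal_wallis,
    shapiro_wilk,
    spearman,
)


class TestShapiroWilk:
    def test_near_normal_sample(self):
        # normal scores of a perfect sample -> W close to 1
        v = sps.norm.ppf((np.arange(1, 51) - 0.375) / 50.25)
        w, p = shapiro_wilk(v)
        assert w > 0.99

    def test_bimodal_sample_rejected(self):
        v = np.concatenate([np.linspace(0, 0.5, 25), np.linspace(9.5, 10, 25)])
        _, p = shapiro_wilk(v)
        assert p < 0.05

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """Three fully separated triples: H = 7.2 by the rank-sum formula."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_identical_groups_floor(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc, 1, 12) for loc in (0.0, 0.4, 1.0)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_permutation_two_groups(self):
        """n=4+4: p equals the exhaustive 70-assignment permutation value."""
        a, b = [1.0, 2.0, 3.0, 4.0], [3.5, 5.0, 6.0, 7.0]
        res = kruskal_wallis([a, b])
        pooled = np.array(a + b)
        h_obs = res.statistic
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(8) if i not in combo]]
            ranks = sps.rankdata(pooled)
            ra = ranks[list(combo)]
            rb = ranks[[i for i in range(8) if i not in combo]]
            h = 12 / (8 * 9) * (ra.sum() ** 2 / 4 + rb.sum() ** 2 / 4) - 3 * 9
            ties = np.unique(pooled, return_counts=True)[1]
            h /= 1 - np.sum(ties**3 - ties) / (8**3 - 8)
            if h >= h_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / len(combos))

    def test_invariance_under_monotone_transform(self):
        groups = [[0.1, 0.5, 0.9], [0.3, 1.2, 2.0], [0.7, 1.5]]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in map(np.asarray, groups)])
        assert res1.statistic == pytest.approx(res2.statistic)


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, np.exp(x / 5)).statistic == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(6.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_permutation_n5(self):
        """p equals the exhaustive 120-permutation tail."""
        x = np.array([2.0, 4.0, 1.0, 5.0, 3.0])
        y = np.array([0.3, 0.9, 0.2, 0.7, 1.0])
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rhos = [np.corrcoef(rx, perm)[0, 1] for perm in itertools.permutations(ry)]
        p_ref = np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12)
        assert res.p_value == pytest.approx(p_ref)

    def test_constant_input_sentinel(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.statistic)
        assert not res.significant

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = spearman(x, y).statistic
        r2 = spearman(np.exp(x), y**3).statistic
        assert r1 == pytest.approx(r2)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestCategorical:
    def test_chi_squared_formula_oracle(self):
        t = np.array([[10, 5], [2, 12]])
        res = categorical_assoc(t)
        rows, cols = t.sum(1), t.sum(0)
        e = np.outer(rows, cols) / t.sum()
        assert res.test == "chi-squared"
        assert res.statistic == pytest.approx(np.sum((t - e) ** 2 / e))

    def test_proportional_table_is_zero(self):
        res = categorical_assoc([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_branch_hypergeometric_oracle(self):
        t = np.array([[1, 5], [7, 2]])  # min expected count 3.2 < 5
        res = categorical_assoc(t)
        assert res.test == "fisher-exact"
        # two-sided Fisher: sum of all tables with pmf <= pmf(observed)
        n, r1, c1 = t.sum(), t[0].sum(), t[:, 0].sum()
        pmf = sps.hypergeom(n, r1, c1).pmf
        support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        p_ref = sum(pmf(k) for k in support if pmf(k) <= pmf(t[0, 0]) * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_simulated_p_for_sparse_larger_table(self):
        t = [[1, 4, 2], [6, 1, 3], [2, 2, 9]]
        res = categorical_assoc(t, seed=0)
        assert res.test == "fisher-simulated"
        assert 0 < res.p_value <= 1
        again = categorical_assoc(t, seed=0)
        assert res.p_value == again.p_value  # seeded determinism

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            categorical_assoc([[0, 0], [1, 2]])


class TestCohortSummary:
    def test_printed_count_percentages(self):
        sex = ["M"] * 23 + ["F"] * 14
        grading = ["moderate"] * 19 + ["poor"] * 15 + ["well"] * 3
        df = pd.DataFrame({"sex": sex, "grading": grading})
        summary = cohort_summary(df)["categorical"]
        male = summary.query("variable == 'sex' and level == 'M'")
        assert male["percent"].item() == 62.2
        mod = summary.query("variable == 'grading' and level == 'moderate'")
        assert mod["percent"].item() == 51.4

    def test_single_lesion_is_100_percent(self):
        df = pd.DataFrame({"necrosis": ["absent"], "tils_percent": [20.0]})
        out = cohort_summary(df)
        assert out["categorical"]["percent"].item() == 100.0
        assert out["continuous"].query("variable == 'tils_percent'")["median"].item() == 20.0

    def test_continuous_median_iqr(self):
        df = pd.DataFrame({"tils_percent": [5.0, 15.0, 40.0, 30.0]})
        row = cohort_summary(df)["continuous"].iloc[0]
        assert row["median"] == pytest.approx(22.5)
        assert row["iqr"] == pytest.approx(32.5 - 12.5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame())


class TestAssociationReport:
    @staticmethod
    def make_cohort(seed=0, n=30, planted=True):
        rng = np.random.default_rng(seed)
        tils = rng.uniform(0, 60, n)
        d_med = (2.0 - 0.01 * tils) if planted else rng.uniform(1.0, 2.0, n)
        d_med = d_med + rng.normal(0, 0.15, n)
        return pd.DataFrame({
            "d_median": d_med,
            "k_median": rng.uniform(0.5, 1.0, n),
            "tils_percent": tils,
            "tsr_percent": rng.uniform(30, 90, n),
            "necrosis": rng.choice(["absent", "focal"], n),
        })

    def test_planted_association_flagged(self):
        cohort = self.make_cohort(planted=True)
        rep = association_report(cohort, ["d_median", "k_median"], ["necrosis"])
        assert rep["spearman_rho"].loc["tils_percent", "d_median"] < -0.5
        assert rep["significant"].loc["tils_percent", "d_median"]

    def test_reproducible_for_identical_input(self):
        cohort = self.make_cohort(seed=5)
        r1 = association_report(cohort, ["d_median"], ["necrosis"])
        r2 = association_report(cohort, ["d_median"], ["necrosis"])
        pd.testing.assert_frame_equal(r1["spearman_p"], r2["spearman_p"])
        pd.testing.assert_frame_equal(r1["kruskal_p"], r2["kruskal_p"])

    def test_single_level_factor_skipped(self):
        cohort = self.make_cohort()
        cohort["necrosis"] = "absent"
        rep = association_report(cohort, ["d_median"], ["necrosis"])
        assert any("levels" in s[2] for s in rep["skipped"])
        assert np.isnan(rep["kruskal_p"].loc["necrosis", "d_median"])

    def test_pairwise_deletion_of_missing(self):
        cohort = self.make_cohort()
        cohort.loc[:4, "d_median"] = np.nan
        rep = association_report(cohort, ["d_median", "k_median"], [])
        # d_median tested on the complete pairs only, k_median on all rows
        assert np.isfinite(rep["spearman_p"].loc["tils_percent", "d_median"])

    def test_bh_option_is_more_conservative(self):
        cohort = self.make_cohort()
        raw = association_report(cohort, ["d_median", "k_median"], ["necrosis"])
        adj = association_report(cohort, ["d_median", "k_median"], ["necrosis"],
                                 bh_correct=True)
        assert adj["significant"].to_numpy().sum() <= raw["significant"].to_numpy().sum()
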