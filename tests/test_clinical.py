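"""Univariate clinical statistics: 2x2 tests, ORs, group comparisons,
logistic regression.  The published baseline-table values are exactly
reconstructable from the cohort margins (n = 53 MIA / 89 IAC)."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from periradiomics.clinical import (
    chi2_dispatch,
    fisher_exact,
    group_compare,
    logistic_regression,
    mann_whitney_u,
    odds_ratio_wald,
    pearson_chi2,
    rxc_chi2,
    table_one,
)

# covariate rows of the study cohort: ((no_mia, no_iac), (yes_mia, yes_iac)),
# published chi-square value, and the correction identified from it
COHORT_2X2 = {
    "gender": ([[42, 69], [11, 20]], 0.057, "none"),
    "lesion_type": ([[47, 76], [6, 13]], 0.309, "none"),
    "family_history": ([[49, 85], [4, 4]], 0.150, "yates"),
    "smoking": ([[45, 79], [8, 10]], 0.447, "none"),
    "drinking": ([[49, 80], [4, 9]], 0.045, "yates"),
    "border": ([[4, 2], [49, 87]], 1.182, "yates"),
    "lobulation": ([[22, 33], [31, 56]], 0.275, "none"),
    "spiculation": ([[26, 45], [27, 44]], 0.030, "none"),
    "vcs": ([[44, 49], [9, 40]], 11.493, "none"),
    "pleural_indentation": ([[33, 52], [20, 37]], 0.204, "none"),
    "vacuole": ([[46, 63], [7, 26]], 4.771, "none"),
    "air_bronchogram": ([[53, 84], [0, 5]], 1.654, "yates"),
}


class TestChi2:
    @pytest.mark.parametrize("name", sorted(COHORT_2X2))
    def test_cohort_values_reproduced_to_printed_precision(self, name):
        table, published, correction = COHORT_2X2[name]
        res = pearson_chi2(table, correction=correction)
        assert res.statistic == pytest.approx(published, abs=5e-4)

    def test_balanced_table_zero(self):
        assert pearson_chi2([[10, 10], [10, 10]]).statistic == 0.0

    def test_uncorrected_matches_scipy_and_rxc_formula(self, rng):
        t = rng.integers(1, 40, (2, 2))
        own = pearson_chi2(t).statistic
        ref = stats.chi2_contingency(t, correction=False).statistic
        assert own == pytest.approx(ref, abs=1e-10)
        assert own == pytest.approx(rxc_chi2(t).statistic, abs=1e-10)

    def test_yates_matches_scipy(self, rng):
        t = rng.integers(1, 40, (2, 2))
        own = pearson_chi2(t, "yates").statistic
        ref = stats.chi2_contingency(t, correction=True).statistic
        assert own == pytest.approx(ref, abs=1e-10)

    def test_row_and_column_swap_invariance(self):
        t = np.array([[44, 49], [9, 40]])
        s0 = pearson_chi2(t).statistic
        assert pearson_chi2(t[::-1, ::-1]).statistic == pytest.approx(s0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 9]])

    def test_dispatch_rule(self):
        # all expected counts >= 5 -> pearson
        assert chi2_dispatch([[42, 69], [11, 20]]).method == "pearson"
        # min expected < 5 -> yates
        assert chi2_dispatch([[49, 85], [4, 4]]).method == "yates"
        # min expected < 1 -> fisher
        assert chi2_dispatch([[60, 60], [0, 1]]).method == "fisher"


def _fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestFisher:
    def test_symmetric_2x2_p_one(self):
        assert fisher_exact([[1, 0], [0, 1]]).p == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_enumeration_oracle(self, trial, rng):
        t = rng.integers(0, 12, (2, 2))
        if 0 in np.r_[t.sum(0), t.sum(1)]:
            return
        assert fisher_exact(t).p == pytest.approx(_fisher_enumeration_oracle(t), abs=1e-9)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[0, 0], [5, 9]]).p == 1.0


class TestOddsRatio:
    def test_vcs_cohort_values(self):
        res = odds_ratio_wald([[44, 49], [9, 40]])
        assert res.odds_ratio == pytest.approx(3.991, abs=5e-4)
        assert res.ci_low == pytest.approx(1.741, abs=5e-4)
        assert res.ci_high == pytest.approx(9.151, abs=5e-4)

    def test_vacuole_cohort_values(self):
        res = odds_ratio_wald([[46, 63], [7, 26]])
        assert res.odds_ratio == pytest.approx(2.712, abs=5e-4)
        assert res.ci_low == pytest.approx(1.084, abs=5e-4)
        assert res.ci_high == pytest.approx(6.785, abs=5e-4)

    def test_symmetric_table_or_one(self):
        assert odds_ratio_wald([[5, 5], [5, 5]]).odds_ratio == 1.0

    def test_margin_swap_inverts_or(self):
        a = odds_ratio_wald([[44, 49], [9, 40]])
        b = odds_ratio_wald([[49, 44], [40, 9]])
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)

    def test_zero_cell_haldane_correction_flagged(self):
        res = odds_ratio_wald([[53, 84], [0, 5]])
        assert res.corrected and res.odds_ratio > 0


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        res = mann_whitney_u([4, 5, 6], [1, 2, 3])
        # scipy reports U of the first sample: fully above -> U = n1*n2
        assert res.statistic in (0.0, 9.0)
        assert res.method == "mwu-exact"

    def test_exact_matches_permutation_oracle(self, rng):
        """Exact two-sided p equals the full permutation distribution of U
        for small samples."""
        from itertools import combinations

        x = [1.2, 3.4, 5.1, 2.2]
        y = [4.3, 6.0, 0.7]
        res = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        n1 = len(x)
        obs_u = stats.mannwhitneyu(x, y).statistic
        us = []
        for idx in combinations(range(len(pooled)), n1):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            us.append(stats.mannwhitneyu(xs, ys).statistic)
        us = np.array(us)
        mu = n1 * len(y) / 2
        p_perm = np.mean(np.abs(us - mu) >= np.abs(obs_u - mu) - 1e-12)
        assert res.p == pytest.approx(p_perm, abs=1e-9)

    def test_u_over_n1n0_equals_auc(self, rng):
        """Cross-module identity with the ROC module."""
        from periradiomics.evaluation import roc_auc

        x = rng.normal(1, 1, 25)
        y = rng.normal(0, 1, 35)
        res = mann_whitney_u(x, y)
        scores = np.r_[x, y]
        lab = np.r_[np.ones(25, int), np.zeros(35, int)]
        auc = roc_auc(scores, lab).auc
        assert res.statistic / (25 * 35) == pytest.approx(auc, abs=1e-12)


class TestGroupCompare:
    def test_normal_samples_dispatch_to_ttest(self, rng):
        v = np.r_[rng.normal(0, 1, 50), rng.normal(0.3, 1, 50)]
        lab = np.r_[np.zeros(50), np.ones(50)]
        res = group_compare(v, lab)
        assert res.method in ("ttest", "mwu")  # gate is stochastic
        # overwhelmingly the t-test branch for clean normal data
        hits = sum(
            group_compare(np.r_[g1, g2], lab).method == "ttest"
            for g1, g2 in (
                (np.random.default_rng(s).normal(0, 1, 50),
                 np.random.default_rng(s + 1000).normal(0, 1, 50))
                for s in range(10)
            )
        )
        assert hits >= 8

    def test_skewed_samples_dispatch_to_mwu(self, rng):
        v = np.r_[rng.lognormal(0, 1.5, 60), rng.lognormal(0.4, 1.5, 60)]
        lab = np.r_[np.zeros(60), np.ones(60)]
        assert group_compare(v, lab).method.startswith("mwu")

    def test_identical_samples_high_p(self, rng):
        x = rng.normal(size=40)
        v = np.r_[x, x]
        lab = np.r_[np.zeros(40), np.ones(40)]
        res = group_compare(v, lab)
        assert res.p > 0.9


class TestLogisticRegression:
    def test_univariate_binary_equals_2x2_odds_ratio(self):
        """Univariate LR on the VCS flag reproduces the collapsed-table
        OR 3.991 with matching CI."""
        x = np.r_[np.zeros(44), np.ones(9), np.zeros(49), np.ones(40)]
        y = np.r_[np.zeros(53), np.ones(89)]
        out = logistic_regression(pd.DataFrame({"vcs": x}), y, mode="univariate")
        row = out.iloc[0]
        assert row["or"] == pytest.approx(3.991, abs=5e-4)
        assert row["ci_low"] == pytest.approx(1.741, abs=5e-4)
        assert row["ci_high"] == pytest.approx(9.151, abs=5e-4)

    def test_null_wald_ci_coverage(self, rng):
        """Under no effect the 95% Wald CI covers OR = 1 about 95% of
        the time."""
        cover = 0
        reps = 200
        for r in range(reps):
            g = np.random.default_rng(r)
            x = g.normal(size=120)
            y = g.integers(0, 2, 120)
            row = logistic_regression(pd.DataFrame({"x": x}), y).iloc[0]
            cover += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert 0.90 <= cover / reps <= 0.99

    def test_intercept_only_probability_is_prevalence(self, rng):
        import statsmodels.api as sm

        y = rng.integers(0, 2, 80).astype(float)
        res = sm.GLM(y, np.ones((80, 1)), family=sm.families.Binomial()).fit()
        assert special.expit(res.params[0]) == pytest.approx(y.mean(), abs=1e-8)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = rng.integers(0, 2, 60)
        with pytest.raises(ValueError, match="collinear"):
            logistic_regression(X, y)


class TestTableOne:
    def test_reconstructed_cohort_table_methods_and_values(self):
        """exact_counts synthetic covariates reproduce the published
        chi-square statistics via the dispatch rule."""
        from periradiomics.synthetic import CohortSpec, simulate_clinical_table

        tab = simulate_clinical_table(CohortSpec(), seed=3, exact_counts=True)
        out = table_one(tab[["label", "vcs", "vacuole", "drinking"]])
        res = {r.covariate: r for r in out.itertuples()}
        assert res["vcs"].statistic == pytest.approx(11.493, abs=5e-4)
        assert res["vcs"].method == "pearson"
        assert res["vacuole"].statistic == pytest.approx(4.771, abs=5e-4)
        assert res["drinking"].statistic == pytest.approx(0.045, abs=5e-4)
        assert res["drinking"].method == "yates"
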