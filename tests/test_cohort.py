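"""Cohort statistics: the normality gate, correlations, summary t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from altinet import (
    CytokineSeverityModel,
    SimConfig,
    delta,
    gated_paired_test,
    pearson_corr,
    pearson_p_from_r,
    simulate_cytokine_cohort,
    two_sample_t_from_summary,
)
from altinet.cohort import signed_rank_null_pmf


class TestDelta:
    def test_elementwise_change(self):
        cohort = pd.DataFrame(
            {
                "cytokine_pre": [10.0, 5.0, 7.0],
                "cytokine_post": [4.0, 5.0, 9.0],
            },
            index=["a", "b", "c"],
        )
        out = delta(cohort)
        assert out.tolist() == [-6.0, 0.0, 2.0]

    def test_missing_values_excluded_with_warning(self):
        cohort = pd.DataFrame(
            {"cytokine_pre": [1.0, np.nan], "cytokine_post": [2.0, 3.0]},
            index=["a", "b"],
        )
        with pytest.warns(UserWarning, match="missing"):
            out = delta(cohort)
        assert list(out.index) == ["a"]


class TestGatedPairedTest:
    def test_normal_differences_choose_paired_t(self, rng):
        chosen = []
        for _ in range(100):
            pre = rng.normal(10, 1, size=20)
            post = pre + rng.normal(0.5, 1, size=20)
            chosen.append(gated_paired_test(pre, post).method)
        assert chosen.count("paired-t") >= 90

    def test_skewed_differences_choose_wilcoxon(self, rng):
        chosen = []
        for _ in range(100):
            pre = rng.normal(10, 1, size=20)
            post = pre + np.exp(rng.normal(0, 1, size=20)) - 1.0
            chosen.append(gated_paired_test(pre, post).method)
        assert chosen.count("wilcoxon-signed-rank") >= 90

    def test_constant_shift_falls_through_to_degenerate(self):
        pre = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero variance"):
            res = gated_paired_test(pre, pre + 2.0)
        assert res.method == "degenerate"
        assert 0 < res.p_two_sided <= 1

    def test_all_zero_differences_return_p_one(self):
        pre = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            res = gated_paired_test(pre, pre.copy())
        assert res.p_two_sided == 1.0

    def test_type_one_error_under_normal_null(self, rng):
        """At alpha = 0.05 the gated test rejects a true null at close to
        the nominal rate (normal differences, n = 12)."""
        rejections = 0
        n_rep = 4000
        for _ in range(n_rep):
            pre = rng.normal(0, 1, size=12)
            post = pre + rng.normal(0, 1, size=12)
            if gated_paired_test(pre, post).p_two_sided <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestPearson:
    def test_exact_negative_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_corr(x, -2 * x + 3)
        assert res.statistic == pytest.approx(-1.0)

    def test_orthogonal_vectors_give_zero_r(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = pearson_corr(x, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-15)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_cohort_generator_recovers_target_r(self):
        rs = []
        for seed in range(300):
            cohort, _ = simulate_cytokine_cohort(SimConfig(seed=seed))
            change = cohort["cytokine_post"] - cohort["cytokine_pre"]
            rs.append(pearson_corr(change, cohort["LLS"]).statistic)
        assert np.mean(rs) == pytest.approx(-0.52, abs=0.05)


class TestPearsonPFromR:
    def test_worked_cohort_statistic(self):
        # r = -0.52 with 22 subjects: p rounds to 0.013
        assert round(pearson_p_from_r(-0.52, 22), 3) == 0.013

    def test_zero_correlation_has_p_one(self):
        assert pearson_p_from_r(0.0, 10) == pytest.approx(1.0)
        assert pearson_p_from_r(0.0, 100) == pytest.approx(1.0)

    def test_matches_t_density_quadrature_oracle(self):
        r, n = 0.3, 50
        t_obs = abs(r) * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        tail, _ = quad(lambda u: stats.t.pdf(u, n - 2), t_obs, np.inf)
        assert pearson_p_from_r(r, n) == pytest.approx(2 * tail, abs=1e-6)

    def test_symmetric_in_sign_and_monotone(self):
        assert pearson_p_from_r(0.4, 15) == pearson_p_from_r(-0.4, 15)
        assert pearson_p_from_r(0.5, 15) < pearson_p_from_r(0.3, 15)
        assert pearson_p_from_r(0.3, 40) < pearson_p_from_r(0.3, 15)

    def test_degenerate_r_returns_limit(self):
        with pytest.warns(UserWarning):
            assert pearson_p_from_r(1.0, 10) == 0.0


class TestTwoSampleFromSummary:
    def test_identical_summaries_give_t_zero(self):
        res = two_sample_t_from_summary(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_severity_row_is_highly_significant(self):
        res = two_sample_t_from_summary(2.0, 1.2, 5, 9.4, 2.3, 5)
        assert res.p_two_sided < 0.001
        assert res.df == 8

    def test_matches_raw_data_construction_oracle(self, rng):
        """Build raw samples with the stated moments; their t equals ours."""
        for _ in range(5):
            m1, s1, n1 = rng.uniform(0, 10), rng.uniform(0.5, 3), 12
            m2, s2, n2 = rng.uniform(0, 10), rng.uniform(0.5, 3), 9
            x = rng.normal(size=n1)
            x = (x - x.mean()) / x.std(ddof=1) * s1 + m1
            y = rng.normal(size=n2)
            y = (y - y.mean()) / y.std(ddof=1) * s2 + m2
            raw = stats.ttest_ind(x, y, equal_var=True)
            res = two_sample_t_from_summary(m1, s1, n1, m2, s2, n2)
            assert res.statistic == pytest.approx(raw.statistic, abs=1e-9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1, 0.0, 5, 2, 1.0, 5)


class TestSignedRankNull:
    @pytest.mark.parametrize("n", [3, 8, 15, 25])
    def test_pmf_sums_to_one(self, n):
        pmf = signed_rank_null_pmf(n)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(pmf) == n * (n + 1) // 2 + 1

    def test_matches_scipy_exact_p(self, rng):
        diffs = rng.normal(0.3, 1.0, size=12)
        w = stats.wilcoxon(diffs, method="exact")
        # two-sided exact p from our DP distribution
        pmf = signed_rank_null_pmf(12)
        ranks = stats.rankdata(np.abs(diffs))
        w_plus = ranks[diffs > 0].sum()
        lo = min(w_plus, 12 * 13 / 2 - w_plus)
        p = 2 * pmf[: int(lo) + 1].sum()
        assert min(p, 1.0) == pytest.approx(w.pvalue, abs=1e-10)


class TestCytokineSeverityModel:
    def test_fit_on_simulated_cohort(self):
        cohort, _ = simulate_cytokine_cohort(SimConfig(seed=31))
        res = CytokineSeverityModel(cohort).fit()
        assert res.correlation.n == 22
        assert -1 <= res.r <= 1
        frame = res.to_frame()
        assert "change vs LLS" in frame.index
        assert "Pearson" in res.summary()

    def test_lls_rule_enforced(self):
        cohort, _ = simulate_cytokine_cohort(SimConfig(seed=31))
        bad = cohort.copy()
        bad.iloc[0, bad.columns.get_loc("LLS")] = 1  # AMS subject with LLS < 3
        with pytest.raises(ValueError, match="LLS"):
            CytokineSeverityModel(bad)
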