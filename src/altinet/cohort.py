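"""Cohort association statistics.

Implements the statistical toolkit used on the validation cohort: paired
pre/post comparisons gated by a Shapiro–Wilk normality test (paired t when
the differences look normal, Wilcoxon signed-rank otherwise), the Pearson
product–moment correlation between per-subject cytokine change and the
Lake Louise severity score, and a pooled-variance two-sample t-test
computable from published summary statistics alone. All tests are
two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | None
    p_two_sided: float
    n: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __str__(self) -> str:
        df = "" if self.df is None else f", df={self.df:g}"
        return (
            f"{self.method}: statistic={self.statistic:.4g}{df}, "
            f"p={self.p_two_sided:.4g} (n={self.n})"
        )


def delta(cohort: pd.DataFrame) -> pd.Series:
    """Per-subject cytokine change, post - pre (pg/mL).

    Subjects with a missing measurement are excluded with a warning.
    """
    have = cohort[["cytokine_pre", "cytokine_post"]].notna().all(axis=1)
    if not have.all():
        warnings.warn(
            f"excluding {int((~have).sum())} subject(s) with missing measurements: "
            f"{list(cohort.index[~have][:5])}"
        )
    sub = cohort[have]
    return sub["cytokine_post"] - sub["cytokine_pre"]


def gated_paired_test(
    pre: np.ndarray | pd.Series,
    post: np.ndarray | pd.Series,
    alpha_normality: float = 0.05,
) -> TestResult:
    """Paired comparison with a Shapiro–Wilk normality gate on differences.

    If the Shapiro–Wilk p exceeds ``alpha_normality`` the paired t-test is
    used; otherwise the Wilcoxon signed-rank test (exact null for n <= 25
    once zero differences are dropped, normal approximation with continuity
    correction above). Constant differences make both the gate and the t
    statistic degenerate: all-zero differences return p = 1 with a warning;
    a non-zero constant difference falls back to the sign-test bound
    2 * 0.5**n with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = len(pre)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    diffs = post - pre

    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning degenerate p = 1")
        return TestResult("degenerate", 0.0, None, 1.0, n, ("all differences zero",))
    if np.ptp(diffs) == 0:
        warnings.warn(
            "paired differences have zero variance; Shapiro-Wilk and paired t "
            "are undefined, returning the sign-test bound"
        )
        p = min(1.0, 2.0 * 0.5**n)
        return TestResult("degenerate", math.nan, None, p, n, ("constant differences",))

    sw_p = stats.shapiro(diffs).pvalue
    if sw_p > alpha_normality:
        t_res = stats.ttest_rel(post, pre)
        return TestResult("paired-t", float(t_res.statistic), float(n - 1), float(t_res.pvalue), n)

    nonzero = diffs[diffs != 0]
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ties) else "approx"
    w_res = stats.wilcoxon(nonzero, alternative="two-sided", method=method, correction=True)
    return TestResult(
        "wilcoxon-signed-rank", float(w_res.statistic), None, float(w_res.pvalue), n
    )


def pearson_corr(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> TestResult:
    """Pearson product–moment correlation with the t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return TestResult("pearson", float(r), float(n - 2), float(p), n)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation r observed with n subjects.

    p = 2 * P[T_{n-2} >= |r| * sqrt(n-2) / sqrt(1 - r^2)]. The degenerate
    |r| >= 1 case returns the limit p = 0 with a warning.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        warnings.warn("|r| >= 1: returning the limiting p = 0")
        return 0.0
    t = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    Suitable for published mean (SD) rows such as a severity-score table;
    df = n1 + n2 - 2.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult("two-sample-t", float(t), float(n1 + n2 - 2), float(p), n1 + n2)


def signed_rank_null_pmf(n: int) -> np.ndarray:
    """Exact null distribution of the Wilcoxon signed-rank statistic W+.

    Dynamic-programming enumeration of all 2**n sign assignments; entry w
    of the returned array is P[W+ = w], w = 0 .. n(n+1)/2. Used as an
    independent cross-check of the exact small-sample test.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank > 0 else counts
        counts = counts + shifted
    return counts / 2.0**n


# ---------------------------------------------------------------------------
# Cohort model
# ---------------------------------------------------------------------------


class CytokineSeverityModel:
    """Cohort-level association of cytokine change with AMS severity.

    Built from a cohort table (index = subject, columns ``group``, ``LLS``,
    ``cytokine_pre``, ``cytokine_post``). ``fit()`` runs the gated paired
    pre/post comparison within each group and the Pearson correlation of
    the per-subject change against the Lake Louise score across the whole
    cohort.
    """

    def __init__(self, cohort: pd.DataFrame):
        required = {"group", "LLS", "cytokine_pre", "cytokine_post"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        bad = cohort[(cohort["group"] == GROUPS[0]) & (cohort["LLS"] < 3)]
        if len(bad):
            raise ValueError(
                f"AMS subjects must have LLS >= 3; offending: {list(bad.index[:5])}"
            )
        self.cohort = cohort

    def fit(self, alpha_normality: float = 0.05) -> "CytokineSeverityResults":
        paired: dict[str, TestResult] = {}
        for group in GROUPS:
            sub = self.cohort[self.cohort["group"] == group]
            if len(sub) >= 3:
                paired[group] = gated_paired_test(
                    sub["cytokine_pre"], sub["cytokine_post"], alpha_normality
                )
        change = delta(self.cohort)
        lls = self.cohort.loc[change.index, "LLS"]
        correlation = pearson_corr(change, lls)
        return CytokineSeverityResults(self, paired, correlation)


class CytokineSeverityResults:
    def __init__(
        self,
        model: CytokineSeverityModel,
        paired_tests: dict[str, TestResult],
        correlation: TestResult,
    ):
        self.model = model
        self.paired_tests = paired_tests
        self.correlation = correlation

    @property
    def r(self) -> float:
        return self.correlation.statistic

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, res in self.paired_tests.items():
            rows.append(
                {
                    "comparison": f"paired pre/post ({group})",
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_two_sided": res.p_two_sided,
                    "n": res.n,
                }
            )
        c = self.correlation
        rows.append(
            {
                "comparison": "change vs LLS",
                "method": c.method,
                "statistic": c.statistic,
                "df": c.df,
                "p_two_sided": c.p_two_sided,
                "n": c.n,
            }
        )
        return pd.DataFrame(rows).set_index("comparison")

    def summary(self) -> str:
        c = self.correlation
        lines = [
            "Cytokine change vs AMS severity",
            "===============================",
            f"cohort size: {len(self.model.cohort)}",
        ]
        for group, res in self.paired_tests.items():
            lines.append(f"{group:>8} pre/post: {res}")
        lines.append(
            f"Pearson r({c.n}) = {c.statistic:.2f}, p = {c.p_two_sided:.3f}"
        )
        return "\n".join(lines)
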