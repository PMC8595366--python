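"""Cohort statistics: rank-sum, Fisher exact (2x2 and RxC), binomial CI, correlation.

Class-count comparisons between conditions use Fisher's exact test
generalized to RxC tables (exact enumeration over the margin-fixed support
for small tables, seeded Monte-Carlo otherwise); continuous per-cell
quantities use the two-sided Wilcoxon rank-sum test; reverser percentages
carry exact binomial confidence intervals. Every method records how it was
computed so figures remain auditable. No multiple-testing correction is
applied: comparisons are reported per-pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

EXACT_RANKSUM_MAX_N = 25
EXACT_FISHER_MAX_TOTAL = 200
MC_FISHER_DRAWS = 100_000


@dataclass
class TestResult:
    p_value: float
    method: str
    statistic: Optional[float] = None
    monte_carlo_se: Optional[float] = None


def binomial_proportion_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval around k/n.

    Returns ``(point, lower, upper)``. The exact interval is conservative;
    the method choice is recorded by this docstring contract rather than a
    runtime flag since only one method is exposed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lower, upper = proportion_confint(k, n, alpha=1 - level, method="beta")
    return k / n, float(lower), float(upper)


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample is small
    (<= 25) and tie-free, and the normal approximation with tie correction
    otherwise; the method used is recorded on the result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= EXACT_RANKSUM_MAX_N and not has_ties
    method = "exact" if exact else "normal_tie_corrected"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(p_value=float(res.pvalue), method=method, statistic=float(res.statistic))


def _log_table_prob(table: np.ndarray, lgf_row, lgf_col, lgf_n) -> float:
    """Log hypergeometric probability of an RxC table with fixed margins."""
    return lgf_row + lgf_col - lgf_n - sum(
        math.lgamma(v + 1) for v in table.ravel()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    R, C = len(row_sums), len(col_sums)

    def rec(r, remaining_cols, rows_out):
        if r == R - 1:
            last = np.array(remaining_cols)
            if (last >= 0).all():
                yield rows_out + [last]
            return
        target = row_sums[r]

        def fill(c, left, row_acc):
            if c == C - 1:
                v = left
                if 0 <= v <= remaining_cols[c]:
                    yield row_acc + [v]
                return
            hi = min(left, remaining_cols[c])
            for v in range(hi + 1):
                yield from fill(c + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            rem = [remaining_cols[c] - row[c] for c in range(C)]
            yield from rec(r + 1, rem, rows_out + [np.array(row)])

    yield from rec(0, list(col_sums), [])


def fisher_exact(
    table: Sequence[Sequence[int]],
    seed: int = 0,
    max_exact_total: int = EXACT_FISHER_MAX_TOTAL,
    n_draws: int = MC_FISHER_DRAWS,
) -> TestResult:
    """Two-sided Fisher's exact test for an RxC contingency table.

    2x2 tables use the standard hypergeometric test. Larger tables sum the
    probabilities of all margin-fixed tables at most as probable as the
    observed one -- by full enumeration when the total count allows it, and
    otherwise by seeded Monte-Carlo over Patefield-sampled tables, with the
    standard error of the p estimate reported.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("table must be a nonnegative integer matrix")
    row_sums = tab.sum(axis=1)
    col_sums = tab.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("table has an all-zero margin")
    n = int(tab.sum())

    if tab.shape == (2, 2):
        _, p = sps.fisher_exact(tab, alternative="two-sided")
        return TestResult(p_value=float(p), method="hypergeometric_2x2")

    lgf_row = sum(math.lgamma(v + 1) for v in row_sums)
    lgf_col = sum(math.lgamma(v + 1) for v in col_sums)
    lgf_n = math.lgamma(n + 1)
    logp_obs = _log_table_prob(tab, lgf_row, lgf_col, lgf_n)
    tol = 1e-9 * abs(logp_obs)

    if n <= max_exact_total:
        total = 0.0
        p_sum = 0.0
        for rows in _enumerate_tables(list(row_sums), list(col_sums)):
            t = np.stack(rows)
            lp = _log_table_prob(t, lgf_row, lgf_col, lgf_n)
            pr = math.exp(lp)
            total += pr
            if lp <= logp_obs + tol:
                p_sum += pr
        # normalize against accumulated rounding over the support
        return TestResult(p_value=min(p_sum / total, 1.0), method="exact_enumeration")

    rng = np.random.default_rng(seed)
    dist = sps.random_table(row_sums, col_sums)
    draws = dist.rvs(n_draws, method="patefield", random_state=rng)
    lps = np.array([
        _log_table_prob(d, lgf_row, lgf_col, lgf_n) for d in draws
    ])
    hits = lps <= logp_obs + tol
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return TestResult(p_value=p, method="monte_carlo", monte_carlo_se=se)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
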