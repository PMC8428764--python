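"""Shared statistical primitives.

All hypothesis tests in the package funnel through these wrappers so that
the exact-vs-asymptotic policy is applied uniformly:

* Wilcoxon rank-sum and signed-rank use a tie-aware exact enumeration for
  combined sample sizes <= 8, scipy's exact method for tie-free samples
  with combined n <= 25, and the normal approximation with tie and
  continuity corrections otherwise.
* Benjamini-Hochberg goes through statsmodels.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "welch_t_test",
    "bh_adjust",
]

_EXACT_ENUM_MAX = 8  # combined n at or below which we enumerate exactly
_EXACT_SCIPY_MAX = 25  # combined n at or below which scipy exact is used (no ties)


def _tail_p(null: np.ndarray, observed: float, alternative: str) -> float:
    """Two-/one-sided p from an enumerated null distribution (inclusive tails)."""
    null = np.asarray(null, dtype=float)
    n = null.size
    ge = np.count_nonzero(null >= observed - 1e-12) / n
    le = np.count_nonzero(null <= observed + 1e-12) / n
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def _exact_rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Tie-aware exact rank-sum via enumeration of all group assignments.

    Statistic is U of the first sample (midranks used for ties), matching
    the convention of scipy.stats.mannwhitneyu.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    obs_u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    null = np.array(
        [ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
         for idx in combinations(range(nx + ny), nx)]
    )
    return float(obs_u), _tail_p(null, obs_u, alternative)


def _exact_signed_rank(d: np.ndarray, alternative: str) -> tuple[float, float]:
    """Tie-aware exact signed-rank via enumeration of all sign assignments.

    `d` must be free of zeros. Statistic is W+ (sum of ranks of positive
    differences). `alternative` refers to the location of the differences.
    """
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    obs = float(ranks[d > 0].sum())
    # all 2^n sign patterns applied to the tie-aware ranks
    signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    null = np.where(signs, ranks, 0.0).sum(axis=1)
    return obs, _tail_p(null, obs, alternative)


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of the first sample, p-value). Exact enumeration
    for combined n <= 8 (tie-aware); scipy exact for tie-free combined
    n <= 25; normal approximation with tie and continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    n = x.size + y.size
    if n <= _EXACT_ENUM_MAX:
        return _exact_rank_sum(x, y, alternative)
    has_ties = np.unique(np.concatenate([x, y])).size < n
    method = "exact" if (n <= _EXACT_SCIPY_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(a, b=None, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on a - b (or on `a` if b is None).

    Zero differences are dropped (Wilcoxon's convention); if all
    differences are zero, returns (0.0, 1.0). Returns (W+ statistic,
    p-value).
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size <= _EXACT_ENUM_MAX:
        return _exact_signed_rank(d, alternative)
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= _EXACT_SCIPY_MAX and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method, correction=True)
    # scipy reports W- for 'less'/'two-sided' in some versions; recompute W+
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


def welch_t_test(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Degenerate case: both groups constant with equal means -> (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires n >= 2 per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
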