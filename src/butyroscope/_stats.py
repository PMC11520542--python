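"""Shared nonparametric test helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic" | "degenerate"
    degenerate: bool


def rank_sum_test(x, y, exact_max_n: int = 10) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses full exact enumeration when both samples have at most
    ``exact_max_n`` observations and there are no ties across the pooled
    data; otherwise the normal approximation with midranks and tie
    correction.  When every pooled value is identical the comparison is
    degenerate and p = 1 is returned with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestResult(
            statistic=x.size * y.size / 2.0, p_value=1.0,
            method="degenerate", degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankTestResult(float(res.statistic), float(res.pvalue), "exact", False)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic", False)
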