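"""Rank-based group comparisons and chi-squared outlier screening.

Two groups are compared by the Wilcoxon/Mann–Whitney rank-sum test
(exact when sample sizes allow and there are no ties, otherwise the
tie-corrected normal approximation); three or more groups by
Kruskal–Wallis followed by pairwise rank-sum tests with
Benjamini–Hochberg adjustment.

Outlier screening follows the classical chi-squared criterion: the
observation farthest from the sample mean is tested with
``(x - mean)^2 / s^2`` against a chi-squared distribution with one
degree of freedom (sample variance, n-1 denominator) and removed only
if p < 0.05.  The test is applied once per call, never iterated
internally.  Note the statistic is bounded by (n-1)^2/n, so very small
samples can never reject: at n = 4 the smallest attainable p is ~0.13.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "OutlierResult", "rank_test", "chisq_outlier"]

OUTLIER_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: which groups, the statistic, raw and adjusted p."""

    comparison: tuple[str, ...]
    method: str
    statistic: float
    p_value: float
    p_adjusted: float
    n: tuple[int, ...]


def _rank_sum(a, b) -> tuple[float, float]:
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method="auto",
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def rank_test(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """Nonparametric comparison of two or more groups.

    Returns a list of :class:`TestResult`: for two groups a single
    rank-sum test; for more, the omnibus Kruskal–Wallis test followed by
    all pairwise rank-sum tests with BH-adjusted p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {name: np.asarray(values, dtype=float) for name, values in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")

    names = list(arrays)
    if len(names) == 2:
        stat, p = _rank_sum(arrays[names[0]], arrays[names[1]])
        return [
            TestResult(
                comparison=tuple(names), method="rank_sum", statistic=stat,
                p_value=p, p_adjusted=p,
                n=(arrays[names[0]].size, arrays[names[1]].size),
            )
        ]

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        # every observation tied: the rank statistic is identically zero
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = _st.kruskal(*arrays.values())
    results = [
        TestResult(
            comparison=tuple(names), method="kruskal_wallis", statistic=float(h),
            p_value=float(p_kw), p_adjusted=float(p_kw),
            n=tuple(arr.size for arr in arrays.values()),
        )
    ]
    pairs = list(combinations(names, 2))
    raw = []
    for a, b in pairs:
        stat, p = _rank_sum(arrays[a], arrays[b])
        raw.append((a, b, stat, p))
    adjusted = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    for (a, b, stat, p), p_adj in zip(raw, adjusted):
        results.append(
            TestResult(
                comparison=(a, b), method="rank_sum", statistic=stat,
                p_value=p, p_adjusted=float(p_adj),
                n=(arrays[a].size, arrays[b].size),
            )
        )
    return results


@dataclass(frozen=True)
class OutlierResult:
    """Outcome of one chi-squared outlier screen."""

    candidate: float
    index: int
    statistic: float
    p_value: float
    removed: bool
    cleaned: np.ndarray


def chisq_outlier(values: Sequence[float], alpha: float = OUTLIER_ALPHA) -> OutlierResult:
    """Screen the most extreme observation with the chi-squared criterion.

    The candidate is the value farthest from the mean; distance ties are
    broken toward the larger absolute value, then toward the larger
    value.  ``cleaned`` excludes the candidate only when ``removed``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    var = x.var(ddof=1)
    if var == 0:
        raise ValueError("zero variance: no outlier test possible")
    mean = x.mean()
    dist = np.abs(x - mean)
    # deterministic tie-break: max distance, then max |x|, then max x
    order = np.lexsort((x, np.abs(x), dist))
    idx = int(order[-1])
    stat = float((x[idx] - mean) ** 2 / var)
    p = float(_st.chi2.sf(stat, df=1))
    removed = p < alpha
    cleaned = np.delete(x, idx) if removed else x.copy()
    return OutlierResult(
        candidate=float(x[idx]), index=idx, statistic=stat, p_value=p,
        removed=removed, cleaned=cleaned,
    )
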