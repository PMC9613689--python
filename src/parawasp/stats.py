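"""Thin statistical wrappers shared across the pipeline stages.

Conventions fixed here so every stage tests the same way: the rank-sum test
is exact for small groups (min(n, m) <= 8) and a tie-corrected normal
approximation without continuity correction otherwise; the 2x2 chi-square
test is Pearson's without Yates correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "Chi2Result", "wilcoxon_ranksum", "chi2_2x2", "spearman"]

EXACT_LIMIT = 8


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    pvalue: float
    method: str  # "exact" or "normal"


@dataclass
class Chi2Result:
    chi2: float
    pvalue: float
    table: np.ndarray


def wilcoxon_ranksum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when ``min(len(x), len(y)) <= 8`` and there are
    no ties across groups; otherwise a tie-corrected normal approximation
    (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if min(x.size, y.size) <= EXACT_LIMIT and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), "exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return RankSumResult(float(res.statistic), float(res.pvalue), "normal")


def chi2_2x2(table, *, yates: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 table (1 df); Yates correction opt-in."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a marginal total is zero")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=yates)
    return Chi2Result(float(chi2), float(p), t)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p; (nan, nan) on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
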