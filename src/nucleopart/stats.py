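"""Group comparison and enrichment statistics.

Rank-based two-group comparisons (Wilcoxon signed-rank for paired data,
Wilcoxon/Mann-Whitney rank-sum for independent groups) and the Pearson
chi-squared test on 2x2 contingency tables used for enrichment claims
(e.g. pI > 8.5 versus nucleolar mislocalisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    """Summary statistics and test result for a two-group comparison."""

    test: str
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    iqr_x: Tuple[float, float]
    iqr_y: Tuple[float, float]
    mean_x: float
    mean_y: float
    statistic: float
    p_value: float


def _iqr(v: np.ndarray) -> Tuple[float, float]:
    return (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def rank_test(x: Sequence[float], y: Sequence[float],
              paired: bool = False, min_n: int = 5) -> GroupComparison:
    """Rank-based comparison of two samples.

    ``paired=True`` runs the Wilcoxon signed-rank test on the differences
    (requiring equal lengths); ``paired=False`` the rank-sum
    (Mann-Whitney U) test on independent samples. The exact small-sample
    null is used when both n <= 25 and the data permit it; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < min_n or len(y) < min_n:
        raise ValueError(f"need at least {min_n} observations per group")
    exact_ok = len(x) <= 25 and len(y) <= 25
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            method = "exact" if exact_ok and not np.any(d == 0) else "approx"
            res = sps.wilcoxon(x, y, method=method, correction=False)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "Wilcoxon signed-rank"
    else:
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if exact_ok and not ties else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Wilcoxon rank-sum"
    return GroupComparison(
        test=name,
        n_x=len(x), n_y=len(y),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        iqr_x=_iqr(x), iqr_y=_iqr(y),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        statistic=stat, p_value=min(p, 1.0),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def chi_square_2x2(table, yates: bool = False) -> Tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table (1 degree of freedom).

    No continuity correction by default; set ``yates=True`` for the Yates-
    corrected statistic. Both margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    stat, p, _dof, _exp = sps.chi2_contingency(t, correction=yates)
    return float(stat), float(p)
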