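"""Contingency-table statistics shared by the mining and EGA modules.

The mining search evaluates Fisher's exact test on very large numbers of
2x2 tables that all share the same column margins (total cases and total
controls of the cohort).  :class:`FisherExactCache` exploits this: for a
fixed cohort it tabulates, per membership size ``m``, the two-sided
exact p-value for every possible case count ``a`` from the hypergeometric
pmf, so repeated queries reduce to array lookups.  Results agree with
``scipy.stats.fisher_exact`` (same "sum of probabilities <= observed"
two-sided convention).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "FisherExactCache",
    "mean_odds_ratio",
    "odds_ratio_2x2",
    "woolf_ci",
    "bh_adjust",
]

# Relative tolerance used by scipy when comparing pmf values for the
# two-sided tail; kept identical so the two routes agree exactly.
_REL_TOL = 1.0 + 1e-7


class FisherExactCache:
    """Two-sided Fisher exact p-values for tables with fixed cohort margins.

    The table tested for a candidate with ``a`` case members out of ``m``
    members is ``[[a, A - a], [m - a, B - (m - a)]]`` where ``A``/``B`` are
    the cohort's total cases/controls.  Under the null, ``a`` follows a
    hypergeometric distribution with population ``A + B``, ``A`` successes
    and ``m`` draws; the two-sided p is the summed probability of all
    outcomes no more likely than the observed one.
    """

    def __init__(self, n_cases: int, n_controls: int):
        if n_cases < 1 or n_controls < 1:
            raise ValueError("need at least one case and one control")
        self.n_cases = int(n_cases)
        self.n_controls = int(n_controls)
        self._n = self.n_cases + self.n_controls
        self._tables: dict[int, tuple[int, np.ndarray]] = {}

    def _table(self, m: int) -> tuple[int, np.ndarray]:
        cached = self._tables.get(m)
        if cached is not None:
            return cached
        lo = max(0, m - self.n_controls)
        hi = min(m, self.n_cases)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, self._n, self.n_cases, m)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        # p[a] = sum of pmf values <= pmf[a] * (1 + eps)
        idx = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right")
        pvals = np.minimum(csum[np.maximum(idx, 1) - 1], 1.0)
        entry = (lo, pvals)
        self._tables[m] = entry
        return entry

    def pvalue(self, a: int, m: int) -> float:
        """Two-sided p for ``a`` case members out of ``m`` members."""
        lo, pvals = self._table(int(m))
        return float(pvals[int(a) - lo])

    def pvalues(self, a: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`pvalue`; groups queries by membership size."""
        a = np.asarray(a, dtype=np.int64)
        m = np.asarray(m, dtype=np.int64)
        out = np.empty(a.shape, dtype=np.float64)
        order = np.argsort(m, kind="stable")
        ms = m[order]
        starts = np.flatnonzero(np.r_[True, np.diff(ms) > 0])
        bounds = np.r_[starts, ms.size]
        for s, e in zip(bounds[:-1], bounds[1:]):
            lo, pvals = self._table(int(ms[s]))
            idx = order[s:e]
            out[idx] = pvals[a[idx] - lo]
        return out


def mean_odds_ratio(
    case_count: int,
    control_count: int,
    total_cases: int,
    total_controls: int,
    haldane: bool = True,
) -> float:
    """Odds ratio of a signature relative to the cohort's mean odds.

    ``(case_count / control_count) / (total_cases / total_controls)``.
    With ``haldane=True`` a zero control count is handled by adding 0.5 to
    the signature's two cells (Haldane-Anscombe continuity correction).
    """
    if control_count == 0:
        if not haldane:
            return math.inf if case_count > 0 else math.nan
        return ((case_count + 0.5) / 0.5) / (total_cases / total_controls)
    return (case_count / control_count) / (total_cases / total_controls)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Plain cross-product odds ratio ``(a/b) / (c/d)`` of a 2x2 table.

    ``a``/``b`` are exposed cases/controls, ``c``/``d`` unexposed cases/
    controls.  No continuity correction; NaN when undefined.
    """
    num = a * d
    den = b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def woolf_ci(a: int, b: int, c: int, d: int, z: float = 1.96) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the 2x2 odds ratio.

    ``exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``; requires all four
    cells positive.
    """
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan)
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(ranked, 1.0)
    return out
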