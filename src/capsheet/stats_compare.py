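"""Exact and rank statistics used across the pipeline.

Two-sided Fisher's exact test with a sample odds ratio on 2×2 tables,
the Wilcoxon rank-sum (Mann–Whitney) two-sample test, Benjamini–Hochberg
false-discovery-rate correction, and significance-star labelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .image_io import ContingencyTable

__all__ = ["ContingencyTable", "FisherResult", "WilcoxonResult",
           "fisher_exact_2x2", "wilcoxon_rank_sum", "bh_adjust", "stars"]


@dataclass(frozen=True)
class FisherResult:
    """Result of a two-sided Fisher's exact test on a 2×2 table.

    ``odds_ratio`` is the sample cross-product ratio a·d/(b·c) (``inf`` when
    only b·c is zero, ``nan`` when both products vanish). ``ci95`` is a 95%
    confidence interval for the odds ratio computed by ``ci_method``.
    """

    odds_ratio: float
    p_two_sided: float
    ci95: tuple[float, float]
    ci_method: str


@dataclass(frozen=True)
class WilcoxonResult:
    p_two_sided: float
    method: str  # "exact" or "normal-approx"


def _woolf_ci(a, b, c, d, alpha=0.05):
    # Log-odds normal interval; undefined when any cell is empty.
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = st.norm.ppf(1 - alpha / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def _conditional_exact_ci(a, b, c, d, alpha=0.05):
    """Exact conditional CI by inverting one-sided noncentral
    hypergeometric tail tests at alpha/2 (Cornfield-style)."""
    n1, n2, m1 = a + b, c + d, a + c
    lo_support = max(0, m1 - n2)
    hi_support = min(m1, n1)
    N = n1 + n2

    def sf_at(psi):  # P(X >= a | psi)
        return st.nchypergeom_fisher.sf(a - 1, N, n1, m1, psi)

    def cdf_at(psi):  # P(X <= a | psi)
        return st.nchypergeom_fisher.cdf(a, N, n1, m1, psi)

    if a == lo_support:
        lo = 0.0
    else:
        lo = math.exp(brentq(lambda t: sf_at(math.exp(t)) - alpha / 2,
                             -50, 50, xtol=1e-10))
    if a == hi_support:
        hi = math.inf
    else:
        hi = math.exp(brentq(lambda t: cdf_at(math.exp(t)) - alpha / 2,
                             -50, 50, xtol=1e-10))
    return (lo, hi)


def fisher_exact_2x2(table: ContingencyTable,
                     ci_method: str = "woolf") -> FisherResult:
    """Two-sided Fisher's exact test on a 2×2 contingency table.

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed that of the observed
    table (probability-mass two-sided rule). ``ci_method`` is ``"woolf"``
    (log-odds normal interval, default) or ``"conditional-exact"``.
    """
    a, b, c, d = table.counts
    if table.total == 0:
        raise ValueError("all-zero contingency table")
    _, p = st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds_ratio = a * d / (b * c)
    elif a * d > 0:
        odds_ratio = math.inf
    else:
        odds_ratio = math.nan
    if ci_method == "woolf":
        ci = _woolf_ci(a, b, c, d)
    elif ci_method == "conditional-exact":
        ci = _conditional_exact_ci(a, b, c, d)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return FisherResult(odds_ratio=float(odds_ratio), p_two_sided=float(p),
                        ci95=ci, ci_method=ci_method)


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact permutation distribution of the rank-sum when the smaller
    sample has at most 10 observations and the pooled data are tie-free;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= 10 and tie_free:
        res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return WilcoxonResult(p_two_sided=float(res.pvalue), method="exact")
    res = st.mannwhitneyu(x, y, alternative="two-sided",
                          method="asymptotic", use_continuity=True)
    return WilcoxonResult(p_two_sided=float(res.pvalue), method="normal-approx")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stars(p: float) -> str:
    """Significance label: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
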