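"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: plain Python loops and
first-principles enumeration only.
"""

from __future__ import annotations

import math


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability is at
    most that of the observed table (with a small relative tolerance for
    float ties).
    """
    n1, m1 = a + b, a + c
    n = a + b + c + d

    def log_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, n1, m1)
        return (math.lgamma(n1 + 1) - math.lgamma(x + 1)
                - math.lgamma(n1 - x + 1)
                + math.lgamma(n - n1 + 1) - math.lgamma(m1 - x + 1)
                - math.lgamma(n - n1 - m1 + x + 1)
                + math.lgamma(m1 + 1) + math.lgamma(n - m1 + 1)
                - math.lgamma(n + 1))

    lo = max(0, m1 - (n - n1))
    hi = min(m1, n1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_prob(x))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def rank_sum_exact_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Assumes tie-free pooled data. Counts the fraction of assignments whose
    rank-sum for the first group is at least as extreme (in either tail) as
    observed.
    """
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    mean = nx * (n + 1) / 2.0
    dev = abs(obs - mean)
    count = 0
    total = 0
    for combo in combinations(range(1, n + 1), nx):
        total += 1
        if abs(sum(combo) - mean) >= dev - 1e-12:
            count += 1
    return count / total


def radial_bin_means(values, center, n_bins: int) -> dict[int, float]:
    """Per-pixel loop grouping intensities by rounded distance to center."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    rows, cols = values.shape
    for i in range(rows):
        for j in range(cols):
            r = round(math.hypot(i - center[0], j - center[1]))
            if r < n_bins:
                sums[r] = sums.get(r, 0.0) + float(values[i, j])
                counts[r] = counts.get(r, 0) + 1
    return {r: sums[r] / counts[r] for r in sums}


def disk_pixel_count(center, radius: float, shape) -> int:
    """Count pixels whose center satisfies the disk inequality (<= radius)."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            if (i - center[0]) ** 2 + (j - center[1]) ** 2 <= radius ** 2:
                count += 1
    return count


def bh_step_up(p_values) -> list[float]:
    """Benjamini–Hochberg step-up by direct application of the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p_values[i] * m / (rank_idx + 1), 1.0)
        adjusted[i] = val
        prev = val
    return adjusted
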