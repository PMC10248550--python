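"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or naive scanning,
deliberately avoiding the code paths (and, where feasible, the libraries)
used by the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations


def hyper_upper_tail_exact(k_p: int, n_total: int, K: int, n_draw: int) -> float:
    """P(X >= k_p) for X ~ Hypergeom(n_total, K, n_draw), exact integers."""
    hi = min(K, n_draw)
    if k_p > hi:
        return 0.0
    num = sum(
        math.comb(K, j) * math.comb(n_total - K, n_draw - j) for j in range(max(k_p, 0), hi + 1)
    )
    return num / math.comb(n_total, n_draw)


def hyper_upper_tail_lgamma(k_p: int, n_total: int, K: int, n_draw: int) -> float:
    """Same tail via log-gamma; handles cohort-scale populations."""

    def lchoose(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -math.inf
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    hi = min(K, n_draw)
    if k_p > hi:
        return 0.0
    logs = [
        lchoose(K, j) + lchoose(n_total - K, n_draw - j) - lchoose(n_total, n_draw)
        for j in range(max(k_p, 0), hi + 1)
    ]
    m = max(logs)
    return math.exp(m) * sum(math.exp(x - m) for x in logs)


def bh_stepup_reference(p_values) -> list[float]:
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p_values[i] / rank_from_top)
        adj[i] = running_min
    return adj


def ranksum_greater_exact(x, y) -> float:
    """One-sided P(rank sum of x >= observed) by full enumeration.

    Enumerates every assignment of the pooled observations to the first
    group; midranks handle ties.
    """
    pooled = sorted(list(x) + list(y))
    n1, n = len(x), len(x) + len(y)

    def midrank(v: float) -> float:
        lo = sum(1 for u in pooled if u < v)
        eq = sum(1 for u in pooled if u == v)
        return lo + (eq + 1) / 2.0

    ranks = [midrank(v) for v in pooled]
    obs = sum(midrank(v) for v in x)
    hits = total = 0
    for idx in combinations(range(n), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w >= obs - 1e-9:
            hits += 1
    return hits / total


def naive_overlap_scan(chroms, positions, intervals) -> list[bool]:
    """Per-variant linear scan over raw (chrom, start, end) intervals.

    Positions are 1-based; intervals 0-based half-open: overlap iff
    start < pos <= end.
    """
    out = []
    for c, p in zip(chroms, positions):
        hit = False
        for ic, s, e in intervals:
            if ic == c and s < p <= e:
                hit = True
                break
        out.append(hit)
    return out


def shuffle_null_moments_enumerated(K: int, n_p: int, n_s: int) -> tuple[float, float]:
    """Mean/SD of the proband in-category count over all label assignments.

    Enumerates every way to choose which n_p of the N variants are labelled
    proband, with K of the N variants in-category. Tiny N only.
    """
    n = n_p + n_s
    counts = []
    members = set(range(K))
    for proband_idx in combinations(range(n), n_p):
        counts.append(len(members.intersection(proband_idx)))
    mean = sum(counts) / len(counts)
    var = sum((c - mean) ** 2 for c in counts) / len(counts)
    return mean, math.sqrt(var)
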