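"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the hypergeometric lattice with exact integer arithmetic, the
rank-sum oracle enumerates all group assignments, and the clustering oracle
performs naive agglomeration from the definition of complete linkage.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, dist

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins, summing those no more probable than the observed table
    (relative tolerance 1e-7 on the comparison)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def numerator(k: int) -> int:
        return comb(r1, k) * comb(r2, c1 - k)

    observed = numerator(a)
    denominator = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(
        numerator(k) for k in range(lo, hi + 1)
        if numerator(k) <= observed * (1 + 1e-7)
    )
    return total / denominator


def rank_sum_exact_oracle(group_a, group_b) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled tie-free observations to the first group."""
    pooled = sorted(list(group_a) + list(group_b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(group_a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in group_a)
    mean = n_a * (len(pooled) + 1) / 2
    obs_dev = abs(observed - mean)
    hits = total = 0
    for combo in combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mean) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def complete_linkage_oracle(points: np.ndarray) -> list[tuple[frozenset, float]]:
    """Naive agglomeration: repeatedly merge the pair of clusters with the
    smallest maximum inter-point distance (ties: smallest member indices).
    Returns each merge as (leaf set, merge height)."""
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(len(points))}
    merges: list[tuple[frozenset, float]] = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i, j in combinations(sorted(clusters), 2):
            d = max(
                dist(points[p], points[q])
                for p in clusters[i] for q in clusters[j]
            )
            key = (d, min(min(clusters[i]), min(clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        (d, _), i, j = best
        merged = clusters.pop(i) | clusters.pop(j)
        clusters[next_id] = merged
        merges.append((merged, d))
        next_id += 1
    return merges


def scipy_tree_merges(tree: np.ndarray, n: int) -> list[tuple[frozenset, float]]:
    """Flatten a SciPy linkage matrix into (leaf set, height) merges."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (left, right, height, _) in enumerate(tree):
        merged = members[int(left)] | members[int(right)]
        members[n + row_idx] = merged
        merges.append((merged, float(height)))
    return merges
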