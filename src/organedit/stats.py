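"""Shared exact-test core used by the filter cascade and the efficiency tests.

Both uses of Fisher's exact test in the pipeline (strand-bias filtering and
per-site between-condition comparison) run through :func:`fisher_exact_2x2`,
so they agree by construction.  The Wilcoxon rank-sum wrapper switches between
the exact null distribution (small tie-free groups) and the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .errors import PreconditionError

__all__ = ["fisher_exact_2x2", "wilcoxon_rank_sum"]

#: largest group size for which the exact rank-sum null distribution is used
EXACT_RANKSUM_MAX_N = 8


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (within relative tolerance 1e-7).  An all-zero table returns 1.0 with a
    warning.
    """
    if min(a, b, c, d) < 0:
        raise PreconditionError("Fisher table counts must be non-negative")
    if a + b + c + d == 0:
        warnings.warn("Fisher's exact test on an all-zero table; returning p=1.0",
                      stacklevel=2)
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have at most
    :data:`EXACT_RANKSUM_MAX_N` observations and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.  Pooled data that are entirely one tied value
    return p = 1.0 (zero-variance guard).

    Returns ``(U statistic, p value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PreconditionError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size <= EXACT_RANKSUM_MAX_N and b.size <= EXACT_RANKSUM_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))
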