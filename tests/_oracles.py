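"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle sums
scipy hypergeometric pmfs, and the richness-difference oracle enumerates the
exact multinomial resampling distribution for tiny cohorts.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
from scipy import stats


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration of the hypergeometric support."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


def _compositions(total: int, parts: int):
    """All nonnegative integer vectors of length `parts` summing to `total`."""
    for cuts in combinations_with_replacement(range(total + 1), parts - 1):
        out = []
        prev = 0
        for cut in cuts:
            out.append(cut - prev)
            prev = cut
        out.append(total - prev)
        yield tuple(out)


def _multinomial_pmf(counts: Sequence[int], probs: Sequence[float]) -> float:
    n = sum(counts)
    coef = math.factorial(n)
    p = 1.0
    for k, q in zip(counts, probs):
        coef //= math.factorial(k)
        p *= q**k
    return coef * p


def richness_diff_tail_exact(
    pool_counts: Sequence[int], na: int, nb: int, observed_abs_diff: int
) -> float:
    """Exact P(|richness(A*) - richness(B*)| >= observed) under the pooled null.

    A* and B* are independent multinomial draws of sizes na and nb from the
    pooled empirical distribution. Feasible only for tiny cohorts.
    """
    total = sum(pool_counts)
    probs = [c / total for c in pool_counts]
    k = len(pool_counts)

    def richness_dist(n: int) -> dict[int, float]:
        dist: dict[int, float] = {}
        for comp in _compositions(n, k):
            r = sum(1 for c in comp if c > 0)
            dist[r] = dist.get(r, 0.0) + _multinomial_pmf(comp, probs)
        return dist

    da, db = richness_dist(na), richness_dist(nb)
    return sum(
        pa * pb
        for ra, pa in da.items()
        for rb, pb in db.items()
        if abs(ra - rb) >= observed_abs_diff
    )
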