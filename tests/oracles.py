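"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the code paths (and scipy routines) used by the
implementation: the Fisher oracle enumerates margin-preserving tables with
``math.comb``; the Mann-Whitney oracle enumerates every label assignment and
counts pairwise wins directly.
"""

from __future__ import annotations

import itertools
from math import comb


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of all tables with the
    observed margins, summing probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(first cell = x | margins), hypergeometric via binomials
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def mann_whitney_p_enumeration(x, y) -> float:
    """Exact two-sided Mann-Whitney p over all label assignments.

    U is computed for each assignment by direct pairwise comparison
    (wins + half-ties); two-sided p counts assignments at least as extreme
    as observed, where extremity is distance of U from its null mean.
    """
    pooled = list(x) + list(y)
    n = len(x)
    total = len(pooled)

    def u_stat(idx: tuple[int, ...]) -> float:
        first = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(total) if i not in set(idx)]
        u = 0.0
        for xi in first:
            for yj in rest:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(tuple(range(n)))
    nm = n * (total - n)
    extremity_obs = abs(u_obs - nm / 2.0)
    count = 0
    n_assign = 0
    for idx in itertools.combinations(range(total), n):
        n_assign += 1
        if abs(u_stat(idx) - nm / 2.0) >= extremity_obs - 1e-9:
            count += 1
    return count / n_assign
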