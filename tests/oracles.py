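"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions (explicit loops, direct
formulas, exhaustive enumeration) and deliberately shares no code with the
package under test.
"""

from __future__ import annotations

import math
from itertools import combinations


def direct_histogram_stats(values, bins=1024, lo=0.0, hi=4000.0):
    """All eight first-order statistics by direct formula evaluation."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n
    out = {"ADCmean": mean}

    def percentile(p):
        # linear interpolation between order statistics
        rank = p / 100.0 * (n - 1)
        k = int(math.floor(rank))
        frac = rank - k
        if k + 1 < n:
            return xs[k] + frac * (xs[k + 1] - xs[k])
        return xs[k]

    out["ADCmd"] = percentile(50.0)
    out["ADC5p"] = percentile(5.0)
    out["ADC95p"] = percentile(95.0)

    if n >= 2:
        out["ADCsd"] = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
    else:
        out["ADCsd"] = math.nan

    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    if n >= 3 and m2 > 0:
        out["ADCsk"] = m3 / m2**1.5
    else:
        out["ADCsk"] = math.nan
    if n >= 4 and m2 > 0:
        out["ADCkurt"] = m4 / m2**2 - 3.0
    else:
        out["ADCkurt"] = math.nan

    width = (hi - lo) / bins
    counts = [0] * bins
    for x in xs:
        x = min(max(x, lo), hi)
        k = int((x - lo) / width)
        counts[min(k, bins - 1)] += 1
    out["ADCentr"] = -sum(
        (c / n) * math.log2(c / n) for c in counts if c > 0
    )
    return out


def u_statistic(a, b):
    """Mann-Whitney U of group a over b: concordant pairs, ties half."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def permutation_mw_pvalue(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments.

    The null distribution of U is built over all C(n1+n2, n1) group
    assignments of the pooled values; the two-sided p is twice the smaller
    tail (capped at 1), matching the exact-test convention.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = u_statistic(a, b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        sel = set(comb)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in idx if i not in sel]
        us.append(u_statistic(ga, gb))
    total = len(us)
    eps = 1e-9
    lo = sum(1 for u in us if u <= u_obs + eps) / total
    hi = sum(1 for u in us if u >= u_obs - eps) / total
    return min(1.0, 2.0 * min(lo, hi))


def pairwise_auc(pos, neg):
    """AUC as the concordant-pair fraction with half credit for ties."""
    return u_statistic(pos, neg) / (len(pos) * len(neg))
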