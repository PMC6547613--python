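"""Independent brute-force oracles used only by the tests.

Everything here enumerates or recomputes from first principles, never through
the package's own code paths.
"""

import math
from itertools import combinations

import numpy as np
from scipy import stats


def _masks(N, k):
    """All size-k subsets of range(N) as bitmasks."""
    out = []
    for combo in combinations(range(N), k):
        m = 0
        for i in combo:
            m |= 1 << i
        out.append(m)
    return out


def enumerate_intersection_distribution(sizes, N):
    """Exact pmf of the k-way intersection size by full enumeration.

    Fixes the first set (valid by symmetry of uniform draws) and enumerates
    every placement of the remaining sets, counting the intersection size
    with popcounts on bitmasks. Feasible only for tiny N.
    """
    first = (1 << sizes[0]) - 1  # first set = {0..n1-1}, WLOG
    pmf = np.zeros(min(sizes) + 1)
    rest = [(_masks(N, n)) for n in sizes[1:]]

    def recurse(depth, inter, weight):
        if depth == len(rest):
            pmf[bin(inter).count("1")] += weight
            return
        w = weight / len(rest[depth])
        for m in rest[depth]:
            recurse(depth + 1, inter & m, w)

    recurse(0, first, 1.0)
    return pmf


def enumerate_jaccard_moments(n_a, n_b, N):
    """Mean and SD of the Jaccard index over all pairs of subset placements."""
    total = s1 = s2 = 0
    for a in _masks(N, n_a):
        for b in _masks(N, n_b):
            union = bin(a | b).count("1")
            j = bin(a & b).count("1") / union if union else 0.0
            s1 += j
            s2 += j * j
            total += 1
    mean = s1 / total
    var = max(s2 / total - mean * mean, 0.0)
    return mean, math.sqrt(var)


def welch_t_pvalue(x, y):
    """Textbook two-sided Welch t-test written out from the formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def brute_force_filter(frame, fc_cut, p_cut):
    """Row-by-row re-filter of a DE table into directional symbol sets."""
    over, under = set(), set()
    for _, row in frame.iterrows():
        fc, p = row["fc_linear"], row["p_value"]
        if not (abs(fc) > fc_cut):
            continue
        if not (p == p and p <= p_cut):  # NaN-safe
            continue
        for sym in str(row["gene_symbol"]).split("///"):
            sym = sym.strip().upper()
            if sym:
                (over if fc > 0 else under).add(sym)
    return over, under
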