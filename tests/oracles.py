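"""Independent, loop-based reference implementations used as test oracles.

Everything here is written from the defining formulas with explicit
loops, deliberately avoiding the code paths (and where possible the
libraries) used by the package itself.
"""

import math
from itertools import combinations

import numpy as np

KINDS = {"ibfe1": ("pearson", "spearman"), "ibfe2": ("pearson",), "ibfe3": ("spearman",)}


def loop_pearson(u, v):
    """Pearson correlation from the definition, with explicit sums."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = math.sqrt(sum((a - mu) ** 2 for a in u))
    dv = math.sqrt(sum((b - mv) ** 2 for b in v))
    if du == 0 or dv == 0:
        return 0.0
    return num / (du * dv)


def midranks(x):
    """Average ranks (1-based), ties receiving the mean of their positions."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for pos in range(i, j + 1):
            ranks[order[pos]] = avg
        i = j + 1
    return ranks


def loop_spearman(u, v):
    return loop_pearson(midranks(list(u)), midranks(list(v)))


def brute_force_ibfe(datasets, variant="ibfe1"):
    """Steps I-III evaluated with nested loops over patient pairs."""
    m = len(datasets[0])
    sims = []
    for X in datasets:
        rows = [list(map(float, r)) for r in np.asarray(X)]
        for kind in KINDS[variant]:
            vecs = [midranks(r) for r in rows] if kind == "spearman" else rows
            S = [[loop_pearson(vecs[a], vecs[b]) for b in range(m)] for a in range(m)]
            for a in range(m):
                S[a][a] = 1.0
            sims.append(S)
    Y = [sum((S[a] for S in sims), []) for a in range(m)]
    Z = [[loop_pearson(Y[a], Y[b]) for b in range(m)] for a in range(m)]
    for a in range(m):
        Z[a][a] = 1.0
    return np.asarray(Z)


def loop_nmi(a, b):
    """NMI with sqrt normalization from entropy/MI definitions."""
    n = len(a)
    pa = {x: sum(1 for v in a if v == x) / n for x in set(a)}
    pb = {x: sum(1 for v in b if v == x) / n for x in set(b)}
    pab = {}
    for x, y in zip(a, b):
        pab[(x, y)] = pab.get((x, y), 0) + 1 / n
    mi = sum(p * math.log(p / (pa[x] * pb[y])) for (x, y), p in pab.items() if p > 0)
    ha = -sum(p * math.log(p) for p in pa.values() if p > 0)
    hb = -sum(p * math.log(p) for p in pb.values() if p > 0)
    if ha == 0 or hb == 0:
        return 1.0 if _same_partition(a, b) else 0.0
    return mi / math.sqrt(ha * hb)


def _same_partition(a, b):
    n = len(a)
    for i, j in combinations(range(n), 2):
        if (a[i] == a[j]) != (b[i] == b[j]):
            return False
    return True


def km_by_hand(times, events):
    """Product-limit estimator at each distinct event time."""
    distinct = sorted(set(times))
    surv = []
    s = 1.0
    for t in distinct:
        at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        if at_risk > 0:
            s *= 1 - d / at_risk
        surv.append((t, s))
    return surv


def logrank_by_hand(t1, e1, t2, e2):
    """Two-group log-rank chi-square statistic via observed-minus-expected."""
    times = sorted(set([t for t, e in zip(t1, e1) if e == 1] + [t for t, e in zip(t2, e2) if e == 1]))
    O1 = E1 = V = 0.0
    for t in times:
        n1 = sum(1 for x in t1 if x >= t)
        n2 = sum(1 for x in t2 if x >= t)
        d1 = sum(1 for x, e in zip(t1, e1) if x == t and e == 1)
        d2 = sum(1 for x, e in zip(t2, e2) if x == t and e == 1)
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V if V > 0 else 0.0
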