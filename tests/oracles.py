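"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, enumeration, closed forms) and written
without reference to the library internals, so they can serve as oracles for
the optimized implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def dcor_bruteforce(x, y) -> float:
    """Distance correlation via explicit O(n^2) double centering."""
    x = [0.0 if math.isnan(v) else float(v) for v in x]
    y = [0.0 if math.isnan(v) else float(v) for v in y]
    n = len(x)

    def centered(v):
        d = [[abs(v[i] - v[j]) for j in range(n)] for i in range(n)]
        row = [sum(d[i]) / n for i in range(n)]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A = centered(x)
    B = centered(y)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvarx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvary = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvarx * dvary))


def mi_bruteforce(x, y, B=10) -> float:
    """Plug-in mutual information via explicit histogram loops (nats)."""
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < B:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]

    def bin_of(v, lo, hi):
        if hi == lo:
            return 0
        return min(int((v - lo) / (hi - lo) * B), B - 1)

    joint = [[0] * B for _ in range(B)]
    for a, b in pairs:
        joint[bin_of(a, min(xs), max(xs))][bin_of(b, min(ys), max(ys))] += 1
    n = len(pairs)
    mi = 0.0
    for i in range(B):
        for j in range(B):
            if joint[i][j] == 0:
                continue
            pij = joint[i][j] / n
            pi = sum(joint[i]) / n
            pj = sum(joint[k][j] for k in range(B)) / n
            mi += pij * math.log(pij / (pi * pj))
    return mi


def precision_recount(labels) -> list:
    """Cumulative precision by recounting labeled pairs at every rank."""
    out = []
    for r in range(1, len(labels) + 1):
        head = [v for v in labels[:r] if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if not head:
            out.append(float("nan"))
        else:
            out.append(sum(1 for v in head if v == 1) / len(head))
    return out


def auroc_paircount(scores, labels) -> float:
    """AUROC by counting concordant pos/neg pairs (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return float("nan")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def jaccard_sets(a, b) -> float:
    sa, sb = set(a), set(b)
    if not (sa | sb):
        return 0.0
    return len(sa & sb) / len(sa | sb)


def hypergeom_uppertail(k, M, K, n) -> float:
    """P(X >= k) for a hypergeometric(M, K, n) via exact binomials."""
    total = math.comb(M, n)
    p = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > M - K:
            continue
        p += math.comb(K, i) * math.comb(M - K, n - i) / total
    return p


def enumerate_labels(complexes: dict) -> tuple[set, set]:
    """Exhaustive intra-/inter-complex pair enumeration from a catalog."""
    positives = set()
    for members in complexes.values():
        for a, b in combinations(sorted(members), 2):
            positives.add((a, b) if a < b else (b, a))
    proteins = sorted({p for m in complexes.values() for p in m})
    negatives = set()
    for a, b in combinations(proteins, 2):
        pair = (a, b) if a < b else (b, a)
        if pair not in positives:
            negatives.add(pair)
    return positives, negatives


def logfit_closedform(steps, y):
    """Least-squares (a, b) for y = a + b*ln(step), via normal equations."""
    t = [math.log(s) for s in steps]
    n = len(t)
    tbar = sum(t) / n
    ybar = sum(y) / n
    b = sum((ti - tbar) * (yi - ybar) for ti, yi in zip(t, y)) / sum((ti - tbar) ** 2 for ti in t)
    a = ybar - b * tbar
    return a, b
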