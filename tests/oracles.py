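"""Independent brute-force reference implementations used as oracles.

Deliberately naive (double loops, direct formulas) and kept free of any
code shared with the package so that agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x: list[float], m: int, r: float) -> tuple[int, int]:
    """(A, B) template-match counts by direct O(N^2) enumeration."""
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def fuzzen_bruteforce(x: list[float], m: int, r: float, gradient: float) -> float:
    """Fuzzy entropy by direct double-loop evaluation."""
    nt = len(x) - m
    mean_m = [sum(x[i : i + m]) / m for i in range(nt)]
    mean_m1 = [sum(x[i : i + m + 1]) / (m + 1) for i in range(nt)]
    phi_m = phi_m1 = 0.0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = max(abs((x[i + k] - mean_m[i]) - (x[j + k] - mean_m[j])) for k in range(m))
            phi_m += math.exp(-((d / r) ** gradient))
            d1 = max(
                abs((x[i + k] - mean_m1[i]) - (x[j + k] - mean_m1[j])) for k in range(m + 1)
            )
            phi_m1 += math.exp(-((d1 / r) ** gradient))
    return -math.log(phi_m1 / phi_m)


def lz76_bruteforce(symbols: list[int]) -> int:
    """LZ76 phrase count: each phrase is the shortest prefix extension not
    reproducible by copying from anywhere earlier in the sequence."""
    n = len(symbols)
    if n <= 1:
        return n
    c = 0
    i = 0
    while i < n:
        k = 1
        while True:
            sub = symbols[i : i + k]
            reproducible = any(
                symbols[p : p + k] == sub for p in range(0, i)
            )
            if not reproducible or i + k >= n:
                c += 1
                i += k
                break
            k += 1
    return c


def auc_paircount(scores: list[float], labels: list[int]) -> float:
    """AUC as the fraction of correctly ordered (pos, neg) pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = len(pos) * len(neg)
    won = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return won / total


def rank_sum_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact rank-sum p via itertools over pooled midranks."""
    from itertools import combinations

    pooled = list(a) + list(b)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = midrank
        i = j + 1
    n_a = len(a)
    w_obs = sum(ranks[:n_a])
    mu = n_a * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(sum(ranks[t] for t in idx) - mu) >= dev:
            hits += 1
    return hits / total
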