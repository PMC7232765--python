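"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain scalar Python from the textbook
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple


def wc84_theta_scalar(n: Sequence[float], p: Sequence[float],
                      h: Sequence[float]) -> Tuple[float, float, float, float]:
    """Weir & Cockerham (1984) a, b, c and theta via direct scalar sums."""
    pops = [(ni, pi, hi) for ni, pi, hi in zip(n, p, h) if ni > 0]
    r = len(pops)
    nbar = sum(ni for ni, _, _ in pops) / r
    nsum = sum(ni for ni, _, _ in pops)
    nc = (nsum - sum(ni * ni for ni, _, _ in pops) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi, _ in pops) / nsum
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi, _ in pops) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, _, hi in pops) / nsum
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def variance_scalar(xs: Sequence[float]) -> float:
    """Sample variance (denominator n-1) by direct summation."""
    n = len(xs)
    mean = sum(xs) / n
    return sum((x - mean) ** 2 for x in xs) / (n - 1)


def pst_scalar(groups: Sequence[Sequence[float]]) -> float:
    """(Var_Total - Var_Sub)/Var_Total with direct scalar sums."""
    pooled = [x for g in groups for x in g]
    var_total = variance_scalar(pooled)
    var_sub = sum(variance_scalar(g) for g in groups) / len(groups)
    return (var_total - var_sub) / var_total


def bh_stepup(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def ks_statistic_categorical(fracs_a: Sequence[float],
                             fracs_b: Sequence[float]) -> float:
    """Sup difference of the two cumulative category distributions."""
    d, ca, cb = 0.0, 0.0, 0.0
    for a, b in zip(fracs_a, fracs_b):
        ca += a
        cb += b
        d = max(d, abs(ca - cb))
    return d
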