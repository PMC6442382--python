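"""Brute-force reference implementations used to cross-check the package.

Each oracle is deliberately naive (normal equations, explicit rank sums,
exact combinatorial tails, textbook formulas) and independent of the code
paths it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats


def ols_oracle(x, y) -> tuple[float, float]:
    """Intercept and slope from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    beta0, beta1 = np.linalg.solve(a, b)
    return float(beta0), float(beta1)


def midranks(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(a, b) -> float:
    """Rank both vectors with midranks, then Pearson on the ranks."""
    ra, rb = midranks(a), midranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra * ra).sum() * (rb * rb).sum()))


def hypergeom_upper_tail_oracle(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n), exact via Fractions."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(total)


def ttest_oracle(a, b) -> tuple[float, float]:
    """Equal-variance two-sample Student's t from the textbook formula;
    two-sided p from the t distribution."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def auc_rank_oracle(pos, neg) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def condition_specific_oracle(zs, outer=2.0, inner=1.0) -> bool:
    """Literal transcription of the rule: |z| greater than `outer` in one
    condition and |z| less than `inner` in all other conditions."""
    for i in range(len(zs)):
        if abs(zs[i]) > outer and all(abs(zs[j]) < inner for j in range(len(zs)) if j != i):
            return True
    return False
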