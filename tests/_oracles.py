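"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written for transparency, not speed: explicit Python
loops, no shared code with the package under test.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def _sigma(x):
    return float(np.std(np.asarray(x, float), ddof=1))


def _vectors(x, m, tau):
    n = len(x) - m * tau
    return [tuple(x[i + k * tau] for k in range(m)) for i in range(n)]


def _cheb(u, v):
    return max(abs(a - b) for a, b in zip(u, v))


def apen_naive(x, m=2, tau=1, r_coeff=0.2):
    x = np.asarray(x, float)
    r = r_coeff * _sigma(x)

    def phi(mm):
        vs = _vectors(x, mm, tau)
        n = len(vs)
        total = 0.0
        for i in range(n):
            c = sum(1 for j in range(n) if _cheb(vs[i], vs[j]) <= r) / n
            total += math.log(c)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_naive(x, m=2, tau=1, r_coeff=0.2):
    x = np.asarray(x, float)
    r = r_coeff * _sigma(x)

    def psi(mm):
        vs = _vectors(x, mm, tau)
        n = len(vs)
        total = 0.0
        for i in range(n):
            total += sum(
                1 for j in range(n) if j != i and _cheb(vs[i], vs[j]) < r
            ) / (n - 1)
        return total / n

    a, b = psi(m), psi(m + 1)
    if a <= 0 or b <= 0:
        return float("nan")
    return -math.log(b / a)


def fuzzyen_naive(x, m=2, tau=1, r_coeff=0.2):
    x = np.asarray(x, float)
    r = r_coeff * _sigma(x)

    def psi(mm):
        vs = _vectors(x, mm, tau)
        n = len(vs)
        total = 0.0
        for i in range(n):
            total += sum(
                math.exp(-math.log(2.0) * (_cheb(vs[i], vs[j]) / r) ** 2)
                for j in range(n)
                if j != i
            ) / (n - 1)
        return total / n

    return -math.log(psi(m + 1) / psi(m))


def disten_naive(x, m=2, tau=1, n_bins=64):
    x = np.asarray(x, float)
    vs = _vectors(x, m, tau)
    n = len(vs)
    dists = [_cheb(vs[i], vs[j]) for i in range(n) for j in range(i + 1, n)]
    lo, hi = min(dists), max(dists)
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for d in dists:
        b = min(int((d - lo) / width), n_bins - 1)
        counts[b] += 1
    total = len(dists)
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h / math.log2(n_bins)


def ce_naive(x, m=2, tau=1, xi=6):
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        q = [0] * len(x)
    else:
        q = [min(int((v - lo) / (hi - lo) * xi), xi - 1) for v in x]

    def se(tokens):
        counts = Counter(tokens)
        n = len(tokens)
        return -sum(c / n * math.log(c / n) for c in counts.values())

    w = [tuple(q[i : i + m]) for i in range(len(q) - m + 1)]
    z = [tuple(q[i : i + m + 1]) for i in range(len(q) - m)]
    wc = Counter(w)
    perc = sum(1 for t in w if wc[t] == 1) / len(w)
    return se(z) - se(w) + perc * se(q)


def permen_naive(x, m=3, tau=1):
    x = np.asarray(x, float)
    n = len(x) - (m - 1) * tau
    pats = []
    for i in range(n):
        w = [x[i + k * tau] for k in range(m)]
        order = sorted(range(m), key=lambda k: (w[k], k))  # stable ties
        pats.append(tuple(order))
    counts = Counter(pats)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h / math.log2(math.factorial(m))


def kappa_naive(cm):
    """Cohen's kappa straight from the definition."""
    cm = np.asarray(cm, float)
    n = cm.sum()
    po = sum(cm[i, i] for i in range(len(cm))) / n
    pe = sum(cm[i, :].sum() * cm[:, i].sum() for i in range(len(cm))) / n**2
    return (po - pe) / (1 - pe)


def majority_label_naive(stages, majority_min=9):
    """Brute-force 300-s labeling: (label or None) by plain counting."""
    if "EXCLUDED" in stages:
        return None
    counts = Counter(stages)
    lab, c = counts.most_common(1)[0]
    return lab if c >= majority_min else None
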