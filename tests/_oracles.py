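"""Independent reference implementations used to check the package's statistics.

These deliberately share no code with tgmseq: the exact test is
re-enumerated in arbitrary precision with mpmath, size factors and the
BH step-up rule are re-derived from their textbook definitions.
"""

from __future__ import annotations

import math

import mpmath as mp
import numpy as np

mp.mp.dps = 50


def _pmf_vector(K: int, mu, var) -> list:
    """pmf of 0..K for NB(mean mu, variance var) or Poisson when var == mu."""
    mu = mp.mpf(mu)
    var = mp.mpf(var)
    out = []
    if var <= mu:
        p0 = mp.e ** (-mu)
        out.append(p0)
        for k in range(K):
            out.append(out[-1] * mu / (k + 1))
    else:
        r = mu * mu / (var - mu)
        p = mu / var
        out.append(p**r)
        for k in range(K):
            out.append(out[-1] * (r + k) / (k + 1) * (1 - p))
    return out


def exact_test_oracle(kA: int, kB: int, sf_a, sf_b, dispersion: float) -> float:
    """Conditional NB exact test by full enumeration in arbitrary precision."""
    K = kA + kB
    if K == 0:
        return 1.0
    sa = [mp.mpf(x) for x in sf_a]
    sb = [mp.mpf(x) for x in sf_b]
    SA, SB = mp.fsum(sa), mp.fsum(sb)
    q = mp.mpf(K) / (SA + SB)
    muA, muB = SA * q, SB * q
    varA = muA + mp.mpf(dispersion) * q * q * mp.fsum(x * x for x in sa)
    varB = muB + mp.mpf(dispersion) * q * q * mp.fsum(x * x for x in sb)
    pA = _pmf_vector(K, muA, varA)
    pB = _pmf_vector(K, muB, varB)
    w = [pA[a] * pB[K - a] for a in range(K + 1)]
    total = mp.fsum(w)
    obs = w[kA]
    acc = mp.fsum(x for x in w if x <= obs * (1 + mp.mpf("1e-20")))
    return float(min(1, acc / total))


def size_factors_oracle(matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios, written out long-hand."""
    n, m = matrix.shape
    geo = np.array([
        math.exp(sum(math.log(x) for x in row) / m) if all(x > 0 for x in row) else float("nan")
        for row in matrix
    ])
    keep = ~np.isnan(geo)
    return np.array([np.median(matrix[keep, j] / geo[keep]) for j in range(m)])


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
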