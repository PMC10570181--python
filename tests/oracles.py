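"""Independent brute-force oracles used to check the fast implementations.

Each oracle is written from the defining formula, not from the code it
checks: BH by literal step-up over the sorted p-values, the hypergeometric
tail by binomial-coefficient enumeration, colocalisation by explicit
enumeration of causal-variant configurations, and single-instrument 2SLS
by the covariance-ratio estimate.
"""

from math import comb

import numpy as np


def bh_stepup_oracle(pvals: np.ndarray) -> np.ndarray:
    """Literal BH: q_(i) = min over j >= i of m p_(j) / j, capped at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(min(candidates), 1.0)
    return q


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) summed exactly from binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(n, K) + 1)) / total


def coloc_enumeration_oracle(labf1, labf2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Posterior over H0..H4 by enumerating causal-variant configurations.

    Works in plain linear space (fine for the |z| <= ~10 fixtures it is
    used with) over all (i, j) pairs of causal positions.
    """
    bf1 = np.exp(np.asarray(labf1, float))
    bf2 = np.exp(np.asarray(labf2, float))
    m = len(bf1)
    s = np.zeros(5)
    s[0] = 1.0
    s[1] = p1 * bf1.sum()
    s[2] = p2 * bf2.sum()
    for i in range(m):
        for j in range(m):
            if i == j:
                s[4] += p12 * bf1[i] * bf2[j]
            else:
                s[3] += p1 * p2 * bf1[i] * bf2[j]
    return s / s.sum()


def ratio_iv_oracle(g, x, y):
    """Single-instrument IV estimate: cov(g, y) / cov(g, x)."""
    g = np.asarray(g, float)
    return float(np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1])
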