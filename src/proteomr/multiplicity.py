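"""Multiple-testing control: Benjamini-Hochberg step-up q-values and
Bonferroni flags.

The proteome scan tests ~1500 proteins at once; significance is declared
either at BH FDR < 0.05 or at the stricter Bonferroni threshold
alpha / m (0.05 / 1463 in the reference analysis).
"""

from __future__ import annotations

import numpy as np

__all__ = ["bh_qvalues", "bonferroni_flags", "adjust_multiplicity"]


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), computed on the sorted p-values
    and mapped back to the input order.  Enforces monotonicity and caps at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_flags(pvals, alpha: float = 0.05) -> np.ndarray:
    """Boolean flags p < alpha / m with m the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=bool)
    return p < alpha / p.size


def adjust_multiplicity(pvals, method: str = "bh", alpha: float = 0.05):
    """Dispatch to BH q-values or Bonferroni significance flags.

    Parameters
    ----------
    pvals : array-like of p-values in (0, 1].
    method : "bh" returns q-values; "bonferroni" returns boolean flags.
    alpha : family-wise level for the Bonferroni threshold.
    """
    if method == "bh":
        return bh_qvalues(pvals)
    if method == "bonferroni":
        return bonferroni_flags(pvals, alpha=alpha)
    raise ValueError(f"unknown method {method!r}; use 'bh' or 'bonferroni'")
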