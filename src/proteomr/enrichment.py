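"""Hypergeometric over-representation of a protein list against gene sets.

Tests whether a selected protein list (e.g. the Bonferroni-significant
BMI-associated proteins) overlaps a gene-set term more than expected by
chance given the analysis universe, with BH FDR across terms.  The
universe defaults to the measured panel; swapping in an all-annotated
universe reproduces the sensitivity design in which relative term
importance changes but overlap counts do not.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from proteomr.multiplicity import bh_qvalues

logger = logging.getLogger("proteomr")

__all__ = ["hypergeom_test", "run_enrichment"]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N items, K annotated to the term, n selected, k selected-and-annotated.
    Computed via the survival function of the exact hypergeometric law
    (log-gamma based, numerically stable).
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_enrichment(selected, universe, collection: dict,
                   q_threshold: float = 0.05, min_size: int = 3,
                   max_size: int = 500) -> pd.DataFrame:
    """Over-representation of ``selected`` within each term of a collection.

    ``collection`` maps term id -> (description, member ids), the in-memory
    form produced by :func:`proteomr.readwrite.read_gmt`.  Members are
    intersected with the universe before testing; terms with fewer than
    ``min_size`` or more than ``max_size`` universe members are skipped.
    Returns records sorted by p with BH q-values and a significance flag.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("empty selected set")
    if not selected <= universe:
        raise ValueError("selected identifiers must be a subset of the "
                         "universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, (desc, members) in collection.items():
        mem = set(members) & universe
        if not mem:
            logger.debug("term %s has no universe members; skipped", term)
            continue
        if not min_size <= len(mem) <= max_size:
            continue
        hit = sorted(selected & mem)
        rows.append({"term": term, "description": desc,
                     "k": len(hit), "K": len(mem), "n": n, "N": N,
                     "p": hypergeom_test(len(hit), len(mem), n, N),
                     "members_hit": ";".join(hit)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_qvalues(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "term"]).reset_index(drop=True)
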