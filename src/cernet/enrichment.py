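"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

For a query gene list of size n drawn from a universe of N genes, and a gene
set with K members in the universe, the enrichment p-value is the
hypergeometric upper tail P(X >= x) where x is the observed overlap. The
universe is the explicit list when one is supplied, otherwise the union of
all set members; query ids outside the universe are dropped with a warning.
A set is called enriched when its BH-adjusted p-value is below the FDR
threshold (default 0.05).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05

ENRICH_COLUMNS = ["set_id", "set_name", "N", "K", "n", "x", "pvalue", "padj", "enriched"]


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), computed stably."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters N={N}, K={K}, n={n}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    # sf(x-1) = P(X > x-1) = P(X >= x)
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Test every gene set for over-representation of the query list.

    Only sets overlapping the query (x >= 1) are reported, sorted by
    (padj, set_id).
    """
    universe = collection.effective_universe()
    if not universe:
        raise ValueError("empty universe: no gene sets or explicit universe given")
    query_set = set(query)
    dropped = query_set - universe
    if dropped:
        logger.warning(
            "%d query id(s) absent from the universe were dropped", len(dropped)
        )
    query_in = query_set & universe
    N = len(universe)
    n = len(query_in)
    rows = []
    for sid in sorted(collection.sets):
        gs = collection.sets[sid]
        members_in = set(gs.members) & universe
        K = len(members_in)
        x = len(members_in & query_in)
        if x < 1:
            continue
        rows.append(
            {
                "set_id": sid,
                "set_name": gs.name,
                "N": N,
                "K": K,
                "n": n,
                "x": x,
                "pvalue": hypergeom_upper_tail(N, K, n, x),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c not in ("padj", "enriched")])
    if len(df):
        df["padj"] = bh_adjust(df["pvalue"])
        df["enriched"] = df["padj"] < fdr
        df = df.sort_values(["padj", "set_id"], ignore_index=True)
    else:
        df["padj"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df[ENRICH_COLUMNS]
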