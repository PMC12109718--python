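"""Hypergeometric over-representation analysis (ORA) with BH correction.

For a query gene list of size n drawn from a universe of size N, and a
gene set with K members in the universe, the enrichment p-value is the
upper tail of the hypergeometric distribution: the probability of
observing at least the seen overlap k,

    p = P(X >= k),  X ~ Hypergeom(N, K, n).

q-values are Benjamini-Hochberg adjusted across all tested sets of one
collection.  Rows are sorted by p, with ties broken by descending
overlap and then set name so output is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_tail(k, N: int, K: int, n: int):
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    Vectorized over ``k``.  P(X >= 0) = 1 by convention.
    """
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, N, K, n)


def ora(
    query: list[str] | pd.Index,
    universe: list[str] | pd.Index,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Test each gene set for over-representation in the query list.

    Returns a DataFrame with one row per tested set: overlap_k,
    set_size_K, query_size_n, universe_N, p_value, q_value and the
    overlapping genes, sorted by p_value.  Sets with no members in the
    universe are skipped and logged.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not query_set:
        raise ValueError("query gene list is empty")
    stray = query_set - universe_set
    if stray:
        raise ValueError(
            f"query must be a subset of the universe; {len(stray)} genes outside, "
            f"e.g. {sorted(stray)[:5]}"
        )
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name, members in sets.sets.items():
        in_universe = sorted(set(members) & universe_set)
        if not in_universe:
            logger.info("gene set %r has no members in the universe; skipped", name)
            continue
        K = len(in_universe)
        overlap = sorted(set(in_universe) & query_set)
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n,
                "universe_N": N,
                "p_value": float(hypergeom_tail(k, N, K, n)),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "overlap_k", "set_size_K", "query_size_n",
                "universe_N", "p_value", "q_value", "overlap_genes",
            ]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(
        ["p_value", "overlap_k", "set_name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df[
        [
            "set_name", "overlap_k", "set_size_K", "query_size_n",
            "universe_N", "p_value", "q_value", "overlap_genes",
        ]
    ]


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
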