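"""Hypergeometric over-representation of a query gene set against a GMT collection.

Given a universe of M background genes, a gene set with K members in the
universe, and a query of n genes with k members in the set, the one-sided
over-representation p-value is the hypergeometric upper tail
``P[X >= k]`` with ``X ~ Hypergeometric(M, K, n)``, BH-adjusted across the
collection. Depletion is not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .lr_database import canonical_symbol

__all__ = ["GeneSetCollection", "overrepresentation"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {canonical_symbol(g) for g in self.universe}
        clean: dict[str, set[str]] = {}
        for name, genes in self.sets.items():
            restricted = {canonical_symbol(g) for g in genes} & self.universe
            if restricted:
                clean[name] = restricted
        self.sets = clean
        if not self.universe:
            raise ValueError("universe is empty")


def overrepresentation(
    query: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Test the query against every set in the collection.

    The query is restricted to the universe first; an empty restricted query
    is an error (nothing can be tested). Rows are sorted by (q, p, set name)
    so the output is deterministic.
    """
    query_set = {canonical_symbol(g) for g in query} & collection.universe
    if not query_set:
        raise ValueError(
            "query is empty after restriction to the universe; "
            "check gene symbols or supply a wider universe"
        )
    M = len(collection.universe)
    n = len(query_set)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        k = len(query_set & genes)
        # upper tail P[X >= k]; sf(k-1) includes k itself
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append((name, k, n, K, M, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "query_size", "set_size", "universe_size", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values(["q", "p", "set_name"], kind="stable").reset_index(drop=True)
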