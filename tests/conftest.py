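"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lrnet.expression import ExpressionMatrix, GroupExpressionProfile


def make_matrix(genes, cells, dense) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a dense gene x cell array."""
    return ExpressionMatrix(
        X=sp.csr_matrix(np.asarray(dense)), genes=pd.Index(genes), cells=pd.Index(cells)
    )


def make_profile(fractions: dict, grouping: str = "cell_type", n_cells: int = 100) -> GroupExpressionProfile:
    """Build a profile from {(gene, group, condition): fraction}; unlisted entries are 0."""
    genes = sorted({g for (g, _, _) in fractions})
    strata = sorted({(grp, cond) for (_, grp, cond) in fractions})
    cols = pd.MultiIndex.from_tuples(strata, names=[grouping, "condition"])
    frame = pd.DataFrame(0.0, index=pd.Index(genes), columns=cols)
    for (g, grp, cond), f in fractions.items():
        frame.at[g, (grp, cond)] = f
    sizes = pd.Series(n_cells, index=cols)
    return GroupExpressionProfile(grouping, frame, sizes)


def random_network_instance(rng: np.random.Generator, max_groups: int = 10, max_pairs: int = 200):
    """A random toy instance: groups, an L-R pair list, and fractions per (gene, group, condition)."""
    n_groups = rng.integers(2, max_groups + 1)
    groups = [f"g{i}" for i in range(n_groups)]
    n_genes = int(rng.integers(5, 40))
    genes = [f"G{i}" for i in range(n_genes)]
    n_pairs = int(rng.integers(1, max_pairs + 1))
    pairs = sorted(
        {
            (genes[int(rng.integers(n_genes))], genes[int(rng.integers(n_genes))])
            for _ in range(n_pairs)
        }
    )
    conditions = ["condA", "condB"]
    fractions = {
        (g, grp, cond): float(rng.random())
        for g in genes
        for grp in groups
        for cond in conditions
    }
    return groups, genes, pairs, conditions, fractions


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
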