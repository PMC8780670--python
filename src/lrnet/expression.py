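"""Per-group gene detection fractions and the strict >20% expressed-gene rule.

A gene is *detected* in a cell when its raw count is > 0; a gene is *expressed*
in a (group, condition) stratum when it is detected in strictly more than a
threshold fraction (default 20%) of that stratum's cells. Detection is computed
on raw counts — normalization preserves zeros, so the detection indicator is
unaffected by per-cell scaling. Cells are pooled across samples within a
condition, matching a one-network-per-condition analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "GroupExpressionProfile", "summarize", "expressed_genes"]


@dataclass
class ExpressionMatrix:
    """Sparse non-negative gene x cell count matrix with gene/cell labels."""

    X: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("count matrix contains negative values")
        if self.genes.has_duplicates:
            dups = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after canonicalization: {dups[:5]}")
        if self.cells.has_duplicates:
            raise ValueError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def detection(self) -> sp.csr_matrix:
        """Boolean (0/1) detection indicator: count > 0."""
        D = self.X.copy()
        D.data = (D.data > 0).astype(np.int64)
        D.eliminate_zeros()
        return D


class GroupExpressionProfile:
    """Per-(group, condition) gene detection fractions.

    ``fractions`` is genes x strata (MultiIndex columns ``(group, condition)``),
    each entry the fraction of the stratum's cells in which the gene is
    detected; ``n_cells`` gives the stratum sizes. Genes not present in the
    profile are treated as never detected (fraction 0).
    """

    def __init__(self, grouping: str, fractions: pd.DataFrame, n_cells: pd.Series):
        if (fractions.to_numpy() < 0).any() or (fractions.to_numpy() > 1).any():
            raise ValueError("detection fractions must lie in [0, 1]")
        if (n_cells <= 0).any():
            raise ValueError("every stored stratum must contain at least one cell")
        self.grouping = grouping
        self.fractions = fractions
        self.n_cells = n_cells

    def strata(self) -> list[tuple[str, str]]:
        return list(self.fractions.columns)

    def groups(self, condition: str) -> list[str]:
        """Groups observed in ``condition``, in column order."""
        out = [g for (g, c) in self.fractions.columns if c == condition]
        if not out:
            raise KeyError(f"condition {condition!r} not present in profile")
        return out

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, c in self.fractions.columns:
            seen.setdefault(c, None)
        return list(seen)

    def fraction(self, gene: str, group: str, condition: str) -> float:
        """Detection fraction of ``gene`` in the stratum; 0.0 for genes absent from the matrix."""
        if (group, condition) not in self.fractions.columns:
            raise KeyError(f"unknown stratum ({group!r}, {condition!r})")
        if gene not in self.fractions.index:
            return 0.0
        return float(self.fractions.at[gene, (group, condition)])

    def expressed_genes(self, group: str, condition: str, threshold: float = 0.20) -> set[str]:
        """Genes with detection fraction strictly greater than ``threshold``.

        The inequality is strict: a gene detected in exactly 20% of cells is
        *not* expressed under the default rule.
        """
        if (group, condition) not in self.fractions.columns:
            raise KeyError(f"unknown stratum ({group!r}, {condition!r})")
        col = self.fractions[(group, condition)]
        return set(col.index[col.to_numpy() > threshold])

    def to_long(self) -> pd.DataFrame:
        """Long-format export: group, condition, gene, fraction, n_cells."""
        rows = []
        for (g, c) in self.fractions.columns:
            df = pd.DataFrame(
                {
                    "group": g,
                    "condition": c,
                    "gene": self.fractions.index,
                    "fraction": self.fractions[(g, c)].to_numpy(),
                    "n_cells": int(self.n_cells[(g, c)]),
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def summarize(
    matrix: ExpressionMatrix, ann: pd.DataFrame, grouping: str = "cell_type"
) -> GroupExpressionProfile:
    """Compute detection fractions per (group, condition) stratum.

    ``grouping`` names the annotation column that defines groups (typically
    ``cell_type`` or ``cluster_id``). Every matrix cell must have exactly one
    annotation row; annotation rows for cells absent from the matrix are
    ignored with a log entry.
    """
    if grouping not in ann.columns:
        raise ValueError(f"annotation has no column {grouping!r}")
    ann = ann.drop_duplicates(subset="cell_id")
    ann_idx = ann.set_index("cell_id")
    missing = matrix.cells.difference(ann_idx.index)
    if len(missing):
        raise ValueError(f"{len(missing)} matrix cells lack annotation (e.g. {list(missing[:3])})")
    extra = ann_idx.index.difference(matrix.cells)
    if len(extra):
        log.info("%d annotation rows refer to cells absent from the matrix; ignored", len(extra))
    ann_idx = ann_idx.loc[matrix.cells]

    keys = list(zip(ann_idx[grouping].astype(str), ann_idx["condition"].astype(str)))
    codes, uniques = pd.factorize(pd.Index(keys), sort=True)
    n_strata = len(uniques)
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(matrix.n_cells, n_strata),
    )
    detected_per_stratum = np.asarray((matrix.detection() @ indicator).todense())
    sizes = np.bincount(codes, minlength=n_strata).astype(float)
    fractions = pd.DataFrame(
        detected_per_stratum / sizes,
        index=matrix.genes,
        columns=pd.MultiIndex.from_tuples(list(uniques), names=[grouping, "condition"]),
    )
    n_cells = pd.Series(sizes.astype(int), index=fractions.columns)
    return GroupExpressionProfile(grouping, fractions, n_cells)


def expressed_genes(
    profile: GroupExpressionProfile, group: str, condition: str, threshold: float = 0.20
) -> set[str]:
    """Module-level convenience wrapper around :meth:`GroupExpressionProfile.expressed_genes`."""
    return profile.expressed_genes(group, condition, threshold)
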