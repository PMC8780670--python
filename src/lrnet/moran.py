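"""Moran's I spatial autocorrelation of gene expression over an embedding kNN graph.

For a weight matrix :math:`w` with total weight :math:`W` over :math:`N` cells
and an expression vector :math:`x`,

.. math::

    I = \\frac{N}{W} \\,
        \\frac{\\sum_i \\sum_j w_{ij} (x_i - \\bar x)(x_j - \\bar x)}
             {\\sum_i (x_i - \\bar x)^2}

I is roughly bounded in [-1, 1]: +1 for perfectly smooth variation over
neighbors, -1 for perfect dispersion, and expectation -1/(N-1) under random
permutation of the values over the nodes. The graph is a union-symmetrized
binary kNN adjacency on 2-D embedding coordinates, built per (cell type,
condition) stratum; significance comes from a seeded permutation test by
default, with a normal (randomization-moments) approximation as an opt-in
alternative. Screening per stratum gates each gene on positive I, a
Benjamini-Hochberg adjusted p <= alpha, and detection in at least ``min_frac``
of the stratum's cells; the cross-condition differential filter retains a
gene present in a single condition iff I > 0.1 and a gene present in both
iff |I_A - I_B| > 0.1 (both inequalities strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "EmbeddingGraph",
    "knn_graph",
    "morans_i",
    "moran_test",
    "screen_genes",
    "differential_filter",
]


@dataclass
class EmbeddingGraph:
    """Binary symmetric kNN adjacency over embedding points."""

    adjacency: sp.csr_matrix
    coords: np.ndarray
    nodes: pd.Index

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.nodes):
            raise ValueError("adjacency shape does not match node count")
        if A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if (abs(A - A.T) > 0).nnz:
            raise ValueError("adjacency must be symmetric")
        if (np.asarray(A.sum(axis=1)).ravel() == 0).any():
            raise ValueError("every node must have at least one neighbor")
        self.adjacency = A

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @property
    def W(self) -> float:
        return float(self.adjacency.sum())


def knn_graph(coords: np.ndarray | pd.DataFrame, k: int, nodes=None) -> EmbeddingGraph:
    """Union-symmetrized binary kNN graph on 2-D (or n-D) coordinates.

    Each point is linked to its k nearest Euclidean neighbors (self excluded);
    the adjacency is then symmetrized by union, so degrees are >= k. Distance
    ties are broken by node index, making the graph deterministic. Distances
    are computed in row chunks, so memory stays bounded for large strata.
    """
    if isinstance(coords, pd.DataFrame):
        if nodes is None:
            nodes = coords.index
        coords = coords.to_numpy(dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if nodes is None:
        nodes = pd.RangeIndex(n)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_points; got k={k}, n={n}")
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    chunk = 1024
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        # stable argsort breaks exact-distance ties by node index
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        cols[start * k : stop * k] = nn.ravel()
    A = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    A.data[:] = 1.0
    return EmbeddingGraph(adjacency=A, coords=coords, nodes=pd.Index(nodes))


def morans_i(x: np.ndarray, g: EmbeddingGraph) -> float:
    """Moran's I of values ``x`` over the graph; NaN for a constant vector.

    A constant vector has zero variance, so the statistic is undefined; the
    NaN return is the flag callers use to exclude the gene downstream.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != g.N:
        raise ValueError(f"expected {g.N} values, got {x.size}")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return math.nan
    num = float(z @ (g.adjacency @ z))
    return (g.N / g.W) * num / denom


def _analytic_p(i_obs: float, z: np.ndarray, g: EmbeddingGraph) -> float:
    """One-sided upper p under the randomization (permutation-moment) normal approximation."""
    n = g.N
    A = g.adjacency
    w = g.W
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((A + A.T).power(2)).sum())
    deg = np.asarray(A.sum(axis=0)).ravel() + np.asarray(A.sum(axis=1)).ravel()
    s2 = float((deg**2).sum())
    m2 = float((z**2).sum()) / n
    m4 = float((z**4).sum()) / n
    b2 = m4 / m2**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * w**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * w**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * w**2
    var = num / den - e_i**2
    if var <= 0:
        return 1.0
    return float(norm.sf((i_obs - e_i) / math.sqrt(var)))


def moran_test(
    x: np.ndarray,
    g: EmbeddingGraph,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
) -> tuple[float, float]:
    """Moran's I with a one-sided p-value for positive autocorrelation.

    The default is a seeded permutation test shuffling the values over nodes:
    ``p = (1 + #{I_perm >= I_obs}) / (1 + n_perm)``. ``method="analytic"``
    instead uses the normal approximation with mean -1/(N-1) and the
    randomization variance; its use should be flagged in any report. Returns
    ``(nan, nan)`` for a constant vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    i_obs = morans_i(x, g)
    if math.isnan(i_obs):
        return (math.nan, math.nan)
    z = x - x.mean()
    if method == "analytic":
        return (i_obs, _analytic_p(i_obs, z, g))
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'analytic'")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = g.adjacency
    obs_num = float(z @ (A @ z))  # denominator and N/W are permutation-invariant
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if float(zp @ (A @ zp)) >= obs_num:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return (i_obs, p)


def screen_genes(
    matrix: ExpressionMatrix,
    ann: pd.DataFrame,
    coords: pd.DataFrame,
    group: str,
    condition: str,
    k: int = 15,
    min_frac: float = 0.01,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    grouping: str = "cell_type",
    genes=None,
    method: str = "permutation",
) -> pd.DataFrame:
    """Per-gene Moran screen within one (group, condition) stratum.

    Expression values are log1p counts; the detection gate (``min_frac``)
    uses raw counts > 0. Every non-constant gene is tested; BH adjustment is
    over that tested family. A gene is called *present* when I > 0, q <=
    alpha, and its detection fraction is >= min_frac. Constant genes are
    reported with NaN statistics and reason ``"constant"``. Returns an empty
    frame (with a log entry) when the stratum has fewer than k+1 cells.
    """
    mask = (ann[grouping].astype(str) == str(group)) & (ann["condition"].astype(str) == str(condition))
    cell_ids = pd.Index(ann.loc[mask, "cell_id"].astype(str))
    cell_ids = cell_ids[cell_ids.isin(matrix.cells) & cell_ids.isin(coords.index)]
    columns = ["gene", "group", "condition", "I", "p", "q", "frac_expr", "present", "reason"]
    params = {"k": k, "min_frac": min_frac, "alpha": alpha, "n_perm": n_perm, "method": method}
    if len(cell_ids) < k + 1:
        log.warning(
            "stratum (%s, %s) has %d cells < k+1=%d; skipped", group, condition, len(cell_ids), k + 1
        )
        out = pd.DataFrame(columns=columns)
        out.attrs["moran_params"] = params
        return out
    col_idx = matrix.cells.get_indexer(cell_ids)
    sub = matrix.X.tocsc()[:, col_idx]
    g = knn_graph(coords.loc[cell_ids], k=k, nodes=cell_ids)
    gene_list = list(matrix.genes if genes is None else genes)
    gene_pos = matrix.genes.get_indexer(gene_list)
    if (gene_pos < 0).any():
        missing = [g_ for g_, p_ in zip(gene_list, gene_pos) if p_ < 0]
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    seeds = np.random.SeedSequence(seed).spawn(len(gene_list))
    rows = []
    for gene, pos, ss in zip(gene_list, gene_pos, seeds):
        counts = np.asarray(sub[pos].todense()).ravel()
        frac = float((counts > 0).mean())
        x = np.log1p(counts)
        if np.ptp(x) == 0.0:
            rows.append((gene, group, condition, math.nan, math.nan, frac, "constant"))
            continue
        i_obs, p = moran_test(x, g, n_perm=n_perm, seed=np.random.default_rng(ss), method=method)
        rows.append((gene, group, condition, i_obs, p, frac, ""))
    res = pd.DataFrame(rows, columns=["gene", "group", "condition", "I", "p", "frac_expr", "reason"])
    res["q"] = math.nan
    tested = res["p"].notna()
    if tested.any():
        res.loc[tested, "q"] = multipletests(res.loc[tested, "p"], method="fdr_bh")[1]
    res["present"] = (
        tested
        & (res["I"] > 0)
        & (res["q"] <= alpha)
        & (res["frac_expr"] >= min_frac)
    )
    res = res[columns]
    res.attrs["moran_params"] = params
    return res


def differential_filter(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    moran_min: float = 0.1,
    delta_min: float = 0.1,
) -> pd.DataFrame:
    """Cross-condition differential call from two Moran screens.

    Only genes *present* on at least one side are considered. A gene present
    in a single condition is retained iff its I is strictly greater than
    ``moran_min``; a gene present in both is retained iff
    ``|I_A - I_B|`` is strictly greater than ``delta_min``. Both screens must
    have been run with identical k / min_frac / alpha / n_perm parameters.
    """
    pa = res_a.attrs.get("moran_params")
    pb = res_b.attrs.get("moran_params")
    if pa is not None and pb is not None and pa != pb:
        raise ValueError(f"screen parameter mismatch: {pa} vs {pb}")
    def _present(res: pd.DataFrame) -> pd.DataFrame:
        if len(res) == 0:
            return pd.DataFrame(columns=["I"]).rename_axis("gene")
        return res[res["present"]].set_index("gene")

    a_present = _present(res_a)
    b_present = _present(res_b)
    genes = sorted(set(a_present.index) | set(b_present.index))
    rows = []
    for gene in genes:
        in_a = gene in a_present.index
        in_b = gene in b_present.index
        i_a = float(a_present.at[gene, "I"]) if in_a else math.nan
        i_b = float(b_present.at[gene, "I"]) if in_b else math.nan
        if in_a and in_b:
            pattern = "both"
            rule = f"|I_A - I_B| > {delta_min}"
            retained = abs(i_a - i_b) > delta_min
        else:
            pattern = "A_only" if in_a else "B_only"
            rule = f"I > {moran_min}"
            retained = (i_a if in_a else i_b) > moran_min
        rows.append((gene, pattern, i_a, i_b, "retained" if retained else "dropped", rule))
    return pd.DataFrame(rows, columns=["gene", "pattern", "I_A", "I_B", "decision", "rule"])
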