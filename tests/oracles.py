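"""Independent brute-force oracles used to check the implementation.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths under test: networks by exhaustive triple loops over
(pair, sender, receiver), Moran's I by a dense quadratic form, kNN by
all-pairs distance comparison, and the hypergeometric tail by explicit
binomial-coefficient enumeration.
"""

from __future__ import annotations

import math

import numpy as np


def brute_expressed(fractions: dict, group: str, threshold: float) -> set[str]:
    """Expressed genes by direct comparison: fraction strictly above threshold."""
    return {g for (g, grp), f in fractions.items() if grp == group and f > threshold}


def brute_network(expressed: dict, pairs: list, groups: list) -> dict:
    """Edge payloads by an exhaustive loop over db x senders x receivers."""
    edges: dict = {}
    for s in groups:
        for r in groups:
            payload = set()
            for (lig, rec) in pairs:
                if lig in expressed[s] and rec in expressed[r]:
                    payload.add((lig, rec))
            if payload:
                edges[(s, r)] = payload
    return edges


def brute_broadcast(edges: dict, groups: list) -> dict:
    """Unique ligand/receptor gene counts per group by enumeration."""
    out = {g: {"ligands": set(), "receptors": set()} for g in groups}
    for (s, r), payload in edges.items():
        for (lig, rec) in payload:
            out[s]["ligands"].add(lig)
            out[r]["receptors"].add(rec)
    return {g: (len(v["ligands"]), len(v["receptors"])) for g, v in out.items()}


def brute_diff(edges_a: dict, edges_b: dict, expressed_a: dict, expressed_b: dict) -> list:
    """Edge-by-edge set differences with side attribution from the expressed sets."""
    changes = []
    for edge in set(edges_a) | set(edges_b):
        s, r = edge
        pa = edges_a.get(edge, set())
        pb = edges_b.get(edge, set())
        for (lig, rec) in pa - pb:
            lig_ok = lig in expressed_b[s]
            rec_ok = rec in expressed_b[r]
            attr = "ligand_side" if (not lig_ok and rec_ok) else (
                "receptor_side" if (lig_ok and not rec_ok) else "both_sides")
            changes.append((s, r, lig, rec, "lost", attr))
        for (lig, rec) in pb - pa:
            lig_ok = lig in expressed_a[s]
            rec_ok = rec in expressed_a[r]
            attr = "ligand_side" if (not lig_ok and rec_ok) else (
                "receptor_side" if (lig_ok and not rec_ok) else "both_sides")
            changes.append((s, r, lig, rec, "gained", attr))
    return sorted(changes)


def dense_moran(x: np.ndarray, adjacency) -> float:
    """Moran's I as a dense quadratic form."""
    A = np.asarray(adjacency.todense(), dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    W = A.sum()
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        return math.nan
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += A[i, j] * z[i] * z[j]
    return (n / W) * num / denom


def brute_knn(coords: np.ndarray, k: int) -> set:
    """Union-symmetrized kNN edge set by all-pairs distances, ties broken by index."""
    n = coords.shape[0]
    edges = set()
    for i in range(n):
        d = [((coords[i] - coords[j]) ** 2).sum() for j in range(n)]
        order = sorted((dist, j) for j, dist in enumerate(d) if j != i)
        for (_, j) in order[:k]:
            edges.add((i, j))
            edges.add((j, i))
    return edges


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(M, K, n), by explicit enumeration."""
    total = math.comb(M, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(M - K, n - j)
    return acc / total
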