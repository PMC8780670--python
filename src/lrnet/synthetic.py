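"""Seeded synthetic snRNA-seq datasets with planted communication and spatial structure.

The generator emulates the statistical structure the downstream analyses
assume, not the full complexity of real tissue: a fixed panel of cell types
(default 8, subdivided into up to 26 clusters) across three conditions, a
per-(gene, cell type, condition) detection probability pi controlling the
fraction of cells in which a gene is detected, zero-truncated negative
binomial counts given detection, per-type Gaussian blobs as the 2-D
embedding, and "smooth" genes whose detection probability and mean rise
along the first embedding axis (hence positive Moran's I). Planted pi values
are kept at least ``threshold_margin`` away from the 0.20 expressed-gene
threshold so that, with a few hundred cells per stratum, realized detection
fractions land on the correct side of the threshold essentially always.

Every dataset ships with a :class:`TruthManifest` recording the expected
expressed-gene sets, the expected per-condition networks, and the planted
smooth genes, so pipeline recovery can be checked exactly. The flagship
scenario is a hub-receptor knockout (an integrin-beta1-like receptor shared
by many collagen/laminin ligands that collapses in one condition), which
plants a block of receptor-side edge losses for the network diff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from . import io as lio
from .expression import ExpressionMatrix
from .lr_database import LRDatabase, LRPair

__all__ = [
    "SyntheticConfig",
    "TruthManifest",
    "SyntheticDataset",
    "generate",
    "write_dataset",
    "read_dataset",
    "hub_knockout_config",
]

DEFAULT_CELL_TYPES = (
    "cardiomyocyte",
    "fibroblast",
    "endothelial",
    "pericyte",
    "smooth_muscle",
    "neuron",
    "dendritic_cell",
    "leukocyte",
)
DEFAULT_CLUSTERS = {
    "cardiomyocyte": 14,
    "fibroblast": 5,
    "endothelial": 2,
    "pericyte": 1,
    "smooth_muscle": 1,
    "neuron": 1,
    "dendritic_cell": 1,
    "leukocyte": 1,
}  # 26 clusters total
DEFAULT_CONDITIONS = ("normal", "nonobstructive", "obstructive")

THRESHOLD = 0.20  # the expressed-gene rule the margins are measured against


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic dataset; generation is a pure function of this."""

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    clusters_per_type: tuple[tuple[str, int], ...] = tuple(DEFAULT_CLUSTERS.items())
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    cells_per_group: int = 300
    samples_per_condition: int = 2
    genes: tuple[str, ...] = ()
    lr_pairs: tuple[tuple[str, str], ...] = ()
    #: explicit detection probabilities, (gene, cell_type, condition) -> pi
    detection: tuple[tuple[tuple[str, str, str], float], ...] = ()
    base_detection: float = 0.05
    #: planted smooth genes, (gene, cell_type, condition) -> (lo, hi) detection range
    smooth: tuple[tuple[tuple[str, str, str], tuple[float, float]], ...] = ()
    mu: float = 2.0
    theta: float = 2.0
    embedding_spread: float = 1.0
    threshold_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_group <= 0:
            raise ValueError("cells_per_group must be positive")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene panel contains duplicates")
        gene_set = set(self.genes)
        for (g, t, c), pi in self.detection:
            if g not in gene_set:
                raise ValueError(f"detection entry for unknown gene {g!r}")
            self._check_pi(pi, g)
        for (g, t, c), (lo, hi) in self.smooth:
            if g not in gene_set:
                raise ValueError(f"smooth entry for unknown gene {g!r}")
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"smooth range for {g!r} must satisfy 0 <= lo <= hi <= 1")
            self._check_pi((lo + hi) / 2, g)
        self._check_pi(self.base_detection, "<base>")
        for (lig, rec) in self.lr_pairs:
            if lig not in gene_set or rec not in gene_set:
                raise ValueError(f"L-R pair ({lig}, {rec}) uses genes outside the panel")

    def _check_pi(self, pi: float, gene: str) -> None:
        if not 0 <= pi <= 1:
            raise ValueError(f"pi for {gene!r} outside [0, 1]")
        if abs(pi - THRESHOLD) < self.threshold_margin:
            raise ValueError(
                f"planted pi={pi} for {gene!r} is within {self.threshold_margin} of the "
                f"{THRESHOLD} threshold; widen the margin or move pi"
            )

    @property
    def detection_map(self) -> dict[tuple[str, str, str], float]:
        return dict(self.detection)

    @property
    def smooth_map(self) -> dict[tuple[str, str, str], tuple[float, float]]:
        return dict(self.smooth)

    @property
    def clusters_map(self) -> dict[str, int]:
        return dict(self.clusters_per_type)

    def pi(self, gene: str, cell_type: str, condition: str) -> float:
        """Planted mean detection probability for a (gene, cell type, condition) stratum."""
        key = (gene, cell_type, condition)
        if key in self.smooth_map:
            lo, hi = self.smooth_map[key]
            return (lo + hi) / 2
        return self.detection_map.get(key, self.base_detection)

    def database(self) -> LRDatabase:
        return LRDatabase(LRPair(l, r, source="synthetic") for (l, r) in self.lr_pairs)


@dataclass
class TruthManifest:
    """What the generator planted, expressed in the analysis's own vocabulary."""

    expressed: dict[tuple[str, str], frozenset[str]]
    networks: dict[str, dict[tuple[str, str], tuple[tuple[str, str], ...]]]
    smooth: dict[tuple[str, str], frozenset[str]]

    def total_pairs(self, condition: str) -> int:
        return sum(len(p) for p in self.networks[condition].values())

    def expected_diff(self, cond_a: str, cond_b: str) -> list[dict]:
        """Expected edge changes A -> B with side attribution, by pure set logic."""
        net_a = self.networks[cond_a]
        net_b = self.networks[cond_b]
        changes: list[dict] = []
        for edge in sorted(set(net_a) | set(net_b)):
            s, r = edge
            pa, pb = set(net_a.get(edge, ())), set(net_b.get(edge, ()))
            for (lig, rec) in sorted(pa - pb):
                changes.append(
                    {
                        "sender": s, "receiver": r, "ligand": lig, "receptor": rec,
                        "direction": "lost",
                        "attribution": self._attr(lig, rec, s, r, cond_b),
                    }
                )
            for (lig, rec) in sorted(pb - pa):
                changes.append(
                    {
                        "sender": s, "receiver": r, "ligand": lig, "receptor": rec,
                        "direction": "gained",
                        "attribution": self._attr(lig, rec, s, r, cond_a),
                    }
                )
        return changes

    def _attr(self, lig: str, rec: str, s: str, r: str, other_cond: str) -> str:
        lig_ok = lig in self.expressed[(s, other_cond)]
        rec_ok = rec in self.expressed[(r, other_cond)]
        if not lig_ok and rec_ok:
            return "ligand_side"
        if lig_ok and not rec_ok:
            return "receptor_side"
        return "both_sides"

    def to_dict(self) -> dict:
        return {
            "expressed": {f"{t}|{c}": sorted(g) for (t, c), g in self.expressed.items()},
            "networks": {
                cond: {f"{s}->{r}": [list(p) for p in pairs] for (s, r), pairs in edges.items()}
                for cond, edges in self.networks.items()
            },
            "smooth": {f"{t}|{c}": sorted(g) for (t, c), g in self.smooth.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        expressed = {
            tuple(k.split("|")): frozenset(v) for k, v in d["expressed"].items()
        }
        networks = {
            cond: {
                tuple(e.split("->")): tuple(tuple(p) for p in pairs)
                for e, pairs in edges.items()
            }
            for cond, edges in d["networks"].items()
        }
        smooth = {tuple(k.split("|")): frozenset(v) for k, v in d["smooth"].items()}
        return cls(expressed=expressed, networks=networks, smooth=smooth)


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    coords: pd.DataFrame
    truth: TruthManifest
    config: SyntheticConfig


def _sample_ztnb(rng: np.random.Generator, mu, theta: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (resample zeros until none remain)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,))
    p = theta / (theta + mu)
    vals = rng.negative_binomial(theta, p)
    vals = np.atleast_1d(np.asarray(vals))
    while True:
        zeros = vals == 0
        if not zeros.any():
            return vals
        vals[zeros] = rng.negative_binomial(theta, p[zeros])


def _truth_networks(config: SyntheticConfig, expressed) -> dict:
    networks: dict[str, dict[tuple[str, str], tuple]] = {}
    pairs = sorted(set(config.lr_pairs))
    for cond in config.conditions:
        edges: dict[tuple[str, str], tuple] = {}
        for s in config.cell_types:
            for r in config.cell_types:
                payload = tuple(
                    (lig, rec)
                    for (lig, rec) in pairs
                    if lig in expressed[(s, cond)] and rec in expressed[(r, cond)]
                )
                if payload:
                    edges[(s, r)] = payload
        networks[cond] = edges
    return networks


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset; byte-identical for identical configs (the seed lives in the config)."""
    rng = np.random.default_rng(config.seed)
    clusters_map = config.clusters_map
    n = config.cells_per_group

    cell_ids: list[str] = []
    ann_rows: list[tuple] = []
    coord_rows: list[np.ndarray] = []
    strata: list[tuple[str, str, slice]] = []  # (cell_type, condition, column slice)
    n_types = len(config.cell_types)
    centers = {
        t: 6.0 * np.array([np.cos(2 * np.pi * i / n_types), np.sin(2 * np.pi * i / n_types)])
        for i, t in enumerate(config.cell_types)
    }
    offset = 0
    for cond in config.conditions:
        for t in config.cell_types:
            k_clusters = clusters_map.get(t, 1)
            for i in range(n):
                cid = f"{cond}.{t}.{i:05d}"
                cell_ids.append(cid)
                ann_rows.append(
                    (
                        cid,
                        t,
                        f"{t}_c{(i % k_clusters) + 1}",
                        cond,
                        f"{cond}_s{(i % config.samples_per_condition) + 1}",
                    )
                )
            coord_rows.append(centers[t] + rng.normal(0.0, config.embedding_spread, size=(n, 2)))
            strata.append((t, cond, slice(offset, offset + n)))
            offset += n

    coords_arr = np.vstack(coord_rows)
    annotation = pd.DataFrame(
        ann_rows, columns=["cell_id", "cell_type", "cluster_id", "condition", "sample_id"]
    )
    coords = pd.DataFrame(coords_arr, columns=["dim1", "dim2"], index=pd.Index(cell_ids, name="cell_id"))

    smooth_map = config.smooth_map
    rows_i: list[np.ndarray] = []
    cols_i: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for gi, gene in enumerate(config.genes):
        for (t, cond, sl) in strata:
            key = (gene, t, cond)
            if key in smooth_map:
                lo, hi = smooth_map[key]
                u = coords_arr[sl, 0]
                z = (u - u.mean()) / (u.std() or 1.0)
                f = expit(2.0 * z)
                pi_vec = lo + (hi - lo) * f
                mu_vec = config.mu * (0.5 + 1.5 * f)
            else:
                pi_vec = np.full(n, config.pi(gene, t, cond))
                mu_vec = np.full(n, config.mu)
            detected = np.nonzero(rng.random(n) < pi_vec)[0]
            if detected.size == 0:
                continue
            counts = _sample_ztnb(rng, mu_vec[detected], config.theta, detected.size)
            rows_i.append(np.full(detected.size, gi, dtype=np.int64))
            cols_i.append(detected + sl.start)
            vals.append(counts.astype(np.int64))

    if rows_i:
        X = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(cols_i))),
            shape=(len(config.genes), len(cell_ids)),
        )
    else:
        X = sp.csr_matrix((len(config.genes), len(cell_ids)), dtype=np.int64)
    matrix = ExpressionMatrix(X=X, genes=pd.Index(config.genes), cells=pd.Index(cell_ids))

    expressed = {
        (t, c): frozenset(g for g in config.genes if config.pi(g, t, c) > THRESHOLD)
        for c in config.conditions
        for t in config.cell_types
    }
    smooth_truth: dict[tuple[str, str], set[str]] = {}
    for (g, t, c) in smooth_map:
        smooth_truth.setdefault((t, c), set()).add(g)
    truth = TruthManifest(
        expressed=expressed,
        networks=_truth_networks(config, expressed),
        smooth={k: frozenset(v) for k, v in smooth_truth.items()},
    )
    return SyntheticDataset(matrix=matrix, annotation=annotation, coords=coords, truth=truth, config=config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as MTX triplet + annotation/coords TSV + pairs CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = lio.write_mtx_dir(dataset.matrix, outdir)
    paths["annotation"] = lio.write_annotation(dataset.annotation, outdir / "annotation.tsv")
    paths["coords"] = lio.write_coords(dataset.coords, outdir / "coords.tsv")
    paths["pairs"] = outdir / "pairs.csv"
    dataset.config.database().to_csv(paths["pairs"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=2, sort_keys=True)
    return paths


def read_dataset(outdir: str | Path):
    """Read back (matrix, annotation, coords, truth) written by :func:`write_dataset`."""
    outdir = Path(outdir)
    matrix = lio.read_mtx_dir(outdir)
    annotation = lio.read_annotation(outdir / "annotation.tsv")
    coords = lio.read_coords(outdir / "coords.tsv")
    with open(outdir / "truth.json", encoding="utf-8") as fh:
        truth = TruthManifest.from_dict(json.load(fh))
    return matrix, annotation, coords, truth


# --- the flagship scenario -------------------------------------------------

HUB_RECEPTOR = "ITGB1"
HUB_LIGANDS = (
    "COL1A2", "COL3A1", "COL4A1", "COL6A1", "COL6A2",
    "COL6A3", "FN1", "LAMA2", "LGALS1", "LUM",
)


def hub_knockout_config(
    seed: int = 0,
    cells_per_group: int = 300,
    n_null_genes: int = 40,
    n_smooth: int = 6,
    expressed_pi: float = 0.5,
    knocked_pi: float = 0.02,
) -> SyntheticConfig:
    """The study-conditions scenario: three conditions, 8 cell types, a hub-receptor knockout.

    The hub receptor (integrin-beta1-like) is expressed in dendritic cells and
    leukocytes under normal and nonobstructive conditions but collapses to
    ``knocked_pi`` in the obstructive condition, while its ten cognate ligands
    stay expressed in fibroblasts and neurons throughout — so every pair lost
    on the affected edges is attributable to the receptor side. Two further
    tiers of pairs (expressed in all conditions; expressed in normal and
    nonobstructive only) make the per-condition totals decline stepwise,
    normal > nonobstructive > obstructive, as in diseased tissue. Smooth genes
    are planted in cardiomyocytes: half specific to the nonobstructive
    condition, half shared by both disease conditions with matched profiles.
    """
    conditions = DEFAULT_CONDITIONS
    detection: dict[tuple[str, str, str], float] = {}

    def express(gene: str, types: tuple[str, ...], conds: tuple[str, ...], pi: float = expressed_pi):
        for t in types:
            for c in conds:
                detection[(gene, t, c)] = pi

    # hub: ligands broadcast by fibroblasts and neurons in every condition
    for lig in HUB_LIGANDS:
        express(lig, ("fibroblast", "neuron"), conditions)
    express(HUB_RECEPTOR, ("dendritic_cell", "leukocyte"), ("normal", "nonobstructive"))
    express(HUB_RECEPTOR, ("dendritic_cell", "leukocyte"), ("obstructive",), pi=knocked_pi)

    tier_all = (("TGFB1", "TGFBR1"), ("VEGFA", "KDR"), ("DLL4", "NOTCH1"))
    for lig, rec in tier_all:
        express(lig, ("fibroblast", "endothelial"), conditions)
        express(rec, ("cardiomyocyte", "endothelial", "pericyte"), conditions)
    tier_no_obstructive = (("PDGFB", "PDGFRB"), ("IGF1", "IGF1R"), ("BMP4", "BMPR2"))
    for lig, rec in tier_no_obstructive:
        express(lig, ("cardiomyocyte", "fibroblast"), ("normal", "nonobstructive"))
        express(rec, ("fibroblast", "smooth_muscle"), ("normal", "nonobstructive"))
    tier_normal_only = (("NPPA", "NPR1"), ("WNT5A", "FZD4"), ("JAG1", "NOTCH3"), ("EFNB2", "EPHB4"))
    for lig, rec in tier_normal_only:
        express(lig, ("neuron", "cardiomyocyte"), ("normal",))
        express(rec, ("endothelial", "leukocyte"), ("normal",))

    lr_pairs = tuple((lig, HUB_RECEPTOR) for lig in HUB_LIGANDS) + tier_all + tier_no_obstructive + tier_normal_only

    smooth: dict[tuple[str, str, str], tuple[float, float]] = {}
    smooth_genes = tuple(f"SMOOTH{i + 1:02d}" for i in range(n_smooth))
    for i, g in enumerate(smooth_genes):
        if i < n_smooth // 2:
            smooth[(g, "cardiomyocyte", "nonobstructive")] = (0.05, 0.65)
        else:
            smooth[(g, "cardiomyocyte", "nonobstructive")] = (0.05, 0.65)
            smooth[(g, "cardiomyocyte", "obstructive")] = (0.05, 0.65)

    null_genes = tuple(f"NULL{i + 1:03d}" for i in range(n_null_genes))
    lr_genes: list[str] = []
    for lig, rec in lr_pairs:
        for g in (lig, rec):
            if g not in lr_genes:
                lr_genes.append(g)
    genes = tuple(lr_genes) + smooth_genes + null_genes

    return SyntheticConfig(
        cells_per_group=cells_per_group,
        genes=genes,
        lr_pairs=lr_pairs,
        detection=tuple(sorted(detection.items())),
        smooth=tuple(sorted(smooth.items())),
        seed=seed,
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
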