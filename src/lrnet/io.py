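"""Readers and writers for the plain-text formats the pipeline consumes.

Counts travel as a Matrix Market triplet (``matrix.mtx`` with genes as rows,
plus ``genes.tsv`` and ``barcodes.tsv`` sidecars, the 10x convention); cell
annotations and embedding coordinates are TSV; gene-set collections are GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .lr_database import canonical_symbol

ANNOTATION_COLUMNS = ("cell_id", "cell_type", "cluster_id", "condition", "sample_id")

__all__ = [
    "ANNOTATION_COLUMNS",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_annotation",
    "write_annotation",
    "read_coords",
    "write_coords",
    "read_gmt",
]


def read_mtx_dir(path: str | Path):
    """Read a 10x-style Matrix Market directory into an :class:`~lrnet.expression.ExpressionMatrix`.

    ``genes.tsv`` may carry one column (symbol) or two (id, symbol); the last
    column is taken as the gene symbol and canonicalized.
    """
    from .expression import ExpressionMatrix

    path = Path(path)
    X = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes_df = pd.read_csv(path / "genes.tsv", sep="\t", header=None, dtype=str)
    genes = pd.Index([canonical_symbol(s) for s in genes_df.iloc[:, -1]])
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, dtype=str)
    cells = pd.Index(barcodes.iloc[:, 0])
    return ExpressionMatrix(X=X, genes=genes, cells=cells)


def write_mtx_dir(matrix, path: str | Path) -> dict[str, Path]:
    """Write an ExpressionMatrix as ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": path / "matrix.mtx",
        "genes": path / "genes.tsv",
        "barcodes": path / "barcodes.tsv",
    }
    coo = sp.coo_matrix(matrix.X)
    scipy.io.mmwrite(paths["matrix"], coo, field="integer")
    pd.DataFrame({"id": matrix.genes, "symbol": matrix.genes}).to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    pd.Series(matrix.cells).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-cell annotation TSV (cell_id, cell_type, cluster_id, condition, sample_id)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"{path}: annotation is missing columns {missing}")
    if ann["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell_id values in annotation")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ann.to_csv(path, sep="\t", index=False)
    return path


def read_coords(path: str | Path) -> pd.DataFrame:
    """Read 2-D embedding coordinates: TSV with columns cell_id, dim1, dim2."""
    coords = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    for c in ("cell_id", "dim1", "dim2"):
        if c not in coords.columns:
            raise ValueError(f"{path}: coordinates need columns cell_id, dim1, dim2")
    coords = coords.set_index("cell_id")[["dim1", "dim2"]].astype(float)
    if not np.isfinite(coords.to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return coords


def write_coords(coords: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    coords.rename_axis("cell_id").reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: ``name<TAB>description<TAB>gene...`` per line.

    Gene symbols are canonicalized; empty sets are dropped.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0].strip()
            genes = {canonical_symbol(g) for g in parts[2:] if g.strip()}
            if name and genes:
                sets[name] = genes
    return sets
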