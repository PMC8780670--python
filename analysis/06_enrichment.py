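#!/usr/bin/env python
"""Over-representation of the lost ligands against a small synthetic gene-set collection.

The query is the set of ligands appearing in pairs lost from nonobstructive to
obstructive; the collection is a synthetic stand-in for a functional catalogue
(one extracellular-matrix/adhesion set that contains the hub's cognate
ligands, plus unrelated sets). The universe is every gene detected in at
least one cell, the module default.
"""

from pathlib import Path

import pandas as pd

from lrnet.enrichment import GeneSetCollection, overrepresentation
from lrnet.io import read_mtx_dir

ROOT = Path(__file__).resolve().parents[1]

# synthetic stand-in for a functional gene-set catalogue
SYNTHETIC_SETS = {
    "ECM_adhesion": {"COL1A2", "COL3A1", "COL4A1", "COL6A1", "COL6A2", "COL6A3",
                     "FN1", "LAMA2", "LGALS1", "LUM", "ITGB1"},
    "growth_factor_signaling": {"TGFB1", "TGFBR1", "PDGFB", "PDGFRB", "IGF1", "IGF1R",
                                "VEGFA", "KDR", "BMP4", "BMPR2"},
    "notch_ephrin": {"DLL4", "NOTCH1", "JAG1", "NOTCH3", "EFNB2", "EPHB4"},
}


def main() -> None:
    data = ROOT / "scratch" / "data"
    outdir = ROOT / "results" / "analysis"
    diff = pd.read_csv(outdir / "diff_nonobstructive_obstructive.tsv", sep="\t")
    lost_ligands = sorted(set(diff.loc[diff["direction"] == "lost", "ligand"]))
    print(f"query: {len(lost_ligands)} ligands lost nonobstructive -> obstructive")

    matrix = read_mtx_dir(data)
    detected = set(matrix.genes[(matrix.X > 0).sum(axis=1).A.ravel() > 0])
    coll = GeneSetCollection(sets=SYNTHETIC_SETS, universe=detected)
    rows = overrepresentation(lost_ligands, coll)
    rows.to_csv(outdir / "enrichment_lost_ligands.tsv", sep="\t", index=False)
    print(rows.to_string(index=False))
    top = rows.iloc[0]
    print(f"top set: {top['set_name']} (overlap {top['overlap']}/{top['set_size']}, "
          f"q = {top['q']:.2e})")


if __name__ == "__main__":
    main()
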