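# lrnet

Ligand–receptor intercellular communication networks and Moran's-I
differential screening for single-nucleus RNA-seq, built for cross-condition
comparisons of tissue states — the motivating case is interventricular-septum
snRNA-seq from hypertrophic cardiomyopathy (HCM), where obstructive and
nonobstructive disease differ in how cell types talk to each other, most
strikingly through loss of the integrin-β1 (ITGB1) receptor hub and its
extracellular-matrix ligands.

The package is aimed at computational biologists who have upstream
processing done (counts, cell-type/cluster annotation, a 2-D embedding) and
want a reproducible, testable implementation of the downstream communication
analysis:

- **L–R database handling** — load, canonicalize, merge, and deduplicate
  published ligand–receptor catalogues on the directed (ligand, receptor)
  gene-pair key.
- **Expressed-gene calling** — a gene is *expressed* in a (cell type,
  condition) stratum when it is detected (raw count > 0) in strictly more
  than 20% of that stratum's cells.
- **Communication networks** — per condition, a directed multigraph over
  cell groups: edge (s, r) carries every pair (L, R) with L expressed in the
  sender and R in the receiver; self-loops included.
- **Network diffs with attribution** — each pair lost or gained between two
  conditions is attributed to the ligand side, the receptor side, or both,
  which is what reveals hub-receptor collapses.
- **Moran's I screening** — per (cell type, condition), the graph
  autocorrelation statistic

  ```
  I = (N / W) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²
  ```

  over a union-symmetrized binary kNN graph on the embedding (wᵢⱼ the
  adjacency, W = Σᵢⱼ wᵢⱼ), with a seeded permutation test, BH adjustment,
  and a ≥1%-detected gate; a cross-condition filter then retains genes
  present in one condition iff I > 0.1 and genes present in both iff
  |I_A − I_B| > 0.1.
- **Over-representation** — hypergeometric upper-tail enrichment of any
  query set (e.g. lost ligands) against a user-supplied GMT collection.
- **Synthetic data** — a seeded generator that plants detection
  probabilities, a hub-receptor knockout, and embedding-smooth genes, with a
  truth manifest so every stage can be checked exactly.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each builds on the previous one's outputs):

```
python analysis/01_simulate.py       # 77 genes x 7200 cells -> scratch/data/
python analysis/02_expression_summary.py
python analysis/03_networks.py
python analysis/04_network_diff.py
python analysis/05_moran_screen.py
python analysis/06_enrichment.py
```

`03_networks.py` prints the per-condition totals of realized
ligand–receptor pairs:

```
total realized ligand-receptor pairs per condition:
  nonobstructive: 70
  normal: 86
  obstructive: 18
```

— communication declines stepwise from normal to nonobstructive to
obstructive, as planted. `04_network_diff.py` then attributes the losses:

```
nonobstructive -> obstructive: 52 pairs lost, 0 gained
attribution of losses: {'both_sides': 12, 'receptor_side': 40}
  losses into dendritic_cell: 20, by receptor: {'ITGB1': 20}
  losses into leukocyte: 20, by receptor: {'ITGB1': 20}
```

All 40 losses into dendritic cells and leukocytes trace to the single
knocked-out ITGB1 receptor — the hub pattern the diff attribution exists to
expose. `05_moran_screen.py` retains exactly the three smooth genes planted
in one condition only (genes smooth in both conditions have |ΔI| ≤ 0.1 and
are dropped), and `06_enrichment.py` finds the lost ligands over-represented
in the ECM/adhesion set (overlap 10/11, q ≈ 8e-09).

The same stages are available as subcommands of the `lrnet` CLI
(`simulate`, `summarize`, `network`, `diff`, `moran`, `filter`, `enrich`,
`report`) for use on real data exported as MTX + TSV.

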