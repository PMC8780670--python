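# Methods

## The communication model

The analysis treats intercellular communication as a binary, expression-gated
relation. Within one condition, cells are pooled across samples and grouped
by cell type (or cluster). A gene is *detected* in a cell when its raw count
is positive; it is *expressed* in a (group, condition) stratum when detected
in strictly more than a threshold fraction (default 0.20) of the stratum's
cells. Detection deliberately uses raw counts: any sensible per-cell
normalization preserves zeros, so the detection indicator — and with it every
downstream result — is invariant to library-size scaling. The strict
inequality matters only at exact ties (a gene detected in exactly 20% of
cells is not expressed) and is tested at the boundary.

Given a ligand–receptor catalogue — a deduplicated set of *directed* gene
pairs, canonicalized to upper-case symbols with no synonym resolution — the
condition's communication network places, on every ordered pair of groups
(s, r) including s = r, the payload

```
payload(s, r) = {(L, R) in DB : L expressed in s, R expressed in r}.
```

The per-condition total is the sum of payload sizes; per-group "broadcast"
counts are unique ligand genes appearing in any realized pair with the group
as sender (receptors mirror-image). Counting unique genes rather than pair
slots is a choice — both are computed, unique genes is the default
(`broadcast_summary(..., unit="pair_slots")` gives the alternative).

Two same-grouping networks are diffed edge by edge. A pair lost going
A → B is attributed to the *ligand side* if the ligand's detection fraction
fell to ≤ threshold in the sender under B while the receptor stayed
expressed in the receiver, to the *receptor side* in the converse case, and
to *both sides* if both fell; gains are attributed symmetrically with the
roles of A and B swapped. This attribution is what makes hub patterns
legible: a single receptor collapsing in one receiver group converts into a
block of receptor-side losses across all of its cognate ligands, which is
exactly the integrin-β1 phenomenon that motivates the design.

Because the relation is binary and threshold-gated, enlarging any expressed
set can only add pairs (monotonicity), totals are invariant to group
relabeling, and applying a diff to network A reconstructs network B — all
three are enforced as property tests against brute-force enumeration.

## Moran's I screening

Spatial differential expression is assessed per (cell type, condition)
stratum on a 2-D embedding supplied as input (the package does not compute
embeddings). The spatial domain is a union-symmetrized binary kNN graph,
default k = 15, built on that stratum's cells only; exact-distance ties
break by node index so the graph is deterministic. For expression values x
(log1p counts) the statistic is

```
I = (N / W) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²
```

with expectation −1/(N−1) under random permutation of values over nodes.
Constant vectors have undefined I and are flagged (NaN with reason code)
rather than tested. Significance is a one-sided seeded permutation test for
positive autocorrelation, p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm),
default n_perm = 999; a normal approximation using the randomization
moments is available as an opt-in alternative (`method="analytic"`) and is
flagged in the output parameters. Only the quadratic form is recomputed per
permutation — the denominator and N/W are permutation-invariant.

A gene is *present* in a stratum when I > 0, its BH-adjusted q over the
tested family (all non-constant genes in that stratum) is ≤ 0.05, and it is
detected in ≥ 1% of the stratum's cells. The cross-condition filter then
retains a gene present in exactly one condition iff I > 0.1, and a gene
present in both iff |I_A − I_B| > 0.1, both strict. The two screens must
share k, n_perm, alpha, and the detection gate; a mismatch is an error.

A note on resolution: with n_perm permutations the smallest attainable p is
1/(n_perm + 1), so the smallest attainable BH q over a family of m genes
with t true positives is roughly m/(t·(n_perm+1)). At the default
n_perm = 999 a 500-gene family with ~20 signals bottoms out near q ≈ 0.025;
199 permutations would make q ≤ 0.05 unreachable for such families, which is
why 999 is the default even though 199 suffices for raw-p calibration.

## Over-representation

Any query gene set (lost ligands, differential genes, …) is tested against a
user-supplied GMT collection by the hypergeometric upper tail
P[X ≥ k], X ~ Hypergeometric(M, K, n), BH-adjusted across the collection.
The universe defaults to all genes detected in at least one cell of the
analyzed stratum and can be overridden; query and sets are restricted to the
universe first, and an empty restricted query is an error. Only
over-representation is tested.

## The synthetic-data generator

The generator emulates the statistical structure the analysis consumes and
nothing more. Per (gene, cell type, condition) stratum a detection
probability π controls the Bernoulli detection layer; detected cells draw
counts from a zero-truncated negative binomial (mean μ = 2, dispersion
θ = 2 — typical of shallow snRNA-seq nuclei). The embedding is a Gaussian
blob per cell type (spread 1.0, centers on a circle); *smooth* genes replace
the constant π by lo + (hi−lo)·logistic(2·z₁) of the standardized first
embedding coordinate (default range 0.05–0.65) and scale μ by the same
logistic factor, giving genuinely positive Moran's I.

The default scenario (`hub_knockout_config`) mirrors the study conditions:
8 cell types subdividable into 26 clusters, 3 conditions (normal,
nonobstructive, obstructive), 300 cells per (type, condition), a hub
receptor expressed at π = 0.5 in dendritic cells and leukocytes that drops
to π = 0.02 in the obstructive condition while its ten cognate
ECM-associated ligands stay at π = 0.5 in fibroblasts and neurons, plus two
pair tiers that switch off along the condition axis so totals decline
stepwise. Every planted π is required to sit at least 0.1 from the 0.20
threshold (validated at config construction): at 300 cells per stratum the
binomial fluctuation of a realized fraction is ~0.03 SD, so realized
fractions land on the correct side of the threshold essentially always, and
the truth manifest — expected expressed sets, expected networks, expected
diff with attributions, planted smooth genes — can be compared *exactly*
against the pipeline.

What the generator does not emulate: batch effects, ambient RNA, doublets,
realistic gene-count scale (tens of genes, not tens of thousands), cluster
heterogeneity within a cell type (clusters of a type share π), or embeddings
learned from the expression itself. Passing tests therefore demonstrate
correctness of the counting, thresholding, graph, and inference machinery
under the model's assumptions — not robustness to upstream artifacts of real
tissue data.

## Numerical and design choices

- Dedup key for catalogues is the canonicalized (ligand, receptor) tuple;
  direction matters; self-pairs are kept; no complex/multi-subunit modeling.
- kNN graphs are computed by chunked exact distances with stable-sort tie
  break, not a tree structure, so results are deterministic and exact; this
  targets strata up to a few tens of thousands of cells.
- BH adjustment is applied within each (group, condition) family.
- Seeds: every stochastic component takes an explicit seed; per-gene
  permutation streams are spawned from a root `SeedSequence`, so screens are
  reproducible and gene-order independent.
- Problem sizes in the shipped drivers and acceptance run (7200-cell study,
  500-cell calibration and recovery strata, 1000 null genes) were chosen so
  the planted effects are unambiguous at desk scale; the statistics they
  feed are size-agnostic.
- CLI exit codes: 0 success, 2 configuration/usage error, 3 data error;
  partial outputs of a failed subcommand are removed; every subcommand
  writes a run log with parameters, seed, input SHA-256 digests, and the
  package version (no timestamps, keeping reruns byte-identical).

## Limitations

- Communication is potential, not measured: co-expression above a detection
  threshold, with no magnitude weighting, no ligand diffusion or spatial
  proximity, and no statistical test on edges (by design — the counting
  itself is the object of interest).
- The Moran screen conditions on the embedding being a faithful spatial
  domain; distortions in the embedding propagate directly into I.
- Catalogue quality bounds everything: the package deduplicates and merges
  lists but does not curate them, resolve aliases, or map orthologs.
- Reproducing the original tissue study's printed pair counts requires its
  deposited datasets and upstream labels (integration, clustering, cell-type
  assignment), which are outside this package's scope; the pipeline accepts
  such data in the documented formats once prepared.
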