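# Methods

## Scope and data model

`netpharm` implements an inference chain for poly-pharmacological
compounds: curated drug–target interactions (DTIs) plus binary substructure
fingerprints feed a tripartite diffusion model that ranks candidate
targets; the resulting target profile is tested for enrichment in
per-cancer significantly-mutated-gene (SMG) sets to rank cancer
indications. Gene identity is the uppercased HGNC-style symbol throughout;
Entrez ids and chromosome locations, when present, are annotation only.

## Interaction curation

`merge_dti_sources` applies three rules in order: rows from score-bearing
sources (STITCH) are kept only when the experimental evidence score is
strictly greater than the cutoff (default 0.7); rows failing the species
filter (default *Homo sapiens*, exact match after trimming and
case-folding; a missing species column passes) are dropped; duplicate
(drug, gene) pairs collapse to one record carrying the union of sources and
the maximum score. Records are sorted by (drug, gene), which makes merging
idempotent and order-insensitive — both are property-tested. SMG catalogs
are GMT files; cancer types with fewer than `min_smg` genes (default 20)
are excluded for lack of statistical power, and the dropped codes are
logged.

## The diffusion model

The network has three layers — drugs, substructures, targets — and two
bipartite edge sets (drug–substructure incidence, known DTIs). There are no
within-layer or substructure–target edges. All-zero substructure columns
are pruned at construction: an unused fragment is an isolated node.

Parameters (defaults α = β = 0.1, γ = −0.5, k = 2, adopted from benchmark
tuning of this model family):

| parameter | role | default |
|---|---|---|
| α ∈ [0,1] | seed-mass split: α to the query's substructures, 1−α to its known targets | 0.1 |
| β ∈ [0,1] | edge-type weight drug-outward: β per drug–substructure edge, 1−β per drug–target edge | 0.1 |
| γ ∈ ℝ | exponent on the receiving node's degree drug-outward; γ < 0 penalizes hubs | −0.5 |
| k ∈ ℕ | number of diffusion rounds | 2 |

One round is phase A (every substructure/target node splits its resource
equally among its drug neighbours) then phase B (every drug sends its
resource to its neighbours with per-edge weight `edge-type weight ×
deg(receiver)^γ`, renormalized per drug). Applying the hub penalty at the
receiving end and renormalizing per sender keeps the process a proper
stochastic flow for every γ: total mass is exactly 1 after every phase
(asserted to 1e−12 on each call). The published description of this model
family fixes the four parameter roles but not the update equations; the
procedure above is this package's normative formalization of those roles,
and its correctness is checked against an independently coded dense
transition-matrix oracle (explicit phase matrices, multiplied k times)
rather than against any external implementation.

Degenerate inputs are resolved as follows. A query with substructures but
no known targets (a new chemical) seeds all mass on its substructures; a
query with targets but no substructures seeds all mass on its targets; a
query with neither cannot be scored and raises a capability error. A drug
whose weighted outflow vanishes (β exactly 0 or 1 with edges of a single
type) falls back to a uniform split over its neighbours so conservation
holds for boundary parameter values. With γ = 0, β = 0.5 and an empty
substructure layer the procedure reduces exactly to classic two-phase
network-based inference on the drug–target bipartite graph (tested against
a hand-coded reference).

All linear algebra is dense numpy: the intended problem sizes (hundreds to
a few thousand nodes) never justify a sparse path.

Ranking is by final target-layer resource, descending, with lexicographic
tie-break on the gene symbol — fully deterministic. Known targets of the
query are excluded before truncation in evaluation settings
(`exclude_known=True`, the default) and can be kept for exploratory
listing.

## Fingerprints

The diffusion engine consumes any binary drug × substructure incidence
matrix; fingerprint bit semantics are delegated to providers. MACCS keys
are computed in-process with RDKit; FP4, Klekota–Roth and PubChem bit
definitions live in external tools, so those families are loaded from
precomputed matrices via the FILE provider (requesting them in-process
raises a capability error saying so). A seeded SYNTH provider supports
simulation. Provider output is binarized (> 0) before use; rare
substructures can optionally be pruned by `min_support`, defaulting to no
pruning beyond the mandatory all-zero-column drop (which provably cannot
change any diffusion score — tested).

## Evaluation metrics

Cross-validation partitions interaction edges (10-fold by default; seeded;
leave-one-out and caller-supplied hold-out lists are also available). For
each drug with held-out positives, candidates are all targets minus the
drug's remaining training positives. With hits TP_d in the top-L over |D|
evaluated drugs and Σpos held-out positives:

* P(L) = ΣTP_d / (L·|D|), R(L) = ΣTP_d / Σpos (pooled).
* eP (macro, default) = mean over drugs of (TP_d/L) / (pos_d/candidates_d) —
  the per-drug precision ratio to random ranking; a pooled micro variant
  is selectable.
* eR (micro) = R(L) · N_T / L with N_T the number of targets.
* AUC = mean over drugs of the rank-sum AUC of held-out positives against
  non-interacting candidates (mid-ranks for ties).

Macro-eP and micro-eR deliberately average differently, so they generally
disagree on the same run; both concentrate near 1 under random scores
(verified by simulation) and a perfect ranking gives AUC 1. A drug that
loses all its training edges in a fold is scored as a new chemical, with a
warning. `compare_families` runs the same harness once per fingerprint
family and orders families by AUC (recall enhancement, then name, as
tie-breaks).

## Enrichment statistics

For target set T and gene set S in a universe of N genes the 2×2 table is
a = |T∩S|, b = |T|−a, c = |S|−a, d = N−a−b−c, tested one-sided
("greater") via the hypergeometric survival function, which is computed in
log-space internally; agreement with exact-rational enumeration of the
tail is tested to 1e−12 for all tables with N ≤ 60.

The universe is configurable: a fixed gene count (default 20 000,
protein-coding genome scale), the union of the tested sets plus the query,
or an explicit list (query genes outside an explicit universe are an
error). Correction over m tests (default: the number of sets tested) is
either the single-step multiplicative rule q = min(1, p·m) — the default,
because published indication screens of this kind print exactly p×m — or
Benjamini–Hochberg step-up with m as the denominator basis; the
multiplicative q dominates the BH q on every input (property-tested).
−log10(q) is always computed from the unrounded q and only rounded for
display. The same machinery drives generic gene-set over-representation
analysis for pathway GMT files.

## Synthetic worlds

`gen_world` emulates exactly the structure the diffusion model exploits:
drugs come in clusters of 5 sharing a dedicated block of 8 substructures
(each block bit present with probability 0.9, background bits at density
0.08 over 120 substructures), and each cluster owns a pool of 6 targets
that each member drug carries with probability `signal_strength` (default
0.8), plus background interactions at density 0.03 over 80 targets. SMG
sets (24 cancer types, 20–60 genes) are drawn from a 2 000-gene namespace
that contains the target genes, keeping chance overlaps sparse. A planted
(drug, cancer, fraction) triple rebuilds that drug's target set (30 genes)
to overlap the cancer's SMG set at the stated fraction of the set's size;
every planted fact is recorded in a truth object for recovery tests. One
seeded generator drives all draws: identical configs produce byte-identical
output files.

What the generator does *not* emulate: real chemistry (no SMILES; bits are
abstract), correlated fingerprint bits within a family, promiscuity
heavy-tails in real DTI data, overlapping or hierarchical SMG sets, and
literature-curation biases. Passing recovery tests therefore demonstrates
that the algorithms find the signal they are designed for, not that real
screens will show the same effect sizes.

Recovery conditions used by the tests and the acceptance script: the
enrichment recovery plants a 0.5 overlap fraction and checks the planted
cancer ranks first in ≥ 49/50 seeded worlds; the target recovery runs at
`signal_strength = 1.0` (the fully deterministic cluster signal — the
generator's notion of "strong signal"), holds out one cluster-pool target
of a query drug that at least one cluster mate still carries (so the
signal exists in the training data), and checks a top-5 hit in ≥ 90% of 50
seeds. At `signal_strength = 0` the same hit rate is statistically
indistinguishable from random, and within-cluster target sharing sits at
the background density (checked within 3 standard errors over 100 worlds).

## Numerical and determinism choices

* Conservation tolerance 1e−12 (asserted after every diffusion phase);
  oracle-equivalence tolerance 1e−10; Fisher-vs-enumeration 1e−12.
* All ranking tie-breaks are lexicographic and documented; degree-summary
  hub tables order by degree descending, name ascending.
* Every random draw flows from an explicit integer seed; pipeline outputs
  embed the tool version and parameters in a comment header, and the
  pipeline runner writes a SHA-256 manifest so reruns can be compared
  bit-for-bit.
* Problem sizes in the bundled tests and acceptance script (worlds of 60
  drugs × 120 substructures × 80 targets; 100 oracle networks ≤ 30 nodes;
  200 evaluation replicates; 50-seed recovery loops; exhaustive Fisher
  tables to N = 60) were chosen so the full suite exercises every claim at
  comfortable desk scale.

## Known limitations

* The diffusion equations are this package's formalization of the
  published parameter roles; other implementations of the same model
  family may place the hub penalty differently and produce different
  scores for γ ≠ 0.
* Published benchmark figures for this model family (top-20 precision
  ≈ 0.05, recall ≈ 0.75, enhancements ≈ 27, AUC ≈ 0.96) depend on a
  specific large training network and fingerprint set and are not
  reproducible from synthetic data; the evaluation harness is validated by
  its properties (random ≈ 1 enhancement, perfect = 1 AUC, signal-bearing
  families outrank noise) instead.
* Enrichment results depend on the unobservable true gene universe; the
  default N = 20 000 is a convention and should be varied in sensitivity
  analyses.
* The FILE provider trusts precomputed fingerprint matrices; no chemistry
  validation is performed on them.
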