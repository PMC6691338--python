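# netpharm

Network-based drug–target prediction and statistical prioritization of
cancer indications for poly-pharmacological compounds.

Natural products such as berberine act on many protein targets at once.
Two questions follow for anyone studying such a compound: *which targets
does it hit beyond the experimentally known ones?* and *which diseases —
here, which cancer types — is that target profile most relevant to?*
`netpharm` answers both with a small, fully tested pipeline:

1. **Known-interaction curation** — merge drug–target interaction (DTI)
   tables from heterogeneous sources, apply evidence-score and species
   filters, deduplicate (`netpharm.catalog_io`).
2. **Target prediction by balanced substructure–drug–target network-based
   inference (bSDTNBI)** — score candidate targets of a (possibly new)
   chemical by resource diffusion on a tripartite network of drugs, binary
   substructure fingerprints, and targets (`netpharm.netinfer`,
   `netpharm.substructures`).
3. **Predictor evaluation** — cross-validated top-*L* precision/recall,
   precision/recall *enhancement* over random ranking, and rank-sum AUC
   (`netpharm.modeleval`).
4. **Indication prioritization** — one-sided Fisher exact enrichment of the
   compound's targets in per-cancer significantly-mutated-gene (SMG) sets,
   with multiplicity correction (`netpharm.enrich`).
5. **Summary networks** — drug–target, target–function and
   drug–target–disease graphs with SIF/GraphML export (`netpharm.netbuild`).
6. **Synthetic data** — a seeded generator with plantable signal, so every
   claim above is testable without external databases (`netpharm.synthgen`).

## The model

**Diffusion.** The tripartite network has drug, substructure and target
layers, with drug–substructure edges from a binary fingerprint matrix and
drug–target edges from the curated catalog. A unit of resource is seeded on
the query drug's neighbours — share *α* on its substructures, 1 − *α* on its
known targets (all of it on the substructures for a new chemical) — and
diffused for *k* rounds. Each round, substructure/target nodes split their
resource equally over their drug neighbours; each drug then redistributes
its resource along its edges with weight

&nbsp;&nbsp;&nbsp;&nbsp;w(d→v) ∝ β·deg(v)^γ for substructures, (1 − β)·deg(v)^γ for targets,

renormalized per drug, so total resource stays exactly 1. γ < 0 penalizes
hub nodes. Defaults α = β = 0.1, γ = −0.5, k = 2. Targets are ranked by
final resource; ties break alphabetically.

**Enrichment.** For target set *T* and a cancer's SMG set *S* in a universe
of *N* genes, the 2×2 table (a, b; c, d) = (|T∩S|, |T|−a, |S|−a, N−a−b−c)
is tested one-sided (hypergeometric tail P(X ≥ a)). P-values are corrected
over the *m* cancer types tested, by default the single-step multiplicative
rule q = min(1, p·m) (Benjamini–Hochberg step-up is available); indications
with q < 0.05 are called significant.

## Worked example

`python examples/rank_indications.py` corrects the bundled 18-cancer
berberine screen (raw one-sided Fisher P-values) over the 24 tested cancer
types and prints:

```
cancer        raw P      adj P -log10(q)  validated
HCC        5.63e-20   1.35e-18     17.87  yes
LUAD       4.52e-10   1.08e-08      7.96  yes
BLCA       4.92e-10   1.18e-08      7.93  yes
...
significant at q < 0.05 : 18
literature-validated    : 10
success rate            : 55.6%
```

All 18 indications stay significant after correction; 10 of them have
published experimental support, a 55.6% validation rate.

`python examples/predict_targets.py` hides one known interaction of a
clustered synthetic drug and recovers it by diffusion:

```
query drug        : D000
hidden interaction: D000 -> G0815
top 10 predicted targets (resource score after k=2 diffusion rounds):
   1. G0815  0.03083  <- hidden target recovered
   2. G1252  0.02212
   ...
```

The score is the fraction of the unit seed resource settling on each
candidate; the hidden target ranks first because the query's structural
cluster mates carry it.

Other examples: `evaluate_predictor.py` (cross-validated metrics vs the
random baseline), `export_networks.py` (drug–target–disease graph and
degree summary), `simulate_world.py` (reproducible synthetic inputs).
A thin CLI wraps the same functions: `netpharm simulate|fingerprints|
predict|eval|enrich|network|run` (see `netpharm --help`).

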