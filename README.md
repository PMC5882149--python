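# macpath

Detection of competing-endogenous-RNA (ceRNA) pathway crosstalk gained or
lost between two conditions, e.g. tumor versus matched normal tissue.

## The problem

Transcripts sharing miRNA binding sites compete for a common miRNA pool and
thereby co-regulate one another (the ceRNA mechanism). When this coupling
is rewired in disease, it rarely rewires one gene at a time: whole
pathways gain or lose co-regulation with other pathways. `macpath` screens
every pair of pathways in a collection for such **cePathway** gains and
losses, both *direct* (through shared binding sites between the two
pathways' genes) and *indirect* (through intermediate "mediating" ceRNAs),
and then extracts a minimum set of mediating genes for each indirect call
by exact set cover.

## The method

1. **ceRNA relationship change network.** Keep genes expressed in > 80%
   of samples and miRNA families with moderate mean abundance
   (0.01–100, the regime where competition is effective). For every gene
   pair with ≥ 6 binding-site families each, test the family overlap with
   a hypergeometric tail probability; Benjamini–Hochberg-significant
   pairs (q < 0.05) become edges. Each edge carries
   Δρ = ρ_tumor − ρ_normal, the change in Pearson co-expression:
   Δρ < 0 is a ceRNA relationship loss, Δρ > 0 a gain.
2. **Direct screen.** For pathway P, each neighbor gene y scores
   θ_P(y) = Σ_{x∈P, (x,y)∈E} Δρ(x,y). Losses (θ < 0) and gains (θ > 0)
   are ranked separately; walking a ranked list against a query pathway Q
   with a weighted Kolmogorov–Smirnov running sum (hit: |θ|/N_R, miss:
   1/(N−N_H)) gives the enrichment score CES_P(Q) ∈ [0, 1]. Significance
   is the fraction of 2,000 label permutations with CES ≥ observed;
   calls require B-H q < 0.01 and CES > 0.6.
3. **Indirect screen.** κ_P(z) = Σ_{x∈P} Δρ(x,z) over genes z two hops
   from P through a mediator y, counted only when Δρ(x,y), Δρ(y,z) and
   Δρ(x,z) agree in sign and (x,z) is itself *not* an edge. The same
   running-sum/permutation machinery applies; significance control uses
   the ForwardStop ordered-testing rule at α = 0.01.
4. **Mediators.** For an indirect call (P, Q), each mediator covers the
   pathway genes on its qualifying chains; the fewest mediators covering
   all involved pathway genes is a minimum set cover, solved exactly by
   integer linear programming (or a built-in branch-and-bound). Distinct
   co-optimal covers are collected across randomized input orderings, and
   the union is tested for enrichment in reference gene lists (e.g. tumor
   suppressors) against size-matched random draws.

A synthetic-data module generates complete studies (expression, miRNA
abundances, binding-site tables, pathway collections) with planted direct
pairs and mediator chains, so the whole pipeline is testable end to end
without any external download.

## Worked example

Simulate a study with one planted direct loss (pathways `PATH00`/`PATH01`)
and one mediated loss chain (`PATH02`→ 6 mediators →`PATH03`), then screen:

```sh
macpath simulate --seed 7 --out-dir fixtures   # (planted spec via --spec JSON)
macpath network --expr fixtures/expression.tsv \
    --mirna-expr fixtures/mirna_expression.tsv \
    --conditions fixtures/conditions.tsv \
    --targets fixtures/targets.tsv --out edges.tsv
macpath direct --network edges.tsv --gmt fixtures/pathways.gmt \
    --direction loss --n-perm 2000 --seed 11 --out direct.tsv
macpath indirect --network edges.tsv --expr fixtures/expression.tsv \
    --conditions fixtures/conditions.tsv --gmt fixtures/pathways.gmt \
    --direction loss --n-perm 2000 --seed 11 --out indirect.tsv \
    --mediators-out mediators.json
```

The network command reports its filter funnel:

```
{"n_genes_in": 200, "n_genes_expressed": 195, "n_genes_with_min_sites": 195,
 "n_mirna_families_active": 300, "n_pairs_tested": 18915, "n_edges": 2083,
 "n_edges_dropped_zero_variance": 0}
```

and the screens recover exactly the planted structures:

```
pathway_P  pathway_Q  direction  CES       p_perm    q_value   n_contributing_genes
PATH00     PATH01     loss       1.000000  0.000000  0.000000  8
PATH01     PATH00     loss       1.000000  0.000000  0.000000  8
```

`direct.tsv` above: CES = 1 means every `PATH01` gene outranks every other
neighbor of `PATH00` in co-expression loss, and no label permutation
reached that score (p = 0). `indirect.tsv` likewise puts
`PATH02`/`PATH03` on top, via the mediators recorded in
`mediators.json`. The full pipeline (`macpath run --config config.json`)
chains all stages, writes a config + manifest for provenance, and is
bit-reproducible for a fixed master seed.

Library use mirrors the CLI: `generate_dataset`, `build_network`,
`screen_all_pairs`, `screen_indirect_pairs`,
`build_cover_instance`/`aggregate_minimal_mediators` operate on in-memory
domain objects.

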