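# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates. Notation: two sample groups, called
*normal* (reference) and *tumor* (contrast); ρ is Pearson correlation
within one group; Δρ = ρ_tumor − ρ_normal.

## The change network

The network's nodes are genes surviving two filters, its edges gene pairs
whose miRNA-binding overlap is unexpectedly large.

**Expression filter.** A gene is kept when its abundance is ≥
`min_abundance` (default 1.0, FPKM-like units) in strictly more than
`min_fraction` (default 0.8) of *all* samples, both groups pooled. The
strict inequality matters at the boundary: 8 of 10 samples fails, 9 of 10
passes.

**Active-family filter.** miRNA families (the TargetScan-style unit of
seed sharing — all overlap counting is at family level, never mature-miRNA
level) are kept when their mean abundance across all samples lies strictly
inside (`mirna_lo`, `mirna_hi`) = (0.01, 100). Very low abundance exerts
no repression to compete over; very high abundance saturates targets, so
competition shifts no occupancy. The window is applied to the *mean*
because per-sample application would make the family universe
sample-dependent and break the common urn needed below. Strict bounds are
a convention; the measure-zero boundary cannot matter in practice.

**Overlap test.** After restricting every gene's family set to the active
universe, genes with fewer than `min_sites` = 6 families are removed.
For each remaining unordered pair (x, y), with universe size M, the
p-value is the hypergeometric upper tail P(K ≥ |F(x) ∩ F(y)|) for drawing
|F(y)| balls from an urn of M containing |F(x)| marked ones. All pairs
share the same urn (the active universe), which is what makes
Benjamini–Hochberg across pairs coherent; edges require q < 0.05.
Filtering genes *before* testing (rather than after correction) keeps the
tested family of hypotheses fixed.

**Edge annotation.** ρ is computed per group (≥ 3 samples required;
Spearman available via `method="spearman"`). A gene with zero variance in
either group has undefined correlation; its edges are dropped and counted,
never coerced to ρ = 0 — an undefined correlation must not masquerade as
absence of co-expression. Sample pairing metadata is carried for
provenance only; no paired statistic is computed, matching the use of
matched cohorts with unpaired correlation estimates.

## Direct screening

θ_P(y) sums Δρ over edges between y and P's members. The ranked loss list
(θ < 0 ascending) and gain list (θ > 0 descending) are handled separately;
a weighted running sum over a ranked list, walked against membership in a
query pathway Q, gives CES_P(Q): a hit at weight |θ| adds |θ|/N_R (N_R =
total hit weight), a miss subtracts 1/(N − N_H). This is the weighted
Kolmogorov–Smirnov form used in gene-set enrichment analysis; the
weighting prevents high scores for query sets clustered mid-list.

Two deliberate choices:

* **CES is the maximum deviation toward the top of the list**, clipped at
  zero, not the maximum absolute deviation. Losses and gains are already
  sign-separated, so a query set clustered at the *bottom* of a loss
  ranking carries no loss signal; under the absolute convention such
  configurations score near 1 and the permutation null becomes
  effectively two-sided, which measurably destroys power. The chosen
  convention also makes the invariant exact: CES = 1 iff every hit
  precedes every miss. CES is invariant to positive rescaling of θ.
* **A pathway's own genes are excluded from its ranking** (restorable
  with `include_members=True`). Self-neighbors measure within-pathway
  co-regulation, not crosstalk toward Q, and because within-pathway
  correlation is forced to approximately match cross-pathway correlation
  (positive semi-definiteness of the correlation matrix), they enter the
  walk as guaranteed misses whose weights are within one edge's worth of
  the true hits — pure dilution.

**Permutation test.** Q-membership labels are permuted over ranking
positions (θ sequence fixed); p = #{CES_perm ≥ CES_obs}/n_perm with
n_perm = 2,000 by default and no +1 smoothing, so p = 0 is attainable and
reported as such. Permutations are vectorized (a 2,000 × N step matrix per
test) and seeded per (P, Q, direction) by CRC-mixing the pathway names
into the master seed, so results do not depend on evaluation order.

**Calling.** Every unordered pathway pair is evaluated in both
orientations (CES_P(Q) ≠ CES_Q(P)); an orientation with fewer than
`min_Q_overlap` = 5 query genes in the ranking is skipped as "not
enriched" (the gate is a count because no test is specified for it; the
count is recorded per call). B-H runs across all p-values within one
direction — losses and gains are corrected separately, consistent with
their separate rankings. A call requires q < 0.01 and CES > 0.6. The 0.6
cutoff is an empirical quantile from the original large-cohort setting
and is configurable; it is kept as the default for fidelity, not
re-derived, since it is data-dependent.

## Indirect screening

κ_P(z) sums Δρ(x, z) over P-members x connected to z through at least one
mediator y with (x,y) ∈ E, (y,z) ∈ E and sign(Δρ(x,y)) = sign(Δρ(y,z)) =
sign(Δρ(x,z)). An exactly zero Δρ is neither gain nor loss and never
qualifies. Each x contributes Δρ(x, z) once regardless of how many
mediators carry it; all carrying mediators are recorded as provenance.
Pairs (x, z) that are themselves edges are excluded — they are direct
evidence — so direct and indirect calls for the same pathway pair rest on
disjoint gene-pair sets. z is restricted to non-members of P. Δρ(x, z)
for non-edges is computed on demand from expression through a
standardized-matrix cache; zero-variance genes are skipped with a count,
as in network construction.

Ranking, CES and permutation are identical to the direct screen. The
significance rule differs: the sorted p-values of all tested orientations
within one direction feed **ForwardStop** — k̂ is the largest k with
(1/k) Σ_{i≤k} −log(1 − p_i) ≤ α (α = 0.01; p clamped to ≤ 1 − 1e−15
before the log), and the k̂ smallest p-values are rejected. No CES cutoff
is applied to indirect calls. Input must arrive sorted; the function
refuses to sort silently because ordered testing makes the ordering part
of the inference. Note that ordering by p-value (rather than a priori) is
inherited from the screening design; under a global null the rule then
rejects whenever the minimum of the tested p-values falls below ≈ α, so
the number of *tested* pairs, controlled by the enrichment gate, is what
keeps the indirect screen conservative.

## Minimum mediating sets

For an indirect call (P, Q), qualifying chains from both orientations are
pooled; a mediator covers the chain endpoints adjacent to it, and
mediators inside P ∪ Q are inadmissible. Pathway genes covered by no
admissible mediator are pruned into an `uncoverable` report instead of
failing the instance (real instances violate the idealization that every
mediator bridges both pathways). Finding the fewest mediators covering
all involved pathway genes is the minimum set cover problem, written as
the standard ILP — binary x_m per mediator, minimize Σ x_m subject to
Σ_{m∋p} x_m ≥ 1 per pathway gene p — and solved exactly by HiGHS
(`scipy.optimize.milp`). A pure-Python branch-and-bound (branch on the
element with fewest covers; greedy upper bound; ⌈uncovered/max-set⌉ lower
bound) provides a solver-independent exact route and is the default for
multi-solution aggregation because its tie-breaking follows the input
order deterministically.

Optimal covers are usually not unique. Aggregation re-solves under random
permutations of the mediator order, collects distinct solutions (all
verified to cover, all verified to share the optimal cardinality — a
larger cover raises an internal error), and reports their union plus the
mediators never used. The greedy solution seeds only the *bound*, never
the answer, so reordering can reach any optimal vertex; an exhaustive
enumerator of all minimum covers (small instances) bounds what the union
can be in tests. Enrichment of a mediator set against a reference list
uses size-matched uniform draws without replacement from a background
(default: all network genes outside P ∪ Q); 100 trials by default, with
the empirical p the fraction of trials at or above the observed fraction.

## The synthetic generator

The generator targets the statistical structure the pipeline consumes —
correlations and family overlaps — rather than simulating titration
kinetics. Baseline expression is log-normal: exp(μ_g + σ·z) with per-gene
μ_g ~ N(3, 0.7) and σ = `noise_sd` = 0.5. Planted co-expression is a
shared standard-normal latent factor on the log scale: members of a
planted structure get √effect·f + √(1−effect)·ε in the structured group
(normal for a loss, tumor for a gain) and independent noise in the other,
so the log-scale correlation equals `effect` and Δρ ≈ ±effect, mildly
attenuated by the exponential marginal (measured: mean planted Δρ of
−0.195/−0.521/−0.83 at effects 0.2/0.5/0.8, monotone as required).

Defaults are the package's study conditions: 200 genes (5 of them silent,
to exercise the expression filter), 20 pathways of 8, 50 samples per
group, 300 active miRNA families plus 20 decoys generated outside the
moderate-abundance window (to exercise the activity filter), 10 random
families per gene, disjoint reserved 10-family core sets per planted
structure.

* **Direct pair:** P's and Q's genes (plus null partners, below) share a
  core set → all cross and within edges exist; one latent factor drives
  both pathways in the structured group.
* **Chain:** P's genes share core A with dedicated mediator genes;
  mediators share core B with Q's genes; A ∩ B = ∅, so (x, z) endpoint
  pairs share no families and no direct edge — the coupling is two-hop
  only. One latent factor drives all three tiers, making every chain
  sign-consistent.
* **Null partners** (30 per planted structure): genes given the planted
  core families but *no* expression structure. They enter the rankings as
  misses with small |θ| (or |κ|), which is what makes the label
  permutation test non-degenerate — without them the ranking would
  contain only query genes, every permutation would be identical, and
  p = 1 by construction. Partners come from the free gene pool first,
  then from non-planted pathways (other pathways' genes sharing binding
  sites is the realistic case).
* **Co-targeting blocks** (off by default): groups of genes sharing a
  core family set with no expression structure, available to stress the
  screens against a dense null network. By default non-planted genes
  carry purely random family sets, so a null dataset yields an (almost
  always) empty network under B-H — the intended null condition for
  calibration.

What passing tests on this generator do **not** show: robustness to
count-type noise (negative binomial overdispersion), to normalization
artifacts, to correlated confounders (batch, purity), or to the highly
non-uniform pathway sizes and target-set degrees of real annotation
databases. The generator's planted effects are block-homogeneous; real
cePathway signal is heterogeneous across gene pairs.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from a master seed by stable hashing of the stage name,
and per-test seeds by hashing (P, Q, direction), so results are invariant
to stage order and evaluation order and bit-identical across reruns (the
determinism test hashes all output files). The test suite and the
acceptance script use the default study conditions above with 500–2,000
permutations, 10–50 replicate collections for calibration and recovery
rates, 100–1,000 random instances for the oracle-equivalence checks, and
exhaustive enumeration limited to instances with ≤ 25 mediators — sizes
chosen so the whole suite runs in well under a minute per component on a
single CPU while keeping every Monte-Carlo margin wide.

## Known limitations

* The screens share one expression matrix between network construction
  and correlation re-estimation for indirect pairs; no cross-validation
  or stability selection is attempted.
* The hypergeometric overlap model treats family sets as exchangeable;
  real binding-site counts are length- and conservation-biased, so the
  urn is optimistic for long 3′UTRs.
* ForwardStop applied to p-sorted hypotheses does not carry the formal
  ordered-testing FDR guarantee; its stringency here rests on α = 0.01
  and the enrichment gate limiting the tested family.
* The 0.6 CES cutoff is inherited, not re-estimated; users applying the
  method to differently sized cohorts should re-derive the empirical
  quantile it stands for.
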