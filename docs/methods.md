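# Methods

This note documents the models and procedures implemented in `isletnet`,
the parameters that matter, the synthetic study design, and the numerical
choices made where the method description left room.

## Tissue-specific network construction

The reference network is an undirected weighted graph; weights are
interaction confidences in (0, 1]. Presence/absence evidence arrives as a
long table (dataset, gene, status) with the closed vocabulary
`present / absent / uncertain / uncovered`. Consolidation follows a
benefit-of-the-doubt rule: a gene is called not-expressed only when at
least one dataset covers it with a confident call (`present` or `absent`)
and *every* confident call is `absent`. Uncovered or uncertain-only genes
count as expressed. The stricter reading — not-expressed when *any*
confident call is absent — is available via
`consolidate_presence(..., require_all_absent=False)`; the default reading
is the one consistent with the benefit-of-the-doubt ethos.

Two tissue networks are derived. Node-removal keeps the subgraph induced on
expressed genes. Edge-reweighting multiplies each edge weight by `rw^n`,
where `n ∈ {0,1,2}` is the number of not-expressed endpoints and
`rw = 0.1` (default) is the probability that a gene is expressed despite
failing the cutoffs. Underflowed weights are retained, never dropped, so
`n` remains recoverable from the ratio; consumers may threshold.

## Overlapping complex discovery

**Cohesiveness search.** Candidates maximize
`f(C) = w_in / (w_in + w_bound + p·|C|)` with penalty `p = 2`. Seeds are
taken in decreasing weighted-degree order, skipping covered nodes; each
seed hill-climbs with single-node additions and removals (strict
improvement, ties prefer additions, then smaller gene identifier). Two
refinements address local optima that single moves provably cannot escape:

* *connected-pair additions* — when no single move improves, pairs (v, w)
  with an edge between them are evaluated in one step, since a weak node
  can unlock a strong neighbour;
* *candidate fusion* — two locally optimal clusters joined by weak edges
  can form a better cluster than either (the joining weight moves from
  both boundaries into the union's interior while the size penalty is
  linear). Candidate pairs whose raw-union cohesiveness comes within 10%
  of the better half are re-climbed from the union, best first; a fused
  cluster replaces its halves only when it strictly beats both.

With these refinements the detector agrees with exhaustive cohesiveness
maximization on every tested random network of ≤ 10 nodes (239 instances).
Candidates with density (mean internal edge weight over all member pairs,
absent edges zero) below 0.2 are discarded.

**Spoke-hub construction.** On the node-removal network, each gene defines
a candidate: itself plus its first-order partners. A single-pass topology
filter then removes every non-hub member with strictly less than 5% of its
network-wide partners inside the *original* candidate (fractions are not
recomputed after removals; the hub is never removed). Partner counts are
taken in the tissue network being decomposed, not the unpruned reference.

**Merging.** Candidates merge when their matching score
`|A∩B|² / (|A||B|)` exceeds 0.3. Merging is sequential: the pair with the
largest sets (descending size of the larger, then the smaller, then
lexicographic members) is unioned first, repeating to a fixed point, which
guarantees no remaining pair exceeds 0.3. The large-first order matters:
noisy look-alike candidates coalesce into broad unions before they are
compared against small tight complexes, whose overlap with the grown union
then falls below the threshold. Each detection stage is merged internally,
the union of both stages is merged again, and the 6–50 size filter is
applied last.

**Metrics.** Diameter (maximum over connected components), average degree,
average clustering coefficient and mean betweenness centrality are
computed unweighted on the induced subgraph of the reweighted network;
density uses the reweighted weights. The whole stage is deterministic.

## Coordinated expression

For complex *c* and tissue *t*, `PCC.mean` is the mean pairwise Pearson
correlation over interacting member pairs only (each edge once). Pairs with
a zero-variance expression vector are undefined and are excluded with the
edge count decremented — absence of evidence, not evidence of no
coordination (setting them to zero instead is available in the low-level
API). The mean is Fisher-transformed, `z = ½ ln((1+r)/(1−r))`, with |r|
clamped at 1 − 10⁻⁶, then standardized within each tissue across all
complexes (sample mean and SD, ddof = 1): per-tissue location and scale
mostly reflect sample size, not biology. A complex is called
islet-coordinated when at least one islet component (whole islet, beta,
non-beta) is among its top-3 tissues by CE. Ranks use competition ("min")
ranking, so exact ties share the best rank — an all-tied complex ranks
every tissue first and is called.

Benchmark complexes are those with ≥ 10% of members in a curated islet
gene set; their maximum CE over the three islet components is compared to
all other complexes with a one-sided Mann–Whitney U test (exact for small
untied samples, asymptotic with tie correction otherwise). Aggregating the
three components by maximum is the default; testing each separately is
available.

## Functional convergence

Per complex, each phenotype gene set (intersected with the network genes;
genes without interaction partners drop out, and a set left empty
contributes p = 1) is tested with the hypergeometric upper tail
P(X ≥ k), inclusive of the observed count, against the network-gene
background. The per-set p-values combine via Fisher's method:
statistic `−2 Σ ln p`, reference chi-square with 2k degrees of freedom.

The empirical null draws `n_samples` (default 100,000) uniform
without-replacement gene sets of the same size from the network and scores
them identically; `P_emp` is the fraction with combined p at most the
observed one. The sampler uses an exact reformulation: genes are
partitioned into *atoms* of identical set membership, and a uniform draw
induces multivariate hypergeometric counts over atoms, from which the
per-set overlap counts — the sufficient statistic — follow directly. This
is distribution-identical to drawing gene sets one at a time (verified
against direct sampling in the tests) and makes the 100,000-draw default
cheap. Nulls are cached per complex size; the per-size RNG stream is
derived from the pipeline seed plus the size, so results do not depend on
evaluation order.

`P_emp = 0` is reported as-is; a `(count+1)/(n+1)` pseudo-count estimator
is available behind a flag because BH on exact zeros can be degenerate.
BH adjustment runs across complexes. Note BH is monotone but not
idempotent (e.g. [0.25, 1.0] → [0.5, 1.0] → [1.0, 1.0]); only monotonicity
is asserted.

Direct gene-set overlap uses the hypergeometric test against a genome-wide
background (default 22,766 genes), with percentages relative to the
smaller set and BH across pairs; consensus genes are those in ≥ 4 sets.

## GWAS signal enrichment

SNPs map to a gene when they fall within 110 kb upstream / 40 kb
downstream of its transcribed region; windows follow the strand
(plus strand: [start − 110 kb, end + 40 kb); minus strand mirrored); a SNP
may map to several genes. Coordinates are 0-based half-open (BED in/out).
The gene score is the minimum mapped SNP p-value, with no multiplicity
correction; genes with no mapped SNP are excluded from both the percentile
computation and the counts.

The enrichment test counts complex genes whose score beats a cutoff at the
95th percentile of all gene scores, read as "the best 5% of gene p-values"
(the MAGENTA convention); the alternative literal reading — the value at
the 95th percentile of the p-values themselves — is behind a flag.
Significance comes from the hypergeometric tail or (default) a permutation
null of random same-size sets drawn from the scored genes; because a
uniform same-size draw makes the null hit count exactly hypergeometric,
the count is sampled directly. The confounder-correcting regression of the
original MAGENTA tool (gene size, SNP density, LD) is deliberately not
reproduced: the synthetic coordinates have uniform gene size and SNP
density, and the random-set null absorbs set size, the dominant remaining
confounder. Because the test statistic is a small count, the test is
discrete and conservative for 6–50-gene sets: its exact null rejection
rate at nominal 0.05 ranges 0.006–0.049 by set size (mean ≈ 0.026 under
the demo conditions). This conservatism is a property of count-based
enrichment at small set sizes, not of the implementation.

The test runs under three complex definitions: all members; without
genome-wide significant genes (score < 5×10⁻⁸, strict); and without the
trait-matched input genes (exclusion applies only to the matched trait's
gene sets). Prioritization selects genes of significant complexes that
appear in no phenotype set, carry support from ≥ 1 islet-biology set, and
have a minimum mapped SNP p below 10⁻⁴ in some trait, sorted by that p.

## Synthetic study design

The generator's defaults are the demo fixture: 2,000 genes, 40 planted
complexes of 8–30 members (disjoint), 13 phenotype sets, 34 tissues
(including whole_islet, beta, non_beta) × 30 samples, seed 42.

* **Network.** Within-module pairs get an edge with probability 0.6 and
  weight Uniform(0.5, 1); the background has two tiers — a sparse
  gene-gene layer (edge probability 2.5×10⁻⁴) and 80 promiscuous hub genes
  each attached to every gene with probability 0.05, weights
  Uniform(0.05, 0.9). The hub tier matters: the spoke-hub 5% filter can
  only prune unspecific partners whose total partner count exceeds ~20, so
  a background with realistic heavy-tailed degrees (as in the
  high-confidence human interactome, mean degree ≈ 46) is required for the
  published filter constant to behave as intended; a flat random
  background at desk scale either defeats the filter or drowns the
  cohesiveness search.
* **Expression.** Gene baselines Uniform(3, 8) with unit Gaussian noise,
  clipped at zero (negligible at ≥ 3σ). Members of complex *c* in its one
  designated coordinated tissue share a latent factor with loading √r, so
  their pairwise correlation is exactly r (default 0.6) there and ≈ 0
  elsewhere. Tissues are assigned round-robin, so a few planted complexes
  are islet-coordinated by construction.
* **Presence evidence.** Three datasets; 10% of genes absent in every
  covering dataset (pruned downstream), 5% uncovered, 5% uncertain-only
  (both retained), the rest mostly present with light per-dataset noise
  that the consolidation rule overrides.
* **Gene sets.** 13 phenotype sets of 30–60 genes (1.5–3% of the
  background, matching the published sets' share of their network); each
  of the 10 *enriched* complexes contributes ⌈0.3·size⌉ members to 4
  supporting sets; remainders fill uniformly from non-planted genes. Four
  islet-biology sets (25–50 genes) and 40 pathway sets (20–60) plant
  similarly with their own fractions.
* **GWAS.** Genes occupy one synthetic chromosome at 200 kb spacing with
  20 kb bodies, so 110/40 kb windows never collide; SNPs (10 per gene) sit
  inside their gene's window under either strand. Causal genes (members of
  enriched complexes) draw SNP p ~ Beta(0.1, 1); null genes uniform, so
  gene-level minimum p has the closed-form null 1 − (1−p)ⁿ.

All generators are pure functions of (config, seed); every stream is
derived from the single seed. What the fixture does *not* emulate:
linkage disequilibrium, gene-size and SNP-density confounding, realistic
expression distributions (RPKM skew, batch effects), identifier mapping
noise, or overlap between planted modules. Passing tests therefore show
that the machinery recovers planted effects under clean conditions — not
that it is robust to those real-data complications.

## Problem sizes and numerical choices

The shipped analyses use the demo scale: empirical nulls at 20,000 draws
per complex size in the pipeline runs and 10,000 in the calibration suite
(500 random complexes); the CE recovery suite uses 200 planted complexes
at 7,000 genes; GWAS calibration uses 400 random sets × 10,000
permutations. The paper-default 100,000 draws remain the `n_samples`
default in `PipelineConfig`.

Ties everywhere break lexicographically on gene identifiers (detection,
merging) or tissue labels (CE ranking), making every stage except the
explicitly seeded null sampling deterministic. Cohesiveness improvements
require an absolute margin of 10⁻¹²; Fisher-z clamps at |r| = 1 − 10⁻⁶;
hypergeometric tails are inclusive of the observed count (exclusive tails
would inflate significance); empirical p-values use the paper-faithful
count/n estimator by default.

## Known limitations

* The cohesiveness search is greedy with local escapes; global optimality
  is verified only for ≤ 10-node instances.
* The empirical convergence null matches random sets on size only, not on
  degree or co-expression structure.
* The GWAS enrichment test is conservative for small complexes (see
  above) and omits MAGENTA's confounder regression.
* Edge-list files cannot represent isolated genes; reading a written
  network drops them (they carry no interactions and do not affect any
  downstream stage).
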