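# isletnet

Tissue-specific protein-complex discovery and disease gene-set convergence
analysis on weighted protein-interaction networks.

## The problem

Complex diseases such as type 2 diabetes are driven by many genes whose
individual signals — GWAS loci, differential expression, methylation, eQTL —
rarely point at the same genes directly. The hypothesis behind this package
is that heterogeneous evidence converges on shared *functional units*:
protein complexes active in the disease-relevant tissue (for diabetes, the
pancreatic islet). The package builds an islet-specific interaction network,
decomposes it into overlapping complexes, scores tissue-coordinated
expression, tests each complex for convergence of disease gene sets, and
verifies candidate complexes against GWAS signal — prioritizing novel genes
that interact with established disease genes.

It is aimed at computational biologists who want the full analysis as a
reusable, tested pipeline. Because the original consortium inputs are
access-controlled, a first-class synthetic-data module generates every input
with planted, recoverable structure, so each stage can be validated against
ground truth.

## The methods at a glance

* **Tissue networks.** From a reference weighted network (weights
  `w_ij ∈ (0,1]`) and multi-dataset presence/absence evidence:
  *node-removal* deletes genes absent in every covering dataset
  (benefit-of-the-doubt for uncovered/uncertain genes); *edge-reweight*
  multiplies each weight by `rw^n`, where `n ∈ {0,1,2}` counts not-expressed
  endpoints and `rw = 0.1` is the residual expression probability.
* **Complex discovery.** Greedy maximization of the cohesiveness
  `f(C) = w_in(C) / (w_in(C) + w_bound(C) + 2|C|)` on the reweighted network
  (minimum density 0.2), plus spoke-hub candidates (a gene and its
  first-order partners, members with < 5% of their partners inside removed)
  on the node-removal network; candidates merge when the matching score
  `|A∩B|²/(|A||B|)` exceeds 0.3; sizes are restricted to 6–50.
* **Coordinated expression (CE).** Per complex and tissue, the mean pairwise
  Pearson correlation over *interacting* pairs, Fisher-transformed and
  standardized across complexes within each tissue; a complex is
  islet-coordinated when an islet tissue component ranks in its CE top 3 of
  34 tissues.
* **Functional convergence.** Per complex, hypergeometric enrichment of each
  of 13 phenotype gene sets against the network background, combined with
  Fisher's method (`−2Σln p`, chi-square with 2k df); an empirical p-value
  compares the combined statistic to random same-size gene sets (default
  100,000), BH-adjusted across complexes.
* **GWAS verification.** SNPs map to genes within 110 kb upstream / 40 kb
  downstream (strand-aware); gene score = minimum mapped SNP p; a
  percentile-cutoff enrichment test (MAGENTA-style, 95th percentile) with a
  random-set permutation null, run with all genes, without genome-wide
  significant genes (p < 5×10⁻⁸), and without input genes.
* **Prioritization.** Genes of significant complexes that sit in no input
  evidence set, have islet-biology support, and carry a nearby SNP with
  p < 10⁻⁴.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
demo fixture (2,000 genes, 40 planted complexes, 13 phenotype sets,
34 tissues, seed 42) and write their tables under `results/demo/`:

```sh
python analysis/01_simulate.py
python analysis/02_build_networks.py
python analysis/03_discover_complexes.py
python analysis/04_coordinated_expression.py
python analysis/05_convergence.py
python analysis/06_gwas_enrichment.py
python analysis/07_prioritize.py
```

which prints, stage by stage:

```
simulated 2000 genes, 12861 interactions, 40 planted complexes (10 with planted gene-set support), 34 tissues x 30 samples
195 of 1984 genes called not-expressed and pruned; node-removal network: 1789 genes / 10707 edges; edge-reweighted network keeps all 1984 genes
72 overlapping complexes over 813 genes (sizes 6-42, median 12); 92% of planted modules recovered at matching score >= 0.5
13 of 72 complexes islet-coordinated (top-3 rule); 8 benchmark complexes (>=10% curated genes) show higher islet CE than the rest (one-sided MWU p = 0.0419)
16 of 72 complexes show significant functional convergence (BH-adjusted empirical p < 0.05, 20000 random sets per size); 1 consensus genes sit in >= 4 of the 13 gene sets
22 of 47 complex-mode combinations enriched for GWAS signal (p < 0.05, 10,000 permutations); 5 pathways over-represented among the 16 significant complexes (BH < 0.05)
18 candidate genes prioritized from 16 significant complexes; 18 carry planted causal GWAS signal
```

Reading the numbers: the discovery stage recovers 92% of the planted modules
(matching score ≥ 0.5); benchmark complexes rich in curated islet genes show
significantly higher islet CE than the background of other complexes; all 16
significant complexes trace back to the 10 modules with planted gene-set
support (several are overlapping views of the same module); and all 18
prioritized genes carry planted causal GWAS signal — on this fixture the
prioritization rule has perfect precision.

The same pipeline is available as a CLI (`isletnet simulate`,
`build-network`, `discover`, `coordinate`, `converge`, `annotate`,
`gwas-enrich`, `prioritize`, `run-all`, `validate`); `isletnet run-all`
executes stages A–H from one YAML config and writes a reproducibility
manifest.

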