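"""Synthetic study data with planted, recoverable structure.

Generates every input the analysis consumes, at desk scale, with a recorded
ground truth so each downstream stage can be validated:

* a sparse weighted interaction network with planted dense modules
  (the "complexes"), emulating a high-confidence physical interactome;
* a multi-tissue expression panel in which each planted complex is
  co-expressed in one designated tissue through a shared latent factor with
  loading sqrt(r), so the expected pairwise Pearson correlation of members
  in that tissue is exactly ``r`` and ~0 elsewhere;
* multi-dataset presence/absence evidence tables for network pruning;
* phenotype gene-set collections in which each *enriched* planted complex
  is supported by several sets containing a fixed fraction of its members;
* gene coordinates on a synthetic chromosome (non-overlapping windows by
  construction) and GWAS summary statistics in which SNPs of causal genes
  draw p ~ Beta(a, 1) with a < 1 (default 0.1) and null SNPs draw uniform
  p-values.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .convergence import GeneSetCollection
from .coordination import DEFAULT_ISLET_COMPONENTS, ExpressionPanel

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_network",
    "generate_expression",
    "generate_presence_evidence",
    "generate_gene_sets",
    "generate_gwas",
    "generate_all",
    "demo_config",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort (defaults = demo fixture)."""

    n_genes: int = 2000
    n_planted: int = 40
    size_range: tuple[int, int] = (8, 30)
    background_edge_prob: float = 0.00025
    within_complex_edge_prob: float = 0.6
    # two-tier background: besides the sparse gene-gene layer above, a small
    # set of promiscuous hub genes carries most background connectivity, as
    # in real interactomes where date-hubs dominate the degree distribution
    n_hubs: int = 80
    hub_attach_prob: float = 0.05
    # uniform weight ranges for background and planted edges
    weight_distribution_params: dict = field(
        default_factory=lambda: {"background": (0.05, 0.9), "planted": (0.5, 1.0)}
    )
    n_tissues: int = 34
    islet_components: tuple[str, str, str] = DEFAULT_ISLET_COMPONENTS
    samples_per_tissue: int = 30
    planted_pairwise_r: float = 0.6
    n_gene_sets: int = 13
    set_size_range: tuple[int, int] = (30, 60)
    planted_set_fraction: float = 0.3
    sets_per_complex: int = 4
    n_enriched: int = 10
    n_snps_per_gene: int = 10
    causal_beta_a: float = 0.1
    n_datasets: int = 3
    fraction_absent: float = 0.10
    fraction_uncertain: float = 0.05
    fraction_uncovered: float = 0.05
    seed: int = 42

    def __post_init__(self):
        for p in (
            self.background_edge_prob,
            self.within_complex_edge_prob,
            self.fraction_absent,
            self.fraction_uncertain,
            self.fraction_uncovered,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.planted_pairwise_r < 1.0:
            raise ValueError("planted_pairwise_r must be in [0, 1)")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("invalid size_range")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def tissues(self) -> list[str]:
        others = [f"tissue_{i:02d}" for i in range(1, self.n_tissues - len(self.islet_components) + 1)]
        return list(self.islet_components) + others


@dataclass
class SyntheticTruth:
    """Everything that was planted, for downstream validation."""

    planted_complexes: list[frozenset] = field(default_factory=list)
    coordinated_tissue_of_complex: dict[int, str] = field(default_factory=dict)
    enriched_complexes: set[int] = field(default_factory=set)
    causal_genes: frozenset = frozenset()
    set_planted_genes: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        for c in self.planted_complexes:
            if not 6 <= len(c) <= 50:
                raise ValueError("planted complexes must have 6-50 members")
        for i in self.enriched_complexes:
            if i >= len(self.planted_complexes):
                raise ValueError("enriched complex id does not refer to a planted complex")


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def generate_network(cfg: GeneratorConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Sparse weighted network with planted dense modules and hub genes.

    Planted member sets are disjoint; within-module pairs get an edge with
    probability ``within_complex_edge_prob`` and a planted-range weight.
    The background has two tiers: a sparse uniform gene-gene layer
    (``background_edge_prob``) and ``n_hubs`` promiscuous hub genes each
    attached to every gene with ``hub_attach_prob``, mimicking the
    heavy-tailed degree distribution of real interactomes. Weights land in
    (0, 1].
    """
    lo, hi = cfg.size_range
    if cfg.n_planted * hi > cfg.n_genes:
        raise ValueError("size_range too large: planted complexes exceed n_genes")
    rng = _rng(cfg, 1)
    genes = cfg.genes
    perm = [genes[i] for i in rng.permutation(cfg.n_genes)]
    sizes = rng.integers(lo, hi + 1, size=cfg.n_planted)
    planted, pos = [], 0
    for s in sizes:
        planted.append(frozenset(perm[pos : pos + s]))
        pos += s

    g = nx.Graph()
    g.add_nodes_from(genes)
    w_bg = cfg.weight_distribution_params["background"]
    w_in = cfg.weight_distribution_params["planted"]

    # planted edges
    for members in planted:
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                if rng.random() < cfg.within_complex_edge_prob:
                    g.add_edge(a, b, weight=float(max(rng.uniform(*w_in), 1e-9)))

    # low-degree background layer: sample the count, then distinct pairs
    n_pairs = cfg.n_genes * (cfg.n_genes - 1) // 2
    n_bg = int(rng.binomial(n_pairs, cfg.background_edge_prob))
    seen = set()
    while len(seen) < n_bg:
        need = n_bg - len(seen)
        ii = rng.integers(0, cfg.n_genes, size=2 * need + 10)
        jj = rng.integers(0, cfg.n_genes, size=2 * need + 10)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a, b = (genes[i], genes[j]) if genes[i] < genes[j] else (genes[j], genes[i])
            if (a, b) in seen or g.has_edge(a, b):
                continue
            seen.add((a, b))
            g.add_edge(a, b, weight=float(max(rng.uniform(*w_bg), 1e-9)))
            if len(seen) >= n_bg:
                break

    # hub layer: promiscuous genes attached broadly across the network
    hubs = [genes[i] for i in rng.choice(cfg.n_genes, size=cfg.n_hubs, replace=False)]
    for h in hubs:
        attach = rng.random(cfg.n_genes) < cfg.hub_attach_prob
        for i in np.nonzero(attach)[0]:
            v = genes[i]
            if v == h or g.has_edge(h, v):
                continue
            g.add_edge(h, v, weight=float(max(rng.uniform(*w_bg), 1e-9)))

    tissues = cfg.tissues
    coord = {i: tissues[i % len(tissues)] for i in range(cfg.n_planted)}
    enriched = set(range(min(cfg.n_enriched, cfg.n_planted)))
    causal = frozenset(g for i in enriched for g in planted[i])
    truth = SyntheticTruth(
        planted_complexes=planted,
        coordinated_tissue_of_complex=coord,
        enriched_complexes=enriched,
        causal_genes=causal,
    )
    return g, truth


def generate_expression(
    net: nx.Graph, truth: SyntheticTruth, cfg: GeneratorConfig
) -> ExpressionPanel:
    """Shared-latent-factor expression panel.

    Member genes of complex *c* in its coordinated tissue follow
    ``x = mu_g + sqrt(r) * F + sqrt(1 - r) * eps`` with a per-(complex,
    tissue, sample) factor F, giving expected pairwise correlation r; all
    other (gene, tissue) combinations are independent noise around mu_g.
    Values are clipped at zero (means are >= 3, so clipping is negligible).
    """
    if cfg.samples_per_tissue < 3:
        raise ValueError("need at least 3 samples per tissue")
    r = cfg.planted_pairwise_r
    rng = _rng(cfg, 2)
    genes = sorted(net.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    tissues = cfg.tissues
    n_s = cfg.samples_per_tissue
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    samples, labels = [], []
    blocks = []
    for t in tissues:
        eps = rng.standard_normal((len(genes), n_s))
        x = mu[:, None] + eps
        # overlay the latent factor for complexes coordinated in this tissue
        for ci, members in enumerate(truth.planted_complexes):
            if truth.coordinated_tissue_of_complex.get(ci) != t or r == 0:
                continue
            f = rng.standard_normal(n_s)
            rows = [gene_idx[g] for g in sorted(members) if g in gene_idx]
            x[rows, :] = (
                mu[rows, None]
                + math.sqrt(r) * f[None, :]
                + math.sqrt(1.0 - r) * eps[rows, :]
            )
        blocks.append(x)
        samples.extend(f"{t}_s{i:02d}" for i in range(n_s))
        labels.extend([t] * n_s)
    values = pd.DataFrame(
        np.clip(np.concatenate(blocks, axis=1), 0.0, None), index=genes, columns=samples
    )
    return ExpressionPanel(values=values, sample_tissue=pd.Series(labels, index=samples))


def generate_presence_evidence(net: nx.Graph, cfg: GeneratorConfig) -> pd.DataFrame:
    """Multi-dataset presence/absence evidence in long format.

    A ``fraction_absent`` share of genes is absent in every dataset covering
    it (and therefore pruned downstream); ``fraction_uncovered`` genes are
    covered by no dataset and ``fraction_uncertain`` only with uncertain
    calls — both survive via the benefit of the doubt.
    """
    rng = _rng(cfg, 3)
    genes = sorted(net.nodes)
    u = rng.random(len(genes))
    c1 = cfg.fraction_absent
    c2 = c1 + cfg.fraction_uncovered
    c3 = c2 + cfg.fraction_uncertain
    rows = []
    for g, x in zip(genes, u):
        if x < c1:
            cls = "absent_all"
        elif x < c2:
            cls = "uncovered_all"
        elif x < c3:
            cls = "uncertain_all"
        else:
            cls = "present"
        for d in range(cfg.n_datasets):
            if cls == "absent_all":
                status = "absent"
            elif cls == "uncovered_all":
                status = "uncovered"
            elif cls == "uncertain_all":
                status = "uncertain"
            else:
                # mostly present with occasional non-confident coverage and
                # isolated absent calls that the consolidation rule overrides
                y = rng.random()
                if y < 0.80:
                    status = "present"
                elif y < 0.90:
                    status = "uncertain"
                elif y < 0.95:
                    status = "uncovered"
                else:
                    status = "absent"
            rows.append({"dataset": f"dataset_{d + 1}", "gene": g, "status": status})
    return pd.DataFrame(rows, columns=["dataset", "gene", "status"])


def _fill_sets(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    n_sets: int,
    size_range: tuple[int, int],
    fraction: float,
    sets_per_complex: int,
    prefix: str,
    category: str,
) -> GeneSetCollection:
    planted_union = set().union(*truth.planted_complexes) if truth.planted_complexes else set()
    non_planted = sorted(set(cfg.genes) - planted_union)
    names = [f"{prefix}_{i + 1:02d}" for i in range(n_sets)]
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_sets)
    contents: dict[str, set] = {n: set() for n in names}
    planted_by_set: dict[str, set] = {n: set() for n in names}
    for rank, ci in enumerate(sorted(truth.enriched_complexes)):
        members = sorted(truth.planted_complexes[ci])
        take = math.ceil(fraction * len(members))
        for j in range(sets_per_complex):
            name = names[(rank * sets_per_complex + j) % n_sets]
            if take > sizes[names.index(name)]:
                raise ValueError(
                    f"planted fraction needs {take} genes but set {name} holds {sizes[names.index(name)]}"
                )
            chosen = rng.choice(members, size=take, replace=False) if fraction > 0 else []
            contents[name].update(chosen)
            planted_by_set[name].update(chosen)
    for name, target in zip(names, sizes):
        need = int(target) - len(contents[name])
        if need > 0:
            pool = [g for g in non_planted if g not in contents[name]]
            contents[name].update(rng.choice(pool, size=min(need, len(pool)), replace=False))
    truth.set_planted_genes.update({n: frozenset(planted_by_set[n]) for n in names})
    coll = GeneSetCollection(
        sets={n: frozenset(contents[n]) for n in names},
        categories={n: category for n in names},
    )
    return coll


def generate_gene_sets(truth: SyntheticTruth, cfg: GeneratorConfig) -> GeneSetCollection:
    """Phenotype evidence sets: each enriched complex is supported by
    ``sets_per_complex`` sets containing ``planted_set_fraction`` of its
    members; the remainder of every set is uniform over non-planted genes."""
    if cfg.n_gene_sets < 1:
        raise ValueError("need at least one gene set")
    return _fill_sets(
        truth,
        cfg,
        _rng(cfg, 4),
        n_sets=cfg.n_gene_sets,
        size_range=cfg.set_size_range,
        fraction=cfg.planted_set_fraction,
        sets_per_complex=cfg.sets_per_complex,
        prefix="phenotype",
        category="phenotype",
    )


def generate_biology_sets(truth: SyntheticTruth, cfg: GeneratorConfig) -> GeneSetCollection:
    """Four islet-biology support sets (smaller, lighter planting)."""
    return _fill_sets(
        truth,
        cfg,
        _rng(cfg, 5),
        n_sets=4,
        size_range=(25, 50),
        fraction=min(cfg.planted_set_fraction, 0.3),
        sets_per_complex=2,
        prefix="biology",
        category="islet_biology",
    )


def generate_pathways(truth: SyntheticTruth, cfg: GeneratorConfig, n_pathways: int = 40) -> GeneSetCollection:
    """Pathway collection: random sets plus one pathway seeded per enriched complex."""
    return _fill_sets(
        truth,
        cfg,
        _rng(cfg, 6),
        n_sets=n_pathways,
        size_range=(20, 60),
        fraction=0.5,
        sets_per_complex=1,
        prefix="pathway",
        category="pathway",
    )


def generate_gwas(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene coordinates and SNP-level summary statistics.

    Genes are laid out on one synthetic chromosome with 200 kb start
    spacing and 20 kb bodies, so the 110/40 kb windows never collide.
    SNPs are placed inside the gene's own window regardless of strand;
    causal genes draw p ~ Beta(a, 1), null genes uniform.
    """
    rng = _rng(cfg, 7)
    genes = cfg.genes
    strands = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    coords = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": [200_000 * (i + 1) for i in range(len(genes))],
            "end": [200_000 * (i + 1) + 20_000 for i in range(len(genes))],
            "strand": strands,
        },
        index=pd.Index(genes, name="gene"),
    )
    rows = []
    for i, g in enumerate(genes):
        start, end = coords.loc[g, "start"], coords.loc[g, "end"]
        pos = rng.integers(start - 30_000, end + 30_000, size=cfg.n_snps_per_gene)
        if g in truth.causal_genes:
            p = rng.beta(cfg.causal_beta_a, 1.0, size=cfg.n_snps_per_gene)
        else:
            p = rng.uniform(0.0, 1.0, size=cfg.n_snps_per_gene)
        p = np.clip(p, 1e-300, 1.0)
        for k in range(cfg.n_snps_per_gene):
            rows.append(
                {"snp": f"rs{i:04d}_{k}", "chrom": "chrS", "pos": int(pos[k]), "p": float(p[k])}
            )
    return coords, pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])


@dataclass
class SyntheticBundle:
    """Everything one simulated study provides."""

    cfg: GeneratorConfig
    net: nx.Graph
    truth: SyntheticTruth
    panel: ExpressionPanel
    presence: pd.DataFrame
    phenotype_sets: GeneSetCollection
    biology_sets: GeneSetCollection
    pathways: GeneSetCollection
    coords: pd.DataFrame
    gwas: pd.DataFrame


def generate_all(cfg: GeneratorConfig) -> SyntheticBundle:
    """Run every generator once, in a fixed order, from one config."""
    net, truth = generate_network(cfg)
    panel = generate_expression(net, truth, cfg)
    presence = generate_presence_evidence(net, cfg)
    phenotype_sets = generate_gene_sets(truth, cfg)
    biology_sets = generate_biology_sets(truth, cfg)
    pathways = generate_pathways(truth, cfg)
    coords, gwas = generate_gwas(truth, cfg)
    return SyntheticBundle(
        cfg=cfg,
        net=net,
        truth=truth,
        panel=panel,
        presence=presence,
        phenotype_sets=phenotype_sets,
        biology_sets=biology_sets,
        pathways=pathways,
        coords=coords,
        gwas=gwas,
    )


def demo_config(seed: int = 42, **overrides) -> GeneratorConfig:
    """The demo fixture: ~2,000 genes, 40 planted complexes, 13 sets, 34 tissues."""
    return replace(GeneratorConfig(seed=seed), **overrides)
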