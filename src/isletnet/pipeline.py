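"""End-to-end orchestration of the islet-complex analysis.

Stages, in order: (A) obtain inputs (synthetic generation or files),
(B) consolidate presence evidence and build the node-removal and
edge-reweighted tissue networks, (C) discover the complex catalog,
(D) coordinated-expression scoring, islet-coordination calls and the
benchmark comparison, (E) functional-convergence testing with the empirical
null, (F) pathway over-representation for the significant complexes,
(G) GWAS signal enrichment under three complex definitions, and
(H) candidate-gene prioritization.

All intermediate artifacts are plain TSV/GMT/JSON in the output directory;
a manifest (config, seed, per-stage row counts — no timestamps) makes runs
comparable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ionet
from .complexes import build_catalog
from .convergence import GeneSetCollection, NullCache, convergence_scan
from .coordination import (
    CEMatrix,
    ExpressionPanel,
    benchmark_complexes,
    fisher_z,
    islet_coordinated,
    mwu_compare,
    standardize_ce,
)
from .gwas import (
    complex_gene_variants,
    magenta_style_enrichment,
    map_snps_to_genes,
    pathway_ora,
    prioritize_candidates,
)
from .network import consolidate_presence, edge_reweight, node_removal
from .synthetic import GeneratorConfig, generate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, with the published method defaults."""

    outdir: str = "results/run"
    seed: int = 42
    generator: GeneratorConfig | None = None  # synthetic mode when set
    inputs: dict = field(default_factory=dict)  # file mode: paths by role
    rw: float = 0.1
    min_density: float = 0.2
    penalty: float = 2.0
    max_overlap: float = 0.3
    min_size: int = 6
    max_size: int = 50
    min_inside_fraction: float = 0.05
    top_k: int = 3
    islet_components: tuple = ("whole_islet", "beta", "non_beta")
    benchmark_min_fraction: float = 0.10
    n_samples: int = 100_000
    alpha: float = 0.05
    percentile: float = 95.0
    n_perm: int = 10_000
    gws_threshold: float = 5e-8
    priority_p_threshold: float = 1e-4
    genome_background: int = 22_766

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            if "islet_components" in gen:
                gen["islet_components"] = tuple(gen["islet_components"])
            if "size_range" in gen:
                gen["size_range"] = tuple(gen["size_range"])
            if "set_size_range" in gen:
                gen["set_size_range"] = tuple(gen["set_size_range"])
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    # the output directory does not affect the science; runs into different
    # directories must produce byte-identical manifests
    payload = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _fast_ce_matrix(catalog, net, panel: ExpressionPanel) -> CEMatrix:
    """Vectorized CE computation over a whole catalog (edge-restricted means)."""
    tissues = panel.tissues
    genes = list(panel.values.index)
    gidx = {g: i for i, g in enumerate(genes)}
    per_tissue = {}
    for t in tissues:
        m = panel.values[panel.samples_of(t)].to_numpy(dtype=float)
        c = m - m.mean(axis=1, keepdims=True)
        d = np.sqrt((c**2).sum(axis=1))
        per_tissue[t] = (c, d)
    rows = {}
    for cx in catalog:
        mset = [g for g in cx.members if g in gidx]
        edges = list(net.subgraph(mset).edges())
        if not edges:
            rows[cx.id] = {t: np.nan for t in tissues}
            continue
        ia = np.array([gidx[a] for a, _ in edges])
        ib = np.array([gidx[b] for _, b in edges])
        vals = {}
        for t in tissues:
            c, d = per_tissue[t]
            da, db = d[ia], d[ib]
            ok = (da > 0) & (db > 0)
            if not ok.any():
                vals[t] = np.nan
                continue
            r = (c[ia[ok]] * c[ib[ok]]).sum(axis=1) / (da[ok] * db[ok])
            vals[t] = float(r.mean())
        rows[cx.id] = vals
    pcc = pd.DataFrame.from_dict(rows, orient="index")[tissues]
    z = pcc.map(fisher_z)
    out = standardize_ce(z)
    out.pcc_mean = pcc
    return out


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_counts: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    out = Path(cfg.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    t0 = time.time()

    # --- stage A: inputs --------------------------------------------------
    if cfg.generator is not None:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        bundle = generate_all(gen)
        net, truth, panel = bundle.net, bundle.truth, bundle.panel
        presence = bundle.presence
        phenotype_sets, biology_sets, pathways = (
            bundle.phenotype_sets,
            bundle.biology_sets,
            bundle.pathways,
        )
        coords, gwas = bundle.coords, bundle.gwas
        ionet.write_edge_list(net, out / "inputs" / "network.tsv")
        ionet.write_presence(presence, out / "inputs" / "presence.tsv")
        ionet.write_expression(panel, out / "inputs" / "expression.tsv", out / "inputs" / "sample_map.tsv")
        ionet.write_gmt(phenotype_sets, out / "inputs" / "phenotype_sets.gmt")
        ionet.write_gmt(biology_sets, out / "inputs" / "biology_sets.gmt")
        ionet.write_gmt(pathways, out / "inputs" / "pathways.gmt")
        ionet.write_bed(coords, out / "inputs" / "genes.bed")
        ionet.write_gwas(gwas, out / "inputs" / "gwas.tsv")
        ionet.write_truth(truth, out / "inputs" / "truth.json")
    else:
        paths = cfg.inputs
        required = ["edge_list", "presence", "expression", "sample_map", "phenotype_gmt"]
        for key in required:
            if key not in paths:
                raise FileNotFoundError(f"stage A (inputs): missing input {key!r}")
        net = ionet.read_edge_list(paths["edge_list"])
        presence = ionet.read_presence(paths["presence"])
        panel = ionet.read_expression(paths["expression"], paths["sample_map"])
        phenotype_sets = ionet.read_gmt(paths["phenotype_gmt"])
        biology_sets = ionet.read_gmt(paths["biology_gmt"]) if "biology_gmt" in paths else GeneSetCollection(sets={})
        pathways = ionet.read_gmt(paths["pathway_gmt"]) if "pathway_gmt" in paths else GeneSetCollection(sets={})
        coords = ionet.read_bed(paths["bed"]) if "bed" in paths else None
        gwas = ionet.read_gwas(paths["gwas"]) if "gwas" in paths else None
    counts["n_genes"] = net.number_of_nodes()
    counts["n_edges"] = net.number_of_edges()

    # --- stage B: tissue networks ----------------------------------------
    call = consolidate_presence(presence, net.nodes)
    removal_net = node_removal(net, call)
    reweighted_net = edge_reweight(net, call, rw=cfg.rw)
    ionet.write_edge_list(removal_net, out / "network_removal.tsv")
    ionet.write_edge_list(reweighted_net, out / "network_reweighted.tsv")
    counts["n_genes_removal"] = removal_net.number_of_nodes()

    # --- stage C: complex catalog ----------------------------------------
    catalog = build_catalog(
        reweighted_net,
        removal_net,
        min_density=cfg.min_density,
        penalty=cfg.penalty,
        max_overlap=cfg.max_overlap,
        min_inside_fraction=cfg.min_inside_fraction,
        min_size=cfg.min_size,
        max_size=cfg.max_size,
    )
    ionet.write_catalog(catalog, out / "catalog.tsv")
    ionet.write_gmt(
        GeneSetCollection(sets={c.id: c.members for c in catalog}, categories={c.id: c.provenance for c in catalog}),
        out / "catalog.gmt",
    )
    counts["n_complexes"] = len(catalog)
    counts["n_catalog_genes"] = len(catalog.genes())
    if len(catalog) == 0:
        logger.warning("empty complex catalog")

    # --- stage D: coordinated expression ---------------------------------
    ce = _fast_ce_matrix(catalog, reweighted_net, panel)
    ce.ce.to_csv(out / "ce_matrix.tsv", sep="\t", index_label="complex_id", float_format="%.6g")
    coordinated = islet_coordinated(ce.ce, cfg.islet_components, top_k=cfg.top_k)
    counts["n_coordinated"] = len(coordinated)
    benchmark_p = float("nan")
    curated = next(
        (s for n, s in biology_sets if biology_sets.categories.get(n) == "islet_biology"), None
    )
    benchmark_ids: set = set()
    if curated and len(catalog) > 1:
        benchmark_ids = benchmark_complexes(catalog, curated, cfg.benchmark_min_fraction)
        islet_max = ce.ce[list(cfg.islet_components)].max(axis=1)
        a = islet_max[islet_max.index.isin(benchmark_ids)].dropna()
        b = islet_max[~islet_max.index.isin(benchmark_ids)].dropna()
        if len(a) and len(b):
            benchmark_p = mwu_compare(a, b, alternative="greater")
    counts["n_benchmark"] = len(benchmark_ids)
    calls = pd.DataFrame(
        {
            "complex_id": [c.id for c in catalog],
            "islet_coordinated": [c.id in coordinated for c in catalog],
            "benchmark": [c.id in benchmark_ids for c in catalog],
        }
    )
    calls.to_csv(out / "coordination_calls.tsv", sep="\t", index=False)

    # --- stage E: functional convergence ---------------------------------
    background = frozenset(net.nodes)
    null_cache = NullCache(background, phenotype_sets, n_samples=cfg.n_samples, seed=cfg.seed)
    results = convergence_scan(
        catalog, phenotype_sets, background, n_samples=cfg.n_samples, seed=cfg.seed, null_cache=null_cache
    )
    conv = pd.DataFrame(
        [
            {
                "complex_id": r.complex_id,
                **{f"p_{k}": v for k, v in r.per_set_p.items()},
                "statistic": r.statistic,
                "p_combined": r.p_combined,
                "p_emp": r.p_emp,
                "p_emp_adj": r.p_emp_adj,
            }
            for r in results
        ]
    )
    conv.to_csv(out / "convergence.tsv", sep="\t", index=False, float_format="%.6g")
    significant = [c for c, r in zip(catalog, results) if r.p_emp_adj < cfg.alpha]
    counts["n_significant"] = len(significant)

    # --- stage F: pathway over-representation ----------------------------
    if len(pathways) and significant:
        candidates = set().union(*(c.members for c in significant))
        ora = pathway_ora(candidates, pathways, net.nodes)
    else:
        ora = pd.DataFrame(columns=["pathway", "n_pathway", "n_overlap", "p", "p_adj"])
    ora.to_csv(out / "pathway_ora.tsv", sep="\t", index=False, float_format="%.6g")
    counts["n_pathways_tested"] = len(ora)

    # --- stage G: GWAS enrichment ----------------------------------------
    gwas_rows = []
    scores = None
    if coords is not None and gwas is not None:
        scores = map_snps_to_genes(gwas, coords, trait="glycemic")
        input_genes = phenotype_sets.union()
        for c in significant:
            for mode in ("all", "no_gws", "no_input"):
                genes_mode = complex_gene_variants(
                    c.members, scores, input_genes, mode=mode, gws_threshold=cfg.gws_threshold
                )
                if genes_mode is None:
                    continue
                p = magenta_style_enrichment(
                    genes_mode,
                    scores,
                    percentile=cfg.percentile,
                    null="random_sets",
                    n_perm=cfg.n_perm,
                    seed=cfg.seed,
                )
                gwas_rows.append(
                    {
                        "complex_id": c.id,
                        "trait": scores.trait,
                        "mode": mode,
                        "n_genes": len(genes_mode),
                        "p": p,
                    }
                )
    gwas_df = pd.DataFrame(gwas_rows, columns=["complex_id", "trait", "mode", "n_genes", "p"])
    gwas_df.to_csv(out / "gwas_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    counts["n_enrichment_tests"] = len(gwas_df)
    counts["n_significant_enrichments"] = int((gwas_df["p"] < cfg.alpha).sum()) if len(gwas_df) else 0

    # --- stage H: prioritization -----------------------------------------
    if scores is not None and significant and len(biology_sets):
        prio = prioritize_candidates(
            significant, phenotype_sets, biology_sets, [scores], p_threshold=cfg.priority_p_threshold
        )
    else:
        prio = pd.DataFrame(columns=["gene", "complexes", "n_biology_sets", "min_snp_p", "trait"])
    prio.to_csv(out / "prioritized.tsv", sep="\t", index=False, float_format="%.6g")
    counts["n_prioritized"] = len(prio)

    manifest = RunManifest(config_hash=_config_hash(cfg), seed=cfg.seed, stage_counts=counts)
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return manifest


# --- input validation -----------------------------------------------------


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Check input files for format violations; returns human-readable issues."""
    issues: list[str] = []
    paths = cfg.inputs
    if not paths:
        return issues  # synthetic mode: generators enforce their own invariants
    if "edge_list" in paths:
        df = pd.read_csv(paths["edge_list"], sep="\t")
        pairs = set()
        for ln, (a, b, w) in enumerate(df.itertuples(index=False, name=None), start=2):
            key = (min(a, b), max(a, b))
            if a == b:
                issues.append(f"edge list line {ln}: self-loop {a}")
            if key in pairs:
                issues.append(f"edge list line {ln}: duplicate edge {a}-{b}")
            pairs.add(key)
            if not 0 < w <= 1:
                issues.append(f"edge list line {ln}: weight {w} outside (0,1]")
    if "gwas" in paths:
        df = pd.read_csv(paths["gwas"], sep="\t")
        bad = df.index[(df["p"] <= 0) | (df["p"] > 1)]
        issues.extend(f"gwas line {i + 2}: p outside (0,1]" for i in bad)
        bad = df.index[df["pos"] < 0]
        issues.extend(f"gwas line {i + 2}: negative position" for i in bad)
    if "phenotype_gmt" in paths:
        with open(paths["phenotype_gmt"]) as fh:
            for ln, line in enumerate(fh, start=1):
                if len(line.rstrip("\n").split("\t")) < 3:
                    issues.append(f"gmt line {ln}: fewer than 3 fields")
    if "expression" in paths and "sample_map" in paths:
        values = pd.read_csv(paths["expression"], sep="\t", index_col="gene", nrows=5)
        sm = pd.read_csv(paths["sample_map"], sep="\t")
        missing = set(values.columns) - set(sm["sample"])
        issues.extend(f"sample {s} missing from sample map" for s in sorted(missing))
    if "bed" in paths:
        df = pd.read_csv(
            paths["bed"], sep="\t", header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"],
        )
        for chrom, sub in df.groupby("chrom"):
            if not sub["start"].is_monotonic_increasing:
                issues.append(f"bed: {chrom} not sorted by start")
        bad = df.index[df["start"] >= df["end"]]
        issues.extend(f"bed line {i + 1}: start >= end" for i in bad)
    return issues
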