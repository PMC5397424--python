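"""Readers and writers for the plain-text interchange formats.

Edge lists, presence evidence, expression matrices, sample maps and GWAS
summaries are TSV; gene sets are GMT; gene coordinates are BED6 (0-based
half-open, strand in column 6); planted truth is JSON. Every writer sorts
its rows so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .convergence import GeneSetCollection
from .coordination import ExpressionPanel
from .network import network_from_edges
from .synthetic import SyntheticTruth


# --- edge lists -----------------------------------------------------------


def write_edge_list(net: nx.Graph, path):
    rows = sorted((min(a, b), max(a, b), d["weight"]) for a, b, d in net.edges(data=True))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edge_list(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return network_from_edges(df.itertuples(index=False, name=None), nodes=nodes)


# --- GMT ------------------------------------------------------------------


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.categories.get(name, "na")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets, cats = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = frozenset(g for g in genes if g)
            cats[name] = desc
    return GeneSetCollection(sets=sets, categories=cats)


# --- expression -----------------------------------------------------------


def write_expression(panel: ExpressionPanel, values_path, sample_map_path):
    panel.values.sort_index().to_csv(values_path, sep="\t", index_label="gene", float_format="%.6g")
    sm = panel.sample_tissue.rename("tissue").rename_axis("sample").reset_index()
    sm.to_csv(sample_map_path, sep="\t", index=False)


def read_expression(values_path, sample_map_path) -> ExpressionPanel:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    sm = pd.read_csv(sample_map_path, sep="\t", dtype=str)
    return ExpressionPanel(values=values, sample_tissue=pd.Series(sm["tissue"].to_numpy(), index=sm["sample"]))


# --- presence evidence ----------------------------------------------------


def write_presence(presence: pd.DataFrame, path):
    presence.sort_values(["dataset", "gene"], kind="stable").to_csv(path, sep="\t", index=False)


def read_presence(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# --- BED6 gene coordinates ------------------------------------------------


def write_bed(coords: pd.DataFrame, path):
    with open(path, "w") as fh:
        for gene, row in coords.sort_values(["chrom", "start"]).iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{gene}\t0\t{row['strand']}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df.set_index("gene")[["chrom", "start", "end", "strand"]]


# --- GWAS summaries -------------------------------------------------------


def write_gwas(snps: pd.DataFrame, path):
    snps.sort_values(["chrom", "pos", "snp"], kind="stable").to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    if (df["p"] <= 0).any() or (df["p"] > 1).any():
        raise ValueError("GWAS p-values must be in (0, 1]")
    return df


# --- truth ----------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path):
    payload = {
        "planted_complexes": [sorted(c) for c in truth.planted_complexes],
        "coordinated_tissue_of_complex": {
            str(k): v for k, v in truth.coordinated_tissue_of_complex.items()
        },
        "enriched_complexes": sorted(truth.enriched_complexes),
        "causal_genes": sorted(truth.causal_genes),
        "set_planted_genes": {k: sorted(v) for k, v in truth.set_planted_genes.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_complexes=[frozenset(c) for c in payload["planted_complexes"]],
        coordinated_tissue_of_complex={
            int(k): v for k, v in payload["coordinated_tissue_of_complex"].items()
        },
        enriched_complexes=set(payload["enriched_complexes"]),
        causal_genes=frozenset(payload["causal_genes"]),
        set_planted_genes={k: frozenset(v) for k, v in payload["set_planted_genes"].items()},
    )


# --- catalog --------------------------------------------------------------


def write_catalog(catalog, path):
    from .complexes import ComplexCatalog  # noqa: F401  (type only)

    with open(path, "w") as fh:
        fh.write(
            "complex_id\tprovenance\tsize\tdensity\tdiameter\tavg_degree\t"
            "clustering_coeff\tmean_betweenness\tmembers\n"
        )
        for c in catalog:
            fh.write(
                f"{c.id}\t{c.provenance}\t{c.size}\t{c.density:.6g}\t{c.diameter:.6g}\t"
                f"{c.avg_degree:.6g}\t{c.clustering_coeff:.6g}\t{c.mean_betweenness:.6g}\t"
                + ",".join(sorted(c.members))
                + "\n"
            )


def read_catalog(path):
    from .complexes import ComplexCatalog, ProteinComplex

    df = pd.read_csv(path, sep="\t", dtype={"complex_id": str, "members": str})
    complexes = [
        ProteinComplex(
            id=row["complex_id"],
            members=frozenset(row["members"].split(",")),
            provenance=row["provenance"],
            density=row["density"],
            diameter=row["diameter"],
            avg_degree=row["avg_degree"],
            clustering_coeff=row["clustering_coeff"],
            mean_betweenness=row["mean_betweenness"],
        )
        for _, row in df.iterrows()
    ]
    return ComplexCatalog(complexes)
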