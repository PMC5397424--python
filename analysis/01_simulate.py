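#!/usr/bin/env python
"""Generate the synthetic islet study: a weighted interactome with planted
complexes and hubs, multi-tissue expression with planted coordination,
presence evidence, phenotype/biology/pathway gene sets and GWAS summaries.

Writes all inputs (plus the planted truth) under results/demo/inputs/.
"""

from pathlib import Path

import isletnet as I
from isletnet import io as ionet
from isletnet.synthetic import generate_biology_sets, generate_pathways

OUT = Path(__file__).resolve().parent.parent / "results" / "demo" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

cfg = I.demo_config(seed=42)
net, truth = I.generate_network(cfg)
panel = I.generate_expression(net, truth, cfg)
presence = I.generate_presence_evidence(net, cfg)
phenotype = I.generate_gene_sets(truth, cfg)
biology = generate_biology_sets(truth, cfg)
pathways = generate_pathways(truth, cfg)
coords, gwas = I.generate_gwas(truth, cfg)

ionet.write_edge_list(net, OUT / "network.tsv")
ionet.write_expression(panel, OUT / "expression.tsv", OUT / "sample_map.tsv")
ionet.write_presence(presence, OUT / "presence.tsv")
ionet.write_gmt(phenotype, OUT / "phenotype_sets.gmt")
ionet.write_gmt(biology, OUT / "biology_sets.gmt")
ionet.write_gmt(pathways, OUT / "pathways.gmt")
ionet.write_bed(coords, OUT / "genes.bed")
ionet.write_gwas(gwas, OUT / "gwas.tsv")
ionet.write_truth(truth, OUT / "truth.json")

print(
    f"simulated {net.number_of_nodes()} genes, {net.number_of_edges()} interactions, "
    f"{len(truth.planted_complexes)} planted complexes "
    f"({len(truth.enriched_complexes)} with planted gene-set support), "
    f"{cfg.n_tissues} tissues x {cfg.samples_per_tissue} samples -> {OUT}"
)
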