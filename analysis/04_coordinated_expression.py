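#!/usr/bin/env python
"""Score per-tissue coordinated expression (edge-restricted mean pairwise
Pearson correlation, Fisher-transformed, standardized within tissue), call
islet-coordinated complexes (islet component in the CE top 3), and compare
curated-gene benchmark complexes against the rest (one-sided Mann-Whitney).
"""

from pathlib import Path

import pandas as pd

from isletnet import io as ionet
from isletnet.coordination import benchmark_complexes, islet_coordinated, mwu_compare
from isletnet.pipeline import _fast_ce_matrix

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"
ISLET = ("whole_islet", "beta", "non_beta")

catalog = ionet.read_catalog(BASE / "catalog.tsv")
net = ionet.read_edge_list(BASE / "network_reweighted.tsv")
panel = ionet.read_expression(BASE / "inputs" / "expression.tsv", BASE / "inputs" / "sample_map.tsv")
biology = ionet.read_gmt(BASE / "inputs" / "biology_sets.gmt")

ce = _fast_ce_matrix(catalog, net, panel)
ce.ce.to_csv(BASE / "ce_matrix.tsv", sep="\t", index_label="complex_id", float_format="%.6g")

coordinated = islet_coordinated(ce.ce, ISLET, top_k=3)
curated = next(s for _, s in biology)
bench = benchmark_complexes(catalog, curated, 0.10)
islet_max = ce.ce[list(ISLET)].max(axis=1)
p = mwu_compare(
    islet_max[islet_max.index.isin(bench)].dropna(),
    islet_max[~islet_max.index.isin(bench)].dropna(),
)

calls = pd.DataFrame(
    {
        "complex_id": [c.id for c in catalog],
        "islet_coordinated": [c.id in coordinated for c in catalog],
        "benchmark": [c.id in bench for c in catalog],
    }
)
calls.to_csv(BASE / "coordination_calls.tsv", sep="\t", index=False)

print(
    f"{len(coordinated)} of {len(catalog)} complexes islet-coordinated (top-3 rule); "
    f"{len(bench)} benchmark complexes (>=10% curated genes) show higher islet CE "
    f"than the rest (one-sided MWU p = {p:.3g})"
)
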