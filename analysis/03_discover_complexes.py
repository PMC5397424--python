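#!/usr/bin/env python
"""Decompose the tissue networks into overlapping protein complexes:
cohesiveness-based detection (min density 0.2) on the reweighted network,
spoke-hub detection (5% partner filter) on the node-removal network,
matching-score merging at 0.3, size filter 6-50, topology metrics.
Also measures recovery of the planted modules.
"""

from pathlib import Path

import numpy as np

from isletnet import io as ionet
from isletnet.complexes import build_catalog, matching_score
from isletnet.convergence import GeneSetCollection

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"

reweighted = ionet.read_edge_list(BASE / "network_reweighted.tsv")
removal = ionet.read_edge_list(BASE / "network_removal.tsv")
truth = ionet.read_truth(BASE / "inputs" / "truth.json")

catalog = build_catalog(reweighted, removal)
ionet.write_catalog(catalog, BASE / "catalog.tsv")
ionet.write_gmt(
    GeneSetCollection(
        sets={c.id: c.members for c in catalog},
        categories={c.id: c.provenance for c in catalog},
    ),
    BASE / "catalog.gmt",
)

recovery = np.mean(
    [
        max((matching_score(pc, c.members) for c in catalog), default=0.0) >= 0.5
        for pc in truth.planted_complexes
    ]
)
sizes = [c.size for c in catalog]
print(
    f"{len(catalog)} overlapping complexes over {len(catalog.genes())} genes "
    f"(sizes {min(sizes)}-{max(sizes)}, median {int(np.median(sizes))}); "
    f"{recovery:.0%} of planted modules recovered at matching score >= 0.5"
)
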