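#!/usr/bin/env python
"""Build the two tissue-specific networks from the reference interactome:
node-removal (prune genes absent in every covering dataset) and
edge-reweight (w' = w * rw^n with rw = 0.1).
"""

from pathlib import Path

from isletnet import io as ionet
from isletnet.network import consolidate_presence, edge_reweight, node_removal

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"

net = ionet.read_edge_list(BASE / "inputs" / "network.tsv")
presence = ionet.read_presence(BASE / "inputs" / "presence.tsv")
call = consolidate_presence(presence, net.nodes)

removal = node_removal(net, call)
reweighted = edge_reweight(net, call, rw=0.1)
ionet.write_edge_list(removal, BASE / "network_removal.tsv")
ionet.write_edge_list(reweighted, BASE / "network_reweighted.tsv")

n_pruned = net.number_of_nodes() - removal.number_of_nodes()
print(
    f"{n_pruned} of {net.number_of_nodes()} genes called not-expressed and pruned; "
    f"node-removal network: {removal.number_of_nodes()} genes / {removal.number_of_edges()} edges; "
    f"edge-reweighted network keeps all {reweighted.number_of_nodes()} genes"
)
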