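import numpy as np
import pytest

import isletnet as I
from isletnet.complexes import build_catalog
from isletnet.network import consolidate_presence, edge_reweight, node_removal


class DemoFixture:
    """The demo study: network, evidence, tissue networks, catalog, sets."""

    def __init__(self, seed=42):
        self.cfg = I.demo_config(seed=seed)
        self.net, self.truth = I.generate_network(self.cfg)
        self.presence = I.generate_presence_evidence(self.net, self.cfg)
        self.call = consolidate_presence(self.presence, self.net.nodes)
        self.removal_net = node_removal(self.net, self.call)
        self.reweighted_net = edge_reweight(self.net, self.call)
        self.catalog = build_catalog(self.reweighted_net, self.removal_net)
        self.phenotype_sets = I.generate_gene_sets(self.truth, self.cfg)


@pytest.fixture(scope="session")
def demo():
    return DemoFixture(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
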