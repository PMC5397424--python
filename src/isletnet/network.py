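"""Tissue-specific interaction-network construction.

A reference protein-interaction network (an undirected :class:`networkx.Graph`
with a ``weight`` attribute in ``(0, 1]`` on every edge) is specialised to a
tissue in two standard ways:

* **node removal** — genes judged not expressed in the tissue are deleted
  together with their interactions;
* **edge reweighting** — every edge weight is multiplied by ``rw ** n`` where
  ``n`` is the number of its endpoints judged not expressed and ``rw`` is the
  residual probability that such a gene is nevertheless expressed
  (default 0.1).

Expression judgements come from heterogeneous presence/absence evidence
tables. A *benefit-of-the-doubt* rule is applied: a gene is flagged
not-expressed only when at least one dataset covers it with a confident call
and every confident call is ``absent``; genes that are uncovered everywhere,
or only called ``uncertain``, count as expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATUSES = frozenset({"present", "absent", "uncertain", "uncovered"})

#: statuses that count as confident coverage of a gene
_CONFIDENT = frozenset({"present", "absent"})


class NetworkFormatError(ValueError):
    """Raised when an edge list or evidence table violates the data model."""


def network_from_edges(edges, nodes=None) -> nx.Graph:
    """Build a weighted interaction network from ``(gene_a, gene_b, weight)`` triples.

    Enforces the invariants: undirected, no self-loops, no duplicate edges
    (a duplicate with a different weight is an error) and weights in (0, 1].
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b, w in edges:
        if a == b:
            raise NetworkFormatError(f"self-loop on {a!r}")
        w = float(w)
        if not (0.0 < w <= 1.0):
            raise NetworkFormatError(f"edge {a!r}-{b!r} weight {w} outside (0, 1]")
        if g.has_edge(a, b):
            raise NetworkFormatError(f"duplicate edge {a!r}-{b!r}")
        g.add_edge(a, b, weight=w)
    return g


@dataclass
class TissueExpressionCall:
    """Per-gene expressed/not-expressed calls for one tissue."""

    expressed: dict[str, bool] = field(default_factory=dict)

    def is_expressed(self, gene: str) -> bool:
        # genes never seen by any evidence table get the benefit of the doubt
        return self.expressed.get(gene, True)

    def n_unexpressed(self, a: str, b: str) -> int:
        """Number of not-expressed endpoints of the edge ``a``–``b`` (0, 1 or 2)."""
        return (not self.is_expressed(a)) + (not self.is_expressed(b))


def consolidate_presence(
    evidence: pd.DataFrame,
    genes,
    *,
    require_all_absent: bool = True,
) -> TissueExpressionCall:
    """Collapse a multi-dataset presence/absence table into one call per gene.

    Parameters
    ----------
    evidence
        Long-format table with columns ``dataset``, ``gene``, ``status``;
        status values must be in ``{present, absent, uncertain, uncovered}``.
    genes
        The genes that need a call (typically the network node set).
    require_all_absent
        Default (True): a gene is not-expressed iff every dataset covering it
        with a confident call says ``absent``. The stricter alternative
        (False) flags a gene as not-expressed if *any* confident call is
        ``absent``.
    """
    bad = set(evidence["status"]) - VALID_STATUSES
    if bad:
        raise NetworkFormatError(f"unknown presence statuses: {sorted(bad)}")

    confident = evidence[evidence["status"].isin(_CONFIDENT)]
    by_gene = confident.groupby("gene")["status"]
    n_cover = by_gene.size()
    n_absent = by_gene.apply(lambda s: (s == "absent").sum())

    expressed: dict[str, bool] = {}
    for gene in genes:
        cov = int(n_cover.get(gene, 0))
        if cov == 0:
            expressed[gene] = True  # benefit of the doubt
            continue
        absent = int(n_absent.get(gene, 0))
        if require_all_absent:
            expressed[gene] = absent < cov
        else:
            expressed[gene] = absent == 0
    return TissueExpressionCall(expressed)


def node_removal(net: nx.Graph, call: TissueExpressionCall) -> nx.Graph:
    """Return the subgraph induced on the expressed genes (weights unchanged)."""
    keep = [v for v in net.nodes if call.is_expressed(v)]
    if not keep:
        logger.warning("node_removal: no gene is expressed; returning the empty network")
    return net.subgraph(keep).copy()


def edge_reweight(net: nx.Graph, call: TissueExpressionCall, rw: float = 0.1) -> nx.Graph:
    """Down-weight edges touching not-expressed genes: ``w' = w * rw**n``.

    ``n`` is the number of not-expressed endpoints (0, 1 or 2). The node set
    is unchanged; weights may underflow but edges are always retained.
    """
    if not (0.0 < rw <= 1.0):
        raise ValueError(f"rw must be in (0, 1], got {rw}")
    out = net.copy()
    for a, b, data in out.edges(data=True):
        n = call.n_unexpressed(a, b)
        if n:
            data["weight"] = data["weight"] * rw**n
    return out


def threshold_presence(values: pd.Series, cutoff: float) -> pd.Series:
    """Helper turning raw per-gene expression values into presence statuses.

    Values >= ``cutoff`` become ``present``, values below become ``absent``;
    NaN becomes ``uncovered``.
    """
    out = pd.Series("uncovered", index=values.index, dtype=object)
    out[values >= cutoff] = "present"
    out[values < cutoff] = "absent"
    return out
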