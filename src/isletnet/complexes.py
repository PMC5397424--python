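"""Overlapping protein-complex discovery on a weighted interaction network.

Two complementary decompositions are combined:

* a greedy seed-and-grow search maximising the *cohesiveness*
  ``f(C) = w_in(C) / (w_in(C) + w_bound(C) + penalty * |C|)`` of a candidate
  set ``C`` (``w_in`` = total internal edge weight, ``w_bound`` = total weight
  on edges leaving ``C``), run on the edge-reweighted tissue network and
  filtered at a minimum density of 0.2;
* a spoke-hub construction — each gene together with its first-order
  interaction partners — on the node-removal tissue network, pruned of
  members with fewer than 5% of their interaction partners inside the
  candidate.

Candidates are merged whenever their matching score
``|A∩B|² / (|A|·|B|)`` exceeds 0.3, then filtered to sizes 6–50.
Every step is deterministic: ties are broken lexicographically on gene
identifiers and merging unions connected components of the overlap graph
until a fixed point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "ProteinComplex",
    "ComplexCatalog",
    "density",
    "cohesiveness",
    "cohesive_detect",
    "spoke_hub_detect",
    "matching_score",
    "merge_complexes",
    "complex_metrics",
    "build_catalog",
]


def density(members, net: nx.Graph) -> float:
    """Average internal edge weight over all member pairs (missing edges = 0)."""
    members = list(members)
    k = len(members)
    if k < 2:
        raise ValueError("density is undefined for fewer than 2 members")
    mset = set(members)
    total = 0.0
    for a in members:
        if a not in net:
            continue
        for b, data in net[a].items():
            if b in mset and a < b:
                total += data["weight"]
    return total / (k * (k - 1) / 2)


def cohesiveness(members, net: nx.Graph, penalty: float = 2.0) -> float:
    """``w_in / (w_in + w_bound + penalty * |C|)`` of a member set."""
    mset = set(members)
    w_in = 0.0
    w_bound = 0.0
    for a in mset:
        for b, data in net[a].items():
            if b in mset:
                if a < b:
                    w_in += data["weight"]
            else:
                w_bound += data["weight"]
    denom = w_in + w_bound + penalty * len(mset)
    return w_in / denom if denom > 0 else 0.0


def _climb(adj, wdeg, initial, penalty):
    """Greedy hill-climb on cohesiveness with single-node add/remove moves.

    When no single move improves, connected pair additions are evaluated as
    an escape from local optima (a weak node can unlock a strong neighbour).
    Returns the locally optimal member set. Deterministic: the best strictly
    improving move is taken, ties preferring additions, then smaller gene id.
    """
    members = set(initial)
    # weight from each touched node to the current cluster
    w_to: dict = {}
    w_in = 0.0
    w_bound = 0.0
    for v in members:
        for u, w in adj[v].items():
            w_to[u] = w_to.get(u, 0.0) + w
    for v in members:
        wv_in = sum(w for u, w in adj[v].items() if u in members)
        w_in += wv_in
        w_bound += wdeg[v] - wv_in
    w_in /= 2.0

    def f(win, wbound, size):
        denom = win + wbound + penalty * size
        return win / denom if denom > 0 else 0.0

    current = f(w_in, w_bound, len(members))
    while True:
        best = None  # (f, is_add, node)
        # additions: external nodes adjacent to the cluster
        for v, wv in w_to.items():
            if v in members or wv <= 0.0:
                continue
            nf = f(w_in + wv, w_bound - wv + (wdeg[v] - wv), len(members) + 1)
            key = (nf, 1, _neg_lex(v))
            if nf > current + 1e-12 and (best is None or key > best[0]):
                best = (key, True, v)
        # removals
        if len(members) > 1:
            for v in members:
                wv = w_to.get(v, 0.0)  # weight from v to the rest of the cluster
                nf = f(w_in - wv, w_bound + wv - (wdeg[v] - wv), len(members) - 1)
                key = (nf, 0, _neg_lex(v))
                if nf > current + 1e-12 and (best is None or key > best[0]):
                    best = (key, False, v)
        if best is None:
            # connected-pair additions: v external (adjacent to C or to w),
            # w a neighbour of v; all terms O(1) from the maintained w_to
            pair_best = None
            for v in sorted(w_to):
                if v in members:
                    continue
                wv = w_to[v]
                for w in sorted(adj[v]):
                    if w in members:
                        continue
                    if w in w_to and w < v:
                        continue  # pair reachable from both sides; count once
                    a_vw = adj[v][w]
                    ww = w_to.get(w, 0.0)
                    new_in = w_in + wv + ww + a_vw
                    new_bound = (
                        w_bound - wv - ww
                        + (wdeg[v] - wv - a_vw)
                        + (wdeg[w] - ww - a_vw)
                    )
                    nf = f(new_in, new_bound, len(members) + 2)
                    key = (nf, _neg_lex(v), _neg_lex(w))
                    if nf > current + 1e-12 and (pair_best is None or key > pair_best[0]):
                        pair_best = (key, v, w)
            if pair_best is None:
                return frozenset(members)
            _, v, w = pair_best
            for node in (v, w):
                wv = w_to.get(node, 0.0)
                members.add(node)
                w_in += wv
                w_bound += wdeg[node] - 2 * wv
                for u, wt in adj[node].items():
                    w_to[u] = w_to.get(u, 0.0) + wt
            current = f(w_in, w_bound, len(members))
            continue
        _, is_add, v = best
        # w_to[v] is v's weight to the other members, which is unchanged by
        # moving v itself; only the neighbours' entries need updating.
        wv = w_to.get(v, 0.0)
        if is_add:
            members.add(v)
            w_in += wv
            w_bound += wdeg[v] - 2 * wv
            for u, w in adj[v].items():
                w_to[u] = w_to.get(u, 0.0) + w
        else:
            members.discard(v)
            w_in -= wv
            w_bound -= wdeg[v] - 2 * wv
            for u, w in adj[v].items():
                w_to[u] = w_to.get(u, 0.0) - w
        current = f(w_in, w_bound, len(members))


class _NegLex:
    """Wrapper inverting lexicographic order so max() prefers smaller ids."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __gt__(self, other):
        return self.v < other.v

    def __lt__(self, other):
        return self.v > other.v

    def __eq__(self, other):
        return self.v == other.v


def _neg_lex(v):
    return _NegLex(v)


def cohesive_detect(
    net: nx.Graph,
    min_density: float = 0.2,
    penalty: float = 2.0,
    seed_all_nodes: bool = False,
) -> list[frozenset]:
    """Greedy cohesiveness-based detection of dense overlapping candidates.

    Seeds are nodes in decreasing weighted-degree order (ties: gene id); a
    node already covered by an accepted candidate is skipped unless
    ``seed_all_nodes`` is set. Candidates with fewer than 2 members or
    density below ``min_density`` are discarded.
    """
    if net.number_of_nodes() == 0:
        return []
    adj = {v: {u: d["weight"] for u, d in net[v].items()} for v in net.nodes}
    wdeg = {v: sum(adj[v].values()) for v in net.nodes}
    order = sorted(net.nodes, key=lambda v: (-wdeg[v], v))

    covered: set = set()
    candidates: list[frozenset] = []
    seen: set = set()
    for seed in order:
        if not seed_all_nodes and seed in covered:
            continue
        cand = _climb(adj, wdeg, {seed}, penalty)
        covered |= cand
        if len(cand) >= 2 and cand not in seen:
            candidates.append(cand)
            seen.add(cand)

    # fusion refinement: two locally optimal clusters joined by weak edges can
    # form a better cluster than either; agglomeratively replace the best such
    # pair by the climbed union until no pair improves
    import heapq

    fscore = {c: cohesiveness(c, net, penalty) for c in candidates}
    alive: set = set(candidates)

    def qualifying(a, b):
        # a raw union need not beat the better half before climbing, but a
        # winning fusion starts close to it; only unions within 10% of the
        # better half's cohesiveness are worth climbing
        if not _touching(a, b, adj):
            return None
        fu = cohesiveness(a | b, net, penalty)
        if fu > 0.9 * max(fscore[a], fscore[b]) + 1e-12:
            return fu
        return None

    heap: list = []
    pool = sorted(alive, key=lambda s: (-len(s), sorted(s)))
    for a, b in itertools.combinations(pool, 2):
        fu = qualifying(a, b)
        if fu is not None:
            heap.append((-fu, sorted(a), sorted(b), a, b))
    heapq.heapify(heap)
    order_of: dict = {c: i for i, c in enumerate(candidates)}
    while heap:
        _, _, _, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        fused = _climb(adj, wdeg, a | b, penalty)
        if len(fused) < 2 or cohesiveness(fused, net, penalty) <= max(fscore[a], fscore[b]) + 1e-12:
            continue  # climb did not actually beat the halves; keep them
        alive.discard(a)
        alive.discard(b)
        if fused in alive or fused in seen and fused not in order_of:
            continue
        seen.add(fused)
        fscore[fused] = cohesiveness(fused, net, penalty)
        order_of.setdefault(fused, min(order_of.get(a, 1 << 30), order_of.get(b, 1 << 30)))
        for other in sorted(alive, key=lambda s: (-len(s), sorted(s))):
            fu = qualifying(fused, other)
            if fu is not None:
                heapq.heappush(heap, (-fu, sorted(fused), sorted(other), fused, other))
        alive.add(fused)

    result = sorted(alive, key=lambda c: order_of.get(c, 1 << 30))
    return [c for c in result if density(c, net) >= min_density]


def _touching(a, b, adj) -> bool:
    """True when two member sets overlap or are joined by at least one edge."""
    if a & b:
        return True
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    return any(u in large for v in small for u in adj[v])


def spoke_hub_detect(net: nx.Graph, min_inside_fraction: float = 0.05) -> list[frozenset]:
    """One candidate per hub: the hub plus its first-order partners.

    A single-pass topology filter removes every non-hub member whose
    network-wide partner count inside the *original* candidate is strictly
    below ``min_inside_fraction`` of its total partner count. Edge weights
    are ignored.
    """
    out = []
    seen = set()
    for hub in sorted(net.nodes):
        cand = set(net[hub]) | {hub}
        if len(cand) < 2:
            continue
        kept = {hub}
        for v in cand - {hub}:
            partners = set(net[v])
            if not partners:
                continue
            inside = len(partners & cand)
            if inside / len(partners) >= min_inside_fraction:
                kept.add(v)
        fs = frozenset(kept)
        if len(fs) >= 2 and fs not in seen:
            out.append(fs)
            seen.add(fs)
    return out


def matching_score(a, b) -> float:
    """Overlap measure ``|a ∩ b|**2 / (|a| * |b|)`` in [0, 1]."""
    if not a or not b:
        raise ValueError("matching_score is undefined for empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def _canonical_order(sets):
    return sorted(sets, key=lambda s: (-len(s), sorted(s)))


def merge_complexes(candidates, max_overlap: float = 0.3) -> list[frozenset]:
    """Union overlapping candidates until no pair has matching score > ``max_overlap``.

    Pairs are merged one at a time in a deterministic order — descending size
    of the larger set, then of the smaller, then lexicographic smallest
    member — until a fixed point, which guarantees the postcondition. The
    large-first order lets noisy look-alike candidates coalesce before they
    are compared against small tight ones, whose overlap with the grown
    union then usually falls below the threshold.
    """
    import heapq

    sets = [frozenset(c) for c in candidates]
    if any(not s for s in sets):
        raise ValueError("candidates must be non-empty sets")
    sets = list(dict.fromkeys(_canonical_order(sets)))  # dedupe, stable order

    alive: dict[int, frozenset] = dict(enumerate(sets))
    index: dict = {}
    for i, s in alive.items():
        for g in s:
            index.setdefault(g, set()).add(i)

    def pair_key(a: frozenset, b: frozenset):
        # larger set first; ties broken on sorted member tuples
        ka, kb = (-len(a), tuple(sorted(a))), (-len(b), tuple(sorted(b)))
        return min(ka, kb), max(ka, kb)

    heap: list = []

    def push_pairs_for(i: int):
        s = alive[i]
        neighbours: set = set()
        for g in s:
            neighbours |= index.get(g, set())
        neighbours.discard(i)
        for j in neighbours:
            if matching_score(s, alive[j]) > max_overlap:
                heapq.heappush(heap, (pair_key(s, alive[j]), i, j))

    for i in list(alive):
        s = alive[i]
        neighbours: set = set()
        for g in s:
            neighbours |= index.get(g, set())
        for j in neighbours:
            if j <= i:
                continue
            if matching_score(s, alive[j]) > max_overlap:
                heapq.heappush(heap, (pair_key(s, alive[j]), i, j))

    next_id = len(sets)
    while heap:
        _, i, j = heapq.heappop(heap)
        if i not in alive or j not in alive:
            continue  # stale entry
        union = alive[i] | alive[j]
        for k in (i, j):
            for g in alive[k]:
                index[g].discard(k)
            del alive[k]
        alive[next_id] = union
        for g in union:
            index.setdefault(g, set()).add(next_id)
        push_pairs_for(next_id)
        next_id += 1
    return _canonical_order(alive.values())


@dataclass
class ProteinComplex:
    """A named (possibly overlapping) complex with topology metrics."""

    id: str
    members: frozenset
    provenance: str  # cohesive | spokehub | merged
    density: float = float("nan")
    diameter: float = float("nan")
    avg_degree: float = float("nan")
    clustering_coeff: float = float("nan")
    mean_betweenness: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ComplexCatalog:
    complexes: list[ProteinComplex] = field(default_factory=list)

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self):
        return len(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    def member_sets(self) -> list[frozenset]:
        return [c.members for c in self.complexes]

    def genes(self) -> set:
        out: set = set()
        for c in self.complexes:
            out |= c.members
        return out


def complex_metrics(members, net: nx.Graph) -> dict:
    """Unweighted topology metrics of the induced subgraph.

    Diameter of a disconnected induced subgraph is the maximum over its
    connected components.
    """
    sub = net.subgraph(members)
    n = sub.number_of_nodes()
    if n == 0:
        return {k: math.nan for k in ("diameter", "avg_degree", "clustering_coeff", "mean_betweenness")}
    diam = 0
    for comp in nx.connected_components(sub):
        if len(comp) > 1:
            diam = max(diam, nx.diameter(sub.subgraph(comp)))
    bet = nx.betweenness_centrality(sub, normalized=True)
    return {
        "diameter": float(diam),
        "avg_degree": 2.0 * sub.number_of_edges() / n,
        "clustering_coeff": nx.average_clustering(sub),
        "mean_betweenness": sum(bet.values()) / n,
    }


def build_catalog(
    reweighted_net: nx.Graph,
    removal_net: nx.Graph,
    *,
    min_density: float = 0.2,
    penalty: float = 2.0,
    max_overlap: float = 0.3,
    min_inside_fraction: float = 0.05,
    min_size: int = 6,
    max_size: int = 50,
) -> ComplexCatalog:
    """Full discovery stage: detect, merge within and across stages, size-filter.

    Cohesive candidates come from the edge-reweighted network (weights
    matter), spoke-hub candidates from the node-removal network (weights
    ignored). Each candidate list is merged internally at ``max_overlap``,
    the union is merged again, and the 6–50 size filter is applied last.
    Metrics are computed on the induced subgraph of the reweighted network
    (unweighted, except density which uses the reweighted weights).
    """
    cohesive = merge_complexes(
        cohesive_detect(reweighted_net, min_density=min_density, penalty=penalty),
        max_overlap,
    ) if reweighted_net.number_of_nodes() else []
    spokehub = merge_complexes(
        spoke_hub_detect(removal_net, min_inside_fraction=min_inside_fraction),
        max_overlap,
    ) if removal_net.number_of_nodes() else []

    origin: dict[frozenset, str] = {}
    for s in spokehub:
        origin[s] = "spokehub"
    for s in cohesive:
        origin[s] = "merged" if s in origin else "cohesive"

    merged = merge_complexes(cohesive + spokehub, max_overlap) if (cohesive or spokehub) else []
    complexes = []
    idx = 1
    for s in merged:
        if not (min_size <= len(s) <= max_size):
            continue
        prov = origin.get(s, "merged")
        met = complex_metrics(s, reweighted_net)
        complexes.append(
            ProteinComplex(
                id=f"Complex-{idx}",
                members=s,
                provenance=prov,
                density=density(s, reweighted_net),
                **met,
            )
        )
        idx += 1
    return ComplexCatalog(complexes)
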