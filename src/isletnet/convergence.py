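"""Functional-convergence testing of disease gene sets on protein complexes.

For each complex, the enrichment of every phenotype gene set is scored with a
hypergeometric upper-tail test against the network gene background; the
per-set p-values are combined with Fisher's combined probability test
(statistic ``-2 * sum(ln p)``, chi-square with ``2k`` degrees of freedom).
Significance of the combined statistic is then calibrated against an
empirical null built by drawing many random gene sets of the same size from
the network and computing their combined statistic exactly as for real
complexes; the empirical p-value is the fraction of random sets at least as
extreme. Empirical p-values are Benjamini-Hochberg adjusted across
complexes.

The empirical null is sampled through an exact reformulation: genes are
partitioned into *atoms* of identical gene-set membership, and a uniform
without-replacement draw of ``size`` genes induces multivariate
hypergeometric counts over the atoms, from which the per-set overlap counts
(the sufficient statistic of the combined test) follow directly. This is
distribution-identical to drawing gene sets one by one and makes 100,000
draws per complex size cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "ConvergenceResult",
    "hypergeom_enrichment",
    "fishers_combined",
    "convergence_scan",
    "NullCache",
    "empirical_null",
    "empirical_p",
    "bh_adjust",
    "direct_overlap_matrix",
    "consensus_genes",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, frozenset]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, background) -> "GeneSetCollection":
        """Intersect every set with a background; empty intersections are kept
        as empty frozensets (they contribute p = 1 downstream)."""
        bg = set(background)
        out = GeneSetCollection.__new__(GeneSetCollection)
        out.sets = {n: frozenset(s & bg) for n, s in self.sets.items()}
        out.categories = dict(self.categories)
        return out

    def union(self) -> frozenset:
        u: set = set()
        for s in self.sets.values():
            u |= s
        return frozenset(u)


def hypergeom_enrichment(hits: int, set_size: int, complex_size: int, background_size: int) -> float:
    """Upper-tail ``P(X >= hits)`` for X ~ Hypergeom(background, set, complex).

    Inclusive of the observed count; ``hits = 0`` gives exactly 1.
    """
    if hits < 0 or set_size < 0 or complex_size < 0:
        raise ValueError("counts must be non-negative")
    if hits > min(set_size, complex_size):
        raise ValueError(f"hits={hits} exceeds min(set, complex)")
    if max(set_size, complex_size) > background_size:
        raise ValueError("set or complex larger than background")
    if hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(hits - 1, background_size, set_size, complex_size))


def fishers_combined(pvals) -> tuple[float, float]:
    """Fisher's combined probability test: ``(-2 sum ln p, chi2_{2k} tail)``."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    return statistic, float(stats.chi2.sf(statistic, 2 * p.size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical null machinery


def _atoms(network_genes, sets: GeneSetCollection):
    """Partition the background into atoms of identical set membership.

    Returns (atom_counts: (n_atoms,), atom_mask: (n_atoms, n_sets) bool).
    """
    names = sets.names()
    pattern: dict[tuple, int] = {}
    counts: list[int] = []
    masks: list[tuple] = []
    for g in sorted(network_genes):
        key = tuple(g in sets.sets[n] for n in names)
        if key not in pattern:
            pattern[key] = len(counts)
            counts.append(0)
            masks.append(key)
        counts[pattern[key]] += 1
    return np.array(counts, dtype=np.int64), np.array(masks, dtype=bool)


def _logsf_tables(sets: GeneSetCollection, complex_size: int, background_size: int):
    """Per-set log upper-tail tables: table[j][k] = ln P(X_j >= k)."""
    tables = []
    for name in sets.names():
        k_set = len(sets.sets[name])
        kmax = min(k_set, complex_size)
        ks = np.arange(0, kmax + 1)
        with np.errstate(divide="ignore"):
            logsf = stats.hypergeom.logsf(ks - 1, background_size, k_set, complex_size)
        logsf[0] = 0.0  # P(X >= 0) = 1 exactly
        tables.append(logsf)
    return tables


class NullCache:
    """Empirical null distributions of the combined statistic, cached per size.

    One pipeline-level seed plus a per-size offset keeps runs reproducible
    even when sizes are requested in different orders.
    """

    def __init__(self, network_genes, sets: GeneSetCollection, n_samples: int = 100_000, seed: int = 0):
        self.background = sorted(network_genes)
        self.sets = sets.restricted_to(self.background)
        self.n_samples = int(n_samples)
        if self.n_samples < 100:
            import warnings

            warnings.warn("empirical null with fewer than 100 samples is unreliable")
        self.seed = int(seed)
        self._atom_counts, self._atom_mask = _atoms(self.background, self.sets)
        self._cache: dict[int, np.ndarray] = {}

    def null_for_size(self, size: int) -> np.ndarray:
        """Sorted array of ``n_samples`` null P_combined values for one size."""
        if size > len(self.background):
            raise ValueError("complex size exceeds network size")
        if size not in self._cache:
            rng = np.random.default_rng([self.seed % (2**31), size])
            draws = rng.multivariate_hypergeometric(
                self._atom_counts, size, size=self.n_samples, method="marginals"
            )
            hits = draws @ self._atom_mask  # (n_samples, n_sets)
            tables = _logsf_tables(self.sets, size, len(self.background))
            stat = np.zeros(self.n_samples)
            for j, tab in enumerate(tables):
                stat += tab[np.minimum(hits[:, j], len(tab) - 1)]
            p_comb = stats.chi2.sf(-2.0 * stat, 2 * len(self.sets))
            self._cache[size] = np.sort(p_comb)
        return self._cache[size]


def empirical_null(complex_size, sets, network_genes, n_samples=100_000, seed=0) -> np.ndarray:
    """Stand-alone null distribution of P_combined for one complex size."""
    return NullCache(network_genes, sets, n_samples=n_samples, seed=seed).null_for_size(complex_size)


def empirical_p(observed: float, null: np.ndarray, pseudo_count: bool = False) -> float:
    """Fraction of null P_combined values <= observed.

    The plain estimator ``count / n`` may be exactly 0; ``pseudo_count``
    switches to ``(count + 1) / (n + 1)``.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    count = int(np.searchsorted(np.sort(null), observed, side="right"))
    if pseudo_count:
        return (count + 1) / (null.size + 1)
    return count / null.size


@dataclass
class ConvergenceResult:
    complex_id: str
    per_set_hits: dict[str, int]
    per_set_p: dict[str, float]
    statistic: float
    p_combined: float
    p_emp: float = float("nan")
    p_emp_adj: float = float("nan")


def convergence_scan(
    catalog,
    sets: GeneSetCollection,
    network_genes,
    *,
    n_samples: int = 100_000,
    seed: int = 0,
    pseudo_count: bool = False,
    null_cache: NullCache | None = None,
) -> list[ConvergenceResult]:
    """Full convergence test for every complex in the catalog.

    Background = network gene set; gene sets are intersected with it first
    (genes without interaction partners drop out; a set left empty
    contributes p = 1). The empirical null is shared across complexes of
    equal size.
    """
    background = frozenset(network_genes)
    restricted = sets.restricted_to(background)
    if null_cache is None:
        null_cache = NullCache(background, sets, n_samples=n_samples, seed=seed)
    results = []
    for c in catalog:
        members = frozenset(c.members) & background
        size = len(members)
        hits, pvals = {}, {}
        for name, s in restricted:
            h = len(members & s)
            hits[name] = h
            pvals[name] = (
                1.0 if len(s) == 0 else hypergeom_enrichment(h, len(s), size, len(background))
            )
        statistic, p_comb = fishers_combined(list(pvals.values()))
        null = null_cache.null_for_size(size)
        p_emp = empirical_p(p_comb, null, pseudo_count=pseudo_count)
        results.append(
            ConvergenceResult(
                complex_id=c.id,
                per_set_hits=hits,
                per_set_p=pvals,
                statistic=statistic,
                p_combined=p_comb,
                p_emp=p_emp,
            )
        )
    adj = bh_adjust([r.p_emp for r in results])
    for r, a in zip(results, adj):
        r.p_emp_adj = float(a)
    return results


def direct_overlap_matrix(sets: GeneSetCollection, genome_background: int = 22_766):
    """Pairwise direct overlap of gene sets against a genome-wide background.

    Returns (count, percent-of-smaller, BH-adjusted-p) DataFrames. The
    percentage is relative to the smaller of the two sets; the
    hypergeometric test uses ``genome_background`` genes as the universe and
    BH adjustment runs across the distinct pairs.
    """
    names = sets.names()
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    for n in names:
        if len(sets.sets[n]) > genome_background:
            raise ValueError(f"set {n!r} larger than the background")
    k = len(names)
    count = pd.DataFrame(0, index=names, columns=names, dtype=int)
    percent = pd.DataFrame(0.0, index=names, columns=names)
    praw = pd.DataFrame(1.0, index=names, columns=names)
    pairs, pvals = [], []
    for i, a in enumerate(names):
        sa = sets.sets[a]
        count.loc[a, a] = len(sa)
        percent.loc[a, a] = 100.0
        for b in names[i + 1 :]:
            sb = sets.sets[b]
            inter = len(sa & sb)
            count.loc[a, b] = count.loc[b, a] = inter
            pct = 100.0 * inter / min(len(sa), len(sb))
            percent.loc[a, b] = percent.loc[b, a] = pct
            p = hypergeom_enrichment(inter, len(sa), len(sb), genome_background)
            pairs.append((a, b))
            pvals.append(p)
    adj = bh_adjust(pvals)
    for (a, b), q in zip(pairs, adj):
        praw.loc[a, b] = praw.loc[b, a] = q
    return count, percent, praw


def consensus_genes(sets: GeneSetCollection, min_sets: int = 4) -> frozenset:
    """Genes appearing in at least ``min_sets`` distinct sets."""
    from collections import Counter

    counts: Counter = Counter()
    for _, s in sets:
        counts.update(s)
    return frozenset(g for g, n in counts.items() if n >= min_sets)
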