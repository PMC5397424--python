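"""Per-tissue coordinated-expression (CE) scoring of protein complexes.

For a complex *c* and tissue *t* the raw score is the mean pairwise Pearson
correlation over the *interacting* member pairs only (each network edge
counted once):

    PCC.mean_ct = sum over edges (x, y) of PCC_xy^t / N_e

The raw means are Fisher-transformed, ``z = atanh(PCC.mean)``, and
standardised within each tissue across all complexes,
``CE_ct = (z_ct - mu_t) / sigma_t``, removing per-tissue location and scale
(which otherwise reflect sample size, not biology). A complex is called
*islet-coordinated* when at least one designated islet tissue component
(whole islet, beta cells, non-beta cells) ranks within the top ``k``
(default 3) tissues by CE.

Zero-variance expression vectors yield an undefined (NaN) pairwise
correlation; undefined pairs are excluded from the edge average with the
edge count decremented accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionPanel",
    "CEMatrix",
    "pairwise_pcc",
    "complex_pcc_mean",
    "fisher_z",
    "standardize_ce",
    "ce_matrix",
    "islet_coordinated",
    "benchmark_complexes",
    "mwu_compare",
]

DEFAULT_ISLET_COMPONENTS = ("whole_islet", "beta", "non_beta")


@dataclass
class ExpressionPanel:
    """Gene x sample expression matrix (RPKM-like) with a sample->tissue map."""

    values: pd.DataFrame  # genes x samples, non-negative
    sample_tissue: pd.Series  # index: sample id, value: tissue label

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.sample_tissue.index)
        if missing:
            raise ValueError(f"samples without a tissue label: {sorted(missing)[:5]}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissue.unique())

    def samples_of(self, tissue: str) -> list[str]:
        s = self.sample_tissue[self.sample_tissue == tissue].index
        return [c for c in self.values.columns if c in set(s)]

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        cols = self.samples_of(tissue)
        if len(cols) < 3:
            raise ValueError(f"tissue {tissue!r} has fewer than 3 samples")
        return self.values[cols]


def pairwise_pcc(x: str, y: str, panel: ExpressionPanel, tissue: str) -> float:
    """Pearson correlation of two genes over one tissue's samples.

    Returns NaN (the undefined sentinel) when either vector has zero
    variance.
    """
    mat = panel.tissue_matrix(tissue)
    for g in (x, y):
        if g not in mat.index:
            raise KeyError(f"gene {g!r} not in expression panel")
    xv = mat.loc[x].to_numpy(dtype=float)
    yv = mat.loc[y].to_numpy(dtype=float)
    if np.std(xv) == 0.0 or np.std(yv) == 0.0:
        return math.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def complex_pcc_mean(members, net: nx.Graph, panel: ExpressionPanel, tissue: str) -> float:
    """Edge-restricted mean pairwise PCC of a complex in one tissue.

    Only pairs joined by a network edge enter the mean; undefined pairs are
    dropped with the effective edge count reduced. Returns NaN if no edge
    has a defined correlation.
    """
    mset = [g for g in members if g in panel.values.index]
    edges = [(a, b) for a, b in net.subgraph(mset).edges()]
    if not edges:
        return math.nan
    mat = panel.tissue_matrix(tissue)
    sub = mat.loc[sorted(set(g for e in edges for g in e))].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(sorted(set(g for e in edges for g in e)))}
    sd = sub.std(axis=1)
    centered = sub - sub.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    total, n_def = 0.0, 0
    for a, b in edges:
        ia, ib = idx[a], idx[b]
        if sd[ia] == 0.0 or sd[ib] == 0.0:
            continue
        r = float(centered[ia] @ centered[ib] / (denom[ia] * denom[ib]))
        total += r
        n_def += 1
    if n_def == 0:
        return math.nan
    return total / n_def


def fisher_z(r: float, r_clamp: float = 1.0 - 1e-6) -> float:
    """Fisher transformation ``0.5 * ln((1+r)/(1-r))`` with clamping at |r|=r_clamp."""
    if math.isnan(r):
        return math.nan
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    r = max(-r_clamp, min(r_clamp, r))
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


@dataclass
class CEMatrix:
    """Raw, Fisher-transformed and standardized CE values (complex x tissue)."""

    pcc_mean: pd.DataFrame
    z: pd.DataFrame
    ce: pd.DataFrame
    mu: pd.Series = field(default=None)
    sigma: pd.Series = field(default=None)


def standardize_ce(z: pd.DataFrame) -> CEMatrix:
    """Standardize Fisher-z values within each tissue across complexes.

    ``mu_t`` and ``sigma_t`` are the sample mean and sd (ddof=1) over all
    complexes with a defined z in tissue ``t``; NaN entries propagate.
    """
    mu = z.mean(axis=0, skipna=True)
    sigma = z.std(axis=0, ddof=1, skipna=True)
    n_def = z.notna().sum(axis=0)
    if (n_def < 2).any():
        bad = list(n_def.index[n_def < 2])
        raise ValueError(f"tissues with fewer than 2 defined z values: {bad}")
    if (sigma == 0).any():
        bad = list(sigma.index[sigma == 0])
        raise ValueError(f"degenerate (zero-sd) z column for tissues: {bad}")
    ce = (z - mu) / sigma
    return CEMatrix(pcc_mean=None, z=z, ce=ce, mu=mu, sigma=sigma)


def ce_matrix(catalog, net: nx.Graph, panel: ExpressionPanel) -> CEMatrix:
    """Compute PCC.mean, Fisher z and standardized CE for a whole catalog."""
    tissues = panel.tissues
    rows = {}
    for c in catalog:
        rows[c.id] = {t: complex_pcc_mean(c.members, net, panel, t) for t in tissues}
    pcc = pd.DataFrame.from_dict(rows, orient="index")[tissues]
    z = pcc.applymap(fisher_z) if hasattr(pcc, "applymap") else pcc.map(fisher_z)
    out = standardize_ce(z)
    out.pcc_mean = pcc
    return out


def islet_coordinated(
    ce: pd.DataFrame,
    islet_components=DEFAULT_ISLET_COMPONENTS,
    top_k: int = 3,
) -> set[str]:
    """Complexes for which an islet component ranks in the CE top ``k`` tissues.

    Ranking is descending competition ("min") ranking, so exact ties share
    the best rank; an all-tied complex ranks every tissue first and is
    therefore called.
    """
    missing = [t for t in islet_components if t not in ce.columns]
    if missing:
        raise ValueError(f"islet components missing from CE matrix: {missing}")
    if ce.shape[1] < top_k:
        raise ValueError(f"need at least top_k={top_k} tissues, have {ce.shape[1]}")
    ranks = ce.rank(axis=1, method="min", ascending=False, na_option="bottom")
    called = (ranks[list(islet_components)] <= top_k).any(axis=1)
    return set(called.index[called])


def benchmark_complexes(catalog, curated_genes, min_fraction: float = 0.10) -> set[str]:
    """Complexes whose membership is at least ``min_fraction`` curated genes."""
    curated = set(curated_genes)
    if not curated:
        raise ValueError("curated gene set is empty")
    out = set()
    for c in catalog:
        if len(c.members & curated) / len(c.members) >= min_fraction:
            out.add(c.id)
    return out


def mwu_compare(values_a, values_b, alternative: str = "greater") -> float:
    """One-sided Mann-Whitney U p-value (exact for small untied samples)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method="auto").pvalue)
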