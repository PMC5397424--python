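import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isletnet.complexes import ComplexCatalog, ProteinComplex
from isletnet.convergence import (
    GeneSetCollection,
    NullCache,
    bh_adjust,
    consensus_genes,
    convergence_scan,
    direct_overlap_matrix,
    empirical_p,
    fishers_combined,
    hypergeom_enrichment,
)


def hypergeom_tail_oracle(hits, set_size, complex_size, background):
    """Brute-force upper tail from the counting definition."""
    total = math.comb(background, complex_size)
    acc = 0
    for i in range(hits, min(set_size, complex_size) + 1):
        acc += math.comb(set_size, i) * math.comb(background - set_size, complex_size - i)
    return acc / total


def chi2_sf_even_dof(x, dof):
    """Closed-form chi-square survival for even dof: exp(-x/2) * sum (x/2)^i / i!."""
    k = dof // 2
    term, acc = 1.0, 1.0
    for i in range(1, k):
        term *= (x / 2) / i
        acc += term
    return math.exp(-x / 2) * acc


def bh_oracle(pvals):
    """Independent step-up implementation."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestHypergeomEnrichment:
    def test_zero_hits_is_one(self):
        assert hypergeom_enrichment(0, 5, 5, 100) == 1.0

    def test_single_favorable_configuration(self):
        assert hypergeom_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_enumeration_for_small_backgrounds(self):
        for background in range(2, 21):
            for set_size in range(1, background + 1):
                for complex_size in range(1, background + 1):
                    for hits in range(0, min(set_size, complex_size) + 1):
                        got = hypergeom_enrichment(hits, set_size, complex_size, background)
                        want = hypergeom_tail_oracle(hits, set_size, complex_size, background)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 5, 5, 100)
        with pytest.raises(ValueError):
            hypergeom_enrichment(1, 50, 5, 10)


class TestFishersCombined:
    def test_all_ones(self):
        stat, p = fishers_combined([1.0, 1.0, 1.0])
        assert stat == 0.0 and p == 1.0

    def test_single_p_identity(self):
        for p in (0.01, 0.3, 0.9):
            assert fishers_combined([p])[1] == pytest.approx(p, rel=1e-9)

    def test_thirteen_halves_closed_form(self):
        stat, p = fishers_combined([0.5] * 13)
        assert stat == pytest.approx(26 * math.log(2), rel=1e-12)
        assert p == pytest.approx(chi2_sf_even_dof(stat, 26), rel=1e-9)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fishers_combined([0.0, 0.5])


class TestBhAdjust:
    def test_step_up_closed_form(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_matches_independent_oracle(self, rng):
        p = rng.uniform(size=50)
        assert bh_adjust(p).tolist() == pytest.approx(bh_oracle(p), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_monotone(self, pvals):
        # adjusted values never fall below the raw ones, and the adjustment
        # preserves the significance ordering (BH is not idempotent: e.g.
        # [0.25, 1.0] -> [0.5, 1.0] -> [1.0, 1.0])
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestEmpiricalP:
    def test_count_formula(self):
        null = np.concatenate([np.full(5, 1e-8), np.full(99_995, 0.5)])
        assert empirical_p(1e-6, null) == pytest.approx(5e-5)

    def test_observed_at_or_above_max_is_one(self):
        assert empirical_p(0.9, np.linspace(0.01, 0.9, 100)) == 1.0

    def test_paper_faithful_zero_and_pseudo_count(self):
        null = np.linspace(0.1, 0.9, 99)
        assert empirical_p(0.01, null) == 0.0
        assert empirical_p(0.01, null, pseudo_count=True) == pytest.approx(1 / 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_monotone_in_observed(self, a, b):
        null = np.linspace(0.0, 1.0, 101)
        lo, hi = sorted((a, b))
        assert empirical_p(lo, null) <= empirical_p(hi, null)


def two_sets_collection():
    return GeneSetCollection(
        sets={
            "s1": frozenset(f"g{i}" for i in range(0, 8)),
            "s2": frozenset(f"g{i}" for i in range(5, 15)),
        }
    )


class TestEmpiricalNull:
    def test_same_seed_reproducible(self):
        genes = [f"g{i}" for i in range(30)]
        sets = two_sets_collection()
        a = NullCache(genes, sets, n_samples=500, seed=3).null_for_size(6)
        b = NullCache(genes, sets, n_samples=500, seed=3).null_for_size(6)
        assert np.array_equal(a, b)

    def test_support_in_unit_interval(self):
        genes = [f"g{i}" for i in range(30)]
        null = NullCache(genes, two_sets_collection(), n_samples=500, seed=1).null_for_size(5)
        assert np.all(null > 0) and np.all(null <= 1)

    def test_matches_direct_gene_sampling_oracle(self):
        # The atom-based sampler must be distribution-identical to literally
        # drawing gene sets and scoring them one at a time.
        genes = [f"g{i}" for i in range(30)]
        sets = two_sets_collection()
        size, n, seed = 7, 4000, 9
        fast = NullCache(genes, sets, n_samples=n, seed=seed).null_for_size(size)
        rng = np.random.default_rng(7)
        direct = []
        for _ in range(n):
            draw = frozenset(rng.choice(genes, size=size, replace=False))
            pv = [
                hypergeom_enrichment(len(draw & s), len(s), size, len(genes))
                for _, s in sets
            ]
            direct.append(fishers_combined(pv)[1])
        # the two paths compute identical discrete distributions whose atoms
        # can differ in the last float ulps; round before comparing so the
        # KS statistic sees shared atoms, not displaced ones
        ks = stats.ks_2samp(np.round(fast, 8), np.round(direct, 8))
        assert ks.pvalue > 0.01


class TestConvergenceScan:
    def small_world(self):
        genes = [f"g{i}" for i in range(40)]
        catalog = ComplexCatalog(
            [
                ProteinComplex("hit", frozenset(genes[:8]), "x"),
                ProteinComplex("miss", frozenset(genes[30:38]), "x"),
            ]
        )
        sets = GeneSetCollection(
            sets={
                "s1": frozenset(genes[:6] + genes[20:24]),
                "s2": frozenset(genes[2:8] + genes[25:28]),
                "s3": frozenset(genes[38:40] + ["not_in_network"]),
            }
        )
        return genes, catalog, sets

    def test_disjoint_complex_has_unit_combined_p(self):
        genes, catalog, sets = self.small_world()
        res = convergence_scan(catalog, sets, genes, n_samples=300, seed=1)
        miss = next(r for r in res if r.complex_id == "miss")
        assert all(v == 1.0 for k, v in miss.per_set_p.items() if k in ("s1", "s2"))

    def test_planted_overlap_detected(self):
        genes, catalog, sets = self.small_world()
        res = convergence_scan(catalog, sets, genes, n_samples=2000, seed=1)
        hit = next(r for r in res if r.complex_id == "hit")
        miss = next(r for r in res if r.complex_id == "miss")
        assert hit.p_combined < 1e-4
        assert hit.p_emp < miss.p_emp

    def test_bh_adjustment_applied_across_complexes(self):
        genes, catalog, sets = self.small_world()
        res = convergence_scan(catalog, sets, genes, n_samples=300, seed=1)
        want = bh_adjust([r.p_emp for r in res])
        assert [r.p_emp_adj for r in res] == pytest.approx(list(want))

    def test_set_outside_network_contributes_unit_p(self):
        genes, catalog, sets = self.small_world()
        res = convergence_scan(catalog, sets, genes[:38], n_samples=300, seed=1)
        assert all(r.per_set_p["s3"] == 1.0 for r in res)


class TestDirectOverlap:
    def test_identical_sets_full_overlap(self):
        sets = GeneSetCollection(sets={"a": frozenset("xyz"), "b": frozenset("xyz")})
        count, percent, padj = direct_overlap_matrix(sets, genome_background=100)
        assert count.loc["a", "b"] == 3
        assert percent.loc["a", "b"] == 100.0

    def test_disjoint_sets(self):
        sets = GeneSetCollection(sets={"a": frozenset("xyz"), "b": frozenset("uvw")})
        count, percent, padj = direct_overlap_matrix(sets, genome_background=100)
        assert count.loc["a", "b"] == 0
        assert percent.loc["a", "b"] == 0.0
        assert padj.loc["a", "b"] == 1.0

    def test_percent_relative_to_smaller_set(self):
        a = frozenset(f"g{i}" for i in range(50))
        b = frozenset(f"g{i}" for i in range(35, 65))  # |b|=30, overlap 15
        sets = GeneSetCollection(sets={"a": a, "b": b})
        _, percent, _ = direct_overlap_matrix(sets, genome_background=1000)
        assert percent.loc["a", "b"] == pytest.approx(50.0)

    def test_set_larger_than_background_rejected(self):
        sets = GeneSetCollection(sets={"a": frozenset("abc"), "b": frozenset("xy")})
        with pytest.raises(ValueError):
            direct_overlap_matrix(sets, genome_background=2)


class TestConsensusGenes:
    def collection(self):
        sets = {f"s{i}": frozenset({"always", f"unique{i}"} | ({"often"} if i < 3 else set())) for i in range(13)}
        return GeneSetCollection(sets=sets)

    def test_boundary_at_min_sets(self):
        got = consensus_genes(self.collection(), min_sets=4)
        assert "always" in got
        assert "often" not in got  # only 3 sets

    def test_min_one_gives_union(self):
        coll = self.collection()
        assert consensus_genes(coll, min_sets=1) == coll.union()
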