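import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import isletnet as I
from isletnet.network import consolidate_presence, node_removal
from isletnet.synthetic import GeneratorConfig, demo_config


def small_cfg(**kw):
    base = dict(
        n_genes=300, n_planted=5, size_range=(6, 12), n_enriched=2,
        samples_per_tissue=5, n_hubs=10, set_size_range=(15, 25), seed=1,
    )
    base.update(kw)
    return demo_config(**base)


class TestConfigValidation:
    def test_r_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(planted_pairwise_r=1.0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(background_edge_prob=1.5)

    def test_size_range_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            I.generate_network(GeneratorConfig(n_genes=50, n_planted=10, size_range=(20, 30)))


class TestGenerateNetwork:
    def test_fixed_seed_determinism(self):
        cfg = small_cfg()
        n1, t1 = I.generate_network(cfg)
        n2, t2 = I.generate_network(cfg)
        assert sorted(n1.edges(data="weight")) == sorted(n2.edges(data="weight"))
        assert t1.planted_complexes == t2.planted_complexes

    def test_full_within_probability_gives_cliques(self):
        cfg = small_cfg(within_complex_edge_prob=1.0)
        net, truth = I.generate_network(cfg)
        for members in truth.planted_complexes:
            sub = net.subgraph(members)
            k = len(members)
            assert sub.number_of_edges() == k * (k - 1) // 2

    def test_pure_single_clique_edge_count(self):
        cfg = small_cfg(
            n_genes=50, n_planted=1, size_range=(6, 6), background_edge_prob=0.0,
            within_complex_edge_prob=1.0, n_hubs=0,
        )
        net, truth = I.generate_network(cfg)
        assert net.number_of_edges() == 15  # C(6,2)

    def test_invariants(self):
        net, truth = I.generate_network(small_cfg())
        assert all(0 < w <= 1 for _, _, w in net.edges(data="weight"))
        assert not any(net.has_edge(v, v) for v in net.nodes)
        for members in truth.planted_complexes:
            assert 6 <= len(members) <= 50


class TestGenerateExpression:
    def test_zero_r_gives_uncorrelated_members(self):
        cfg = small_cfg(planted_pairwise_r=0.0, samples_per_tissue=50, n_tissues=4)
        net, truth = I.generate_network(cfg)
        panel = I.generate_expression(net, truth, cfg)
        members = sorted(truth.planted_complexes[0])[:8]
        tissue = truth.coordinated_tissue_of_complex[0]
        mat = panel.tissue_matrix(tissue).loc[members].to_numpy()
        corr = np.corrcoef(mat)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert abs(off.mean()) < 0.05

    def test_planted_r_recovered(self):
        cfg = small_cfg(planted_pairwise_r=0.9, samples_per_tissue=100, n_tissues=4)
        net, truth = I.generate_network(cfg)
        panel = I.generate_expression(net, truth, cfg)
        members = sorted(truth.planted_complexes[0])
        tissue = truth.coordinated_tissue_of_complex[0]
        mat = panel.tissue_matrix(tissue).loc[members].to_numpy()
        corr = np.corrcoef(mat)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert 0.8 <= off.mean() <= 0.95

    def test_other_tissue_uncorrelated(self):
        cfg = small_cfg(planted_pairwise_r=0.9, samples_per_tissue=100, n_tissues=4)
        net, truth = I.generate_network(cfg)
        panel = I.generate_expression(net, truth, cfg)
        members = sorted(truth.planted_complexes[0])
        other = next(
            t for t in panel.tissues if t != truth.coordinated_tissue_of_complex[0]
        )
        mat = panel.tissue_matrix(other).loc[members].to_numpy()
        off = np.corrcoef(mat)[np.triu_indices(len(members), k=1)]
        assert abs(off.mean()) < 0.1

    def test_deterministic_and_nonnegative(self):
        cfg = small_cfg()
        net, truth = I.generate_network(cfg)
        a = I.generate_expression(net, truth, cfg)
        b = I.generate_expression(net, truth, cfg)
        assert a.values.equals(b.values)
        assert (a.values.to_numpy() >= 0).all()


class TestPresenceEvidence:
    def test_zero_absent_fraction_leaves_network_unchanged(self):
        cfg = small_cfg(fraction_absent=0.0)
        net, _ = I.generate_network(cfg)
        presence = I.generate_presence_evidence(net, cfg)
        call = consolidate_presence(presence, net.nodes)
        pruned = node_removal(net, call)
        # the per-dataset noise never produces absent-in-all by construction
        assert pruned.number_of_nodes() >= 0.97 * net.number_of_nodes()

    def test_fully_uncovered_keeps_every_gene(self):
        cfg = small_cfg(fraction_absent=0.0, fraction_uncertain=0.0, fraction_uncovered=1.0)
        net, _ = I.generate_network(cfg)
        presence = I.generate_presence_evidence(net, cfg)
        assert set(presence["status"]) == {"uncovered"}
        call = consolidate_presence(presence, net.nodes)
        assert node_removal(net, call).number_of_nodes() == net.number_of_nodes()

    def test_absent_fraction_prunes(self):
        cfg = small_cfg(fraction_absent=0.3)
        net, _ = I.generate_network(cfg)
        call = consolidate_presence(I.generate_presence_evidence(net, cfg), net.nodes)
        kept = node_removal(net, call).number_of_nodes() / net.number_of_nodes()
        assert 0.6 < kept < 0.8

    def test_deterministic(self):
        cfg = small_cfg()
        net, _ = I.generate_network(cfg)
        assert I.generate_presence_evidence(net, cfg).equals(
            I.generate_presence_evidence(net, cfg)
        )


class TestGenerateGeneSets:
    def test_supporting_sets_contain_planted_fraction(self):
        cfg = small_cfg(n_genes=800, n_planted=3, size_range=(20, 20), n_enriched=1,
                        planted_set_fraction=0.3, set_size_range=(30, 40))
        net, truth = I.generate_network(cfg)
        sets = I.generate_gene_sets(truth, cfg)
        complex0 = truth.planted_complexes[0]
        supporting = [
            name for name, s in sets if len(s & complex0) >= math.ceil(0.3 * 20)
        ]
        assert len(supporting) >= 4

    def test_zero_fraction_gives_null_collection(self):
        cfg = small_cfg(planted_set_fraction=0.0)
        net, truth = I.generate_network(cfg)
        sets = I.generate_gene_sets(truth, cfg)
        planted_union = set().union(*truth.planted_complexes)
        for _, s in sets:
            assert not (s & planted_union)

    def test_truth_records_per_set_planted_genes(self):
        cfg = small_cfg()
        net, truth = I.generate_network(cfg)
        sets = I.generate_gene_sets(truth, cfg)
        for name, planted in truth.set_planted_genes.items():
            if name in sets.sets:
                assert planted <= sets.sets[name]

    def test_deterministic(self):
        cfg = small_cfg()
        net, truth1 = I.generate_network(cfg)
        s1 = I.generate_gene_sets(truth1, cfg)
        net, truth2 = I.generate_network(cfg)
        s2 = I.generate_gene_sets(truth2, cfg)
        assert s1.sets == s2.sets


class TestGenerateGwas:
    def test_null_min_p_matches_order_statistic(self):
        # gene-level min of n uniforms has CDF 1 - (1-p)^n
        cfg = demo_config(seed=42, n_genes=2000, n_planted=5, n_enriched=0, n_snps_per_gene=10)
        net, truth = I.generate_network(cfg)
        coords, snps = I.generate_gwas(truth, cfg)
        assert not truth.causal_genes
        minp = snps.assign(gene=[s.split("_")[0] for s in snps["snp"]]).groupby("gene")["p"].min()
        transformed = 1 - (1 - minp.to_numpy()) ** cfg.n_snps_per_gene
        assert stats.kstest(transformed, "uniform").pvalue > 0.01

    def test_single_null_snp_is_uniform(self):
        cfg = demo_config(seed=4, n_genes=1500, n_planted=5, n_enriched=0, n_snps_per_gene=1)
        net, truth = I.generate_network(cfg)
        _, snps = I.generate_gwas(truth, cfg)
        assert stats.kstest(snps["p"].to_numpy(), "uniform").pvalue > 0.01

    def test_causal_genes_stochastically_smaller(self):
        cfg = small_cfg(n_enriched=2)
        net, truth = I.generate_network(cfg)
        _, snps = I.generate_gwas(truth, cfg)
        gene_of = {f"rs{i:04d}": g for i, g in enumerate(cfg.genes)}
        snps = snps.assign(gene=[gene_of[s.rsplit("_", 1)[0]] for s in snps["snp"]])
        causal = snps[snps["gene"].isin(truth.causal_genes)]["p"]
        null = snps[~snps["gene"].isin(truth.causal_genes)]["p"]
        assert causal.median() < 0.1 < null.median()

    def test_windows_never_collide(self):
        cfg = small_cfg()
        net, truth = I.generate_network(cfg)
        coords, _ = I.generate_gwas(truth, cfg)
        ordered = coords.sort_values("start")
        gap = ordered["start"].to_numpy()[1:] - ordered["end"].to_numpy()[:-1]
        assert (gap >= 150_000).all()

    def test_deterministic(self):
        cfg = small_cfg()
        net, truth = I.generate_network(cfg)
        c1, s1 = I.generate_gwas(truth, cfg)
        c2, s2 = I.generate_gwas(truth, cfg)
        assert c1.equals(c2) and s1.equals(s2)


def test_truth_invariants_enforced():
    with pytest.raises(ValueError):
        I.SyntheticTruth(planted_complexes=[frozenset({"a", "b"})])
    with pytest.raises(ValueError):
        I.SyntheticTruth(
            planted_complexes=[frozenset(f"g{i}" for i in range(6))],
            enriched_complexes={3},
        )
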