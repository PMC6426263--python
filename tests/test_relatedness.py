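import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sweepscan.allele_stats import FreqTable, haplotype_freq
from sweepscan.errors import EstimationError
from sweepscan.relatedness import (KinshipTable, build_family_network,
                                   estimate_kinship, ibd_probabilities,
                                   inbreeding_f, prune_related)
from sweepscan.synthetic_data import (RelativesSpec, default_config,
                                      simulate_dataset)
from sweepscan.variant_io import GenotypeSet, PopulationMap


def _panel(rng, n_ind=30, n_snps=3000):
    freqs = rng.uniform(0.2, 0.8, n_snps)
    alleles = (rng.random((2 * n_ind, n_snps)) < freqs).astype(np.int8)
    d = alleles[0::2] + alleles[1::2]
    genos = GenotypeSet(d, [f"s{i}" for i in range(n_ind)])
    p = d.sum(axis=0) / (2 * n_ind)
    ft = FreqTable("P", p, np.full(n_snps, 2 * n_ind, dtype=np.int64))
    return genos, ft


class TestIbdProbabilities:
    def test_self_pair_is_almost_surely_ibd2(self, rng):
        genos, ft = _panel(rng)
        d = np.vstack([genos.dosages, genos.dosages[0:1]])
        genos2 = GenotypeSet(d, genos.samples + ["dup"])
        p0, p1, p2 = ibd_probabilities(genos2, ft, (0, 30), min_sites=200)
        assert p2 > 0.95
        phi = p1 / 4 + p2 / 2
        assert phi == pytest.approx(0.5, abs=0.02)

    def test_unrelated_pair_small_phi(self, rng):
        genos, ft = _panel(rng)
        p0, p1, p2 = ibd_probabilities(genos, ft, (0, 1), min_sites=200)
        assert p1 / 4 + p2 / 2 < 0.05

    def test_parent_offspring_ibd1(self, related_dataset):
        ds = related_dataset
        genos = ds.haplotypes.to_genotypes()
        ft = haplotype_freq(ds.haplotypes, ds.popmap, "pop1")
        pair = next(t for t in ds.truth["relatives"]
                    if t["relationship"] == "parent_offspring")
        i = genos.samples.index(pair["pair"][0])
        j = genos.samples.index(pair["pair"][1])
        p0, p1, p2 = ibd_probabilities(genos, ft, (i, j), min_sites=200)
        assert p1 > 0.9
        assert 0.2 <= p1 / 4 + p2 / 2 <= 0.3

    def test_too_few_sites_raises(self, rng):
        genos, ft = _panel(rng, n_snps=100)
        with pytest.raises(EstimationError):
            ibd_probabilities(genos, ft, (0, 1), min_sites=200)

    def test_invariant_to_allele_label_swap(self, rng):
        genos, ft = _panel(rng)
        a = ibd_probabilities(genos, ft, (2, 5), min_sites=200)
        flipped = GenotypeSet(2 - genos.dosages, genos.samples)
        ft2 = FreqTable("P", 1 - ft.p, ft.n)
        b = ibd_probabilities(flipped, ft2, (2, 5), min_sites=200)
        assert a == pytest.approx(b, abs=1e-9)


class TestInbreeding:
    def test_fully_heterozygous_individual_negative_f(self):
        n_snps = 500
        d = np.ones((4, n_snps), dtype=np.int8)
        d[1:] = np.tile([0, 2], (3, n_snps // 2))
        genos = GenotypeSet(d, ["het", "a", "b", "c"])
        ft = FreqTable("P", np.full(n_snps, 0.5), np.full(n_snps, 8, dtype=np.int64))
        assert inbreeding_f(genos, ft, 0) < 0

    def test_selfed_offspring_f_near_half(self, rng):
        n_ind, n_snps = 40, 8000
        freqs = rng.uniform(0.2, 0.8, n_snps)
        alleles = (rng.random((2 * n_ind, n_snps)) < freqs).astype(np.int8)
        # selfed child of individual 0: both gametes drawn from its two haplotypes
        g1 = np.where(rng.random(n_snps) < 0.5, alleles[0], alleles[1])
        g2 = np.where(rng.random(n_snps) < 0.5, alleles[0], alleles[1])
        d = np.vstack([alleles[0::2] + alleles[1::2], (g1 + g2)[None, :]])
        genos = GenotypeSet(d, [f"s{i}" for i in range(n_ind)] + ["selfed"])
        p = d[:-1].sum(axis=0) / (2 * n_ind)
        ft = FreqTable("P", p, np.full(n_snps, 2 * n_ind, dtype=np.int64))
        assert inbreeding_f(genos, ft, n_ind) == pytest.approx(0.5, abs=0.06)

    def test_random_panmictic_individual_f_near_zero(self, rng):
        genos, ft = _panel(rng, n_snps=5000)
        assert abs(inbreeding_f(genos, ft, 3)) < 0.05


def _kin_table(pairs):
    rows = [{"id1": a, "id2": b, "P0": 0.0, "P1": 0.0, "P2": 0.0,
             "PI_HAT": 2 * phi, "phi": phi} for a, b, phi in pairs]
    return KinshipTable(pd.DataFrame(rows), pd.DataFrame({"id": [], "F": []}))


class TestFamilyNetwork:
    def test_second_degree_connects_third_degree_does_not_at_default(self):
        kin = _kin_table([("a", "b", 0.125), ("c", "d", 0.0625)])
        g = build_family_network(kin, threshold=0.1)
        assert g.has_edge("a", "b") and not g.has_edge("c", "d")

    def test_lower_threshold_admits_third_degree(self):
        kin = _kin_table([("a", "b", 0.125), ("c", "d", 0.0625)])
        g06 = build_family_network(kin, threshold=0.06)
        g10 = build_family_network(kin, threshold=0.1)
        assert g06.number_of_edges() > g10.number_of_edges()

    def test_zero_kinship_gives_edgeless_network(self):
        g = build_family_network(_kin_table([("a", "b", 0.0)]), 0.1)
        assert g.number_of_edges() == 0

    def test_display_filter_uses_pi_hat(self):
        kin = _kin_table([("a", "b", 0.2), ("c", "d", 0.01)])
        assert len(kin.display_pairs(0.05)) == 1


class TestPruneRelated:
    def test_edgeless_network_removes_nobody(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert prune_related(g) == []

    def test_star_removes_only_the_hub(self):
        g = nx.Graph()
        for leaf in "bcd":
            g.add_edge("a", leaf, phi=0.25)
        assert prune_related(g) == ["a"]

    def test_tie_broken_by_phi_sum_then_id(self):
        g = nx.Graph()
        g.add_edge("b", "x", phi=0.3)
        g.add_edge("a", "y", phi=0.2)
        # degrees equal; 'b' has larger incident phi and goes first
        assert prune_related(g)[0] == "b"

    def test_random_graphs_end_edgeless_with_no_overremoval(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            nx.set_edge_attributes(g, 0.25, "phi")
            removed = prune_related(g)
            h = g.copy()
            h.remove_nodes_from(removed)
            assert h.number_of_edges() == 0
            assert len(removed) <= g.number_of_edges()

    def test_exhaustive_four_node_graphs_leave_no_edges(self):
        import itertools
        nodes = list("abcd")
        all_edges = list(itertools.combinations(nodes, 2))
        for mask in range(1 << len(all_edges)):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for k, e in enumerate(all_edges):
                if mask >> k & 1:
                    g.add_edge(*e, phi=0.25)
            removed = prune_related(g)
            g.remove_nodes_from(removed)
            assert g.number_of_edges() == 0


def test_pedigree_rank_order_po_and_sibs_above_half_sibs():
    cfg = default_config("related", seed=11)
    cfg.relatives = [RelativesSpec("parent_offspring", 3),
                     RelativesSpec("full_sibs", 3),
                     RelativesSpec("half_sibs", 3)]
    ds = simulate_dataset(cfg)
    genos = ds.haplotypes.to_genotypes()
    ft = haplotype_freq(ds.haplotypes, ds.popmap, "pop1")
    means = {}
    for rel in ("parent_offspring", "full_sibs", "half_sibs"):
        phis = []
        for t in ds.truth["relatives"]:
            if t["relationship"] != rel:
                continue
            i = genos.samples.index(t["pair"][0])
            j = genos.samples.index(t["pair"][1])
            p0, p1, p2 = ibd_probabilities(genos, ft, (i, j), min_sites=200)
            phis.append(p1 / 4 + p2 / 2)
        means[rel] = np.mean(phis)
    assert means["parent_offspring"] == pytest.approx(0.25, abs=0.03)
    assert means["full_sibs"] == pytest.approx(0.25, abs=0.04)
    assert means["half_sibs"] == pytest.approx(0.125, abs=0.04)
    assert means["half_sibs"] < min(means["parent_offspring"], means["full_sibs"])


def test_full_sibs_show_ibd2(related_dataset):
    ds = related_dataset
    genos = ds.haplotypes.to_genotypes()
    ft = haplotype_freq(ds.haplotypes, ds.popmap, "pop1")
    sib = next(t for t in ds.truth["relatives"] if t["relationship"] == "full_sibs")
    i = genos.samples.index(sib["pair"][0])
    j = genos.samples.index(sib["pair"][1])
    p0, p1, p2 = ibd_probabilities(genos, ft, (i, j), min_sites=200)
    assert p2 > 0.1
    assert p1 / 4 + p2 / 2 == pytest.approx(0.25, abs=0.05)


def test_estimate_kinship_bundles_pairs_and_inbreeding(rng):
    genos, ft = _panel(rng, n_ind=8)
    kin = estimate_kinship(genos, ft, min_sites=200)
    assert len(kin.pairs) == 8 * 7 // 2
    assert len(kin.inbreeding) == 8
    assert (kin.pairs["phi"] < 0.1).all()
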