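"""Enrichment, cross-talk graph, R-score and hub-gene behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

import rewirenet as rn
from rewirenet.pathways import r_score

from conftest import make_network, random_adjacency
from oracles import (components_oracle, fisher_greater_oracle,
                     hypergeom_tail_oracle)


def _collection(sets, universe):
    return rn.GeneSetCollection(dict(sets), list(universe))


class TestEnrichment:
    def test_set_equal_to_query_is_most_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        zeta = set(universe[:10])
        coll = _collection({"HIT": universe[:10], "MISS": universe[50:60]}, universe)
        table = rn.enrich(zeta, coll).set_index("pathway")
        assert table.loc["HIT", "enriched"]
        assert table.loc["HIT", "enrich_p"] < 1e-10
        assert not table.loc["MISS", "enriched"]

    def test_hypergeometric_tail_matches_exact_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        zeta = set(universe[:10])
        members = universe[5:15]  # overlap 5
        coll = _collection({"S": members}, universe)
        p = rn.enrich(zeta, coll)["enrich_p"].iloc[0]
        assert p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10), rel=1e-10)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            u = int(rng.integers(20, 61))
            universe = [f"g{i}" for i in range(u)]
            set_size = int(rng.integers(1, 15))
            draws = int(rng.integers(1, 15))
            members = list(rng.choice(universe, size=set_size, replace=False))
            zeta = set(rng.choice(universe, size=draws, replace=False))
            coll = _collection({"S": members}, universe)
            p = rn.enrich(zeta, coll)["enrich_p"].iloc[0]
            overlap = len(set(members) & zeta)
            assert p == pytest.approx(
                hypergeom_tail_oracle(overlap, u, set_size, draws), rel=1e-9)

    def test_empty_overlap_with_universe_rejected(self):
        coll = _collection({"S": ["a"]}, ["a", "b"])
        with pytest.raises(ValueError):
            rn.enrich({"zzz"}, coll)


class TestCrosstalk:
    def test_identical_sets_connected(self):
        universe = [f"g{i}" for i in range(50)]
        graph = rn.pathway_connectivity({"A": universe[:10], "B": universe[:10]},
                                        universe)
        assert len(graph.edges) == 1
        assert graph.pc("A") == 1 and graph.pc("B") == 1

    def test_disjoint_sets_not_connected(self):
        universe = [f"g{i}" for i in range(1000)]
        graph = rn.pathway_connectivity({"A": universe[:10], "B": universe[10:20]},
                                        universe)
        assert len(graph.edges) == 0

    def test_fisher_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            u = int(rng.integers(20, 61))
            universe = [f"g{i}" for i in range(u)]
            na, nb = int(rng.integers(2, 16)), int(rng.integers(2, 16))
            a = list(rng.choice(universe, size=na, replace=False))
            b = list(rng.choice(universe, size=nb, replace=False))
            graph = rn.pathway_connectivity({"A": a, "B": b}, universe)
            shared = len(set(a) & set(b))
            expected = fisher_greater_oracle(shared, na, nb, u)
            got = graph.pairs.set_index(["pathway_a", "pathway_b"]).loc[("A", "B"), "fisher_p"]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_crosstalk_frequency_conservation(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {"S1": universe[:12], "S2": universe[6:18], "S3": universe[10:22]}
        graph = rn.pathway_connectivity(sets, universe, fisher_alpha=1.1)
        cf = rn.crosstalk_frequency(graph, signalling_only=False)
        assert cf.sum() == sum(len(s) for s in sets.values())

    def test_signalling_tagging(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {"WNT signalling": universe[:12], "Cell cycle": universe[6:18]}
        coll = _collection(sets, universe)
        assert coll.signalling_names() == {"WNT signalling"}
        assert coll.signalling_names(tags=["Cell cycle"]) == {"Cell cycle"}

    def test_ipc_components_match_union_find_oracle(self):
        universe = [f"g{i}" for i in range(200)]
        # chain A-B-C with strong overlaps, D isolated
        sets = {"A": universe[0:15], "B": universe[7:22], "C": universe[14:29],
                "D": universe[100:115]}
        graph = rn.pathway_connectivity(sets, universe)
        ipc = rn.ipc_clusters(graph)
        got = [set(p.split(";")) for p in ipc["pathways"]]
        edges = list(zip(graph.edges["pathway_a"], graph.edges["pathway_b"]))
        expected = components_oracle(list(sets), edges)
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
        assert {"A", "B", "C"} in got and {"D"} in got


class TestSubnetworkProperties:
    def test_clique_values(self):
        adj = ~np.eye(6, dtype=bool)
        net = make_network(adj)
        empty = make_network(np.zeros((6, 6), dtype=bool), genes=net.genes)
        props = rn.pathway_subnetwork_properties(net.genes, net, empty)
        assert props["delta_d"] == 1.0 and props["phi_d"] == 5.0
        assert props["im_clustering"] == 1.0 and props["filter_pass"]
        assert props["delta_c"] == 0.0 and props["phi_c"] == 0.0

    def test_tiny_pathway_fails_filter(self):
        net = make_network(~np.eye(4, dtype=bool))
        props = rn.pathway_subnetwork_properties(net.genes[:1], net, net)
        assert props["filter_pass"] is False
        assert props["phi_d"] == 0.0

    def test_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            n = int(rng.integers(6, 14))
            adj = random_adjacency(rng, n)
            net = make_network(adj)
            pick = sorted(rng.choice(n, size=int(rng.integers(2, n)), replace=False))
            genes = [net.genes[i] for i in pick]
            props = rn.pathway_subnetwork_properties(genes, net, net)
            sub = adj[np.ix_(pick, pick)]
            k = len(pick)
            degs = sub.sum(axis=1)
            assert props["phi_d"] == pytest.approx(degs.mean())
            assert props["delta_d"] == pytest.approx(sub.sum() / (k * (k - 1)))


class TestRScore:
    def test_identical_subnetworks_pc_ten(self):
        val, reason = r_score(pc=10, phi_d=3.0, phi_c=3.0, delta_d=0.4, delta_c=0.4)
        assert val == pytest.approx(1.0) and reason == "ok"

    def test_empty_control_pc_one(self):
        val, _ = r_score(pc=1, phi_d=2.0, phi_c=0.0, delta_d=0.3, delta_c=0.0)
        assert val == pytest.approx(2.0)

    def test_hand_arithmetic_case(self):
        val, _ = r_score(pc=100, phi_d=4.0, phi_c=6.0, delta_d=0.5, delta_c=0.25)
        assert val == pytest.approx(2.0 + (-0.5) + 0.5)
        # independent formula evaluation
        assert val == pytest.approx(math.log10(100) + (4 - 6) / 4 + (0.5 - 0.25) / 0.5)

    def test_undefined_reasons(self):
        assert r_score(0, 1, 1, 1, 1)[1] == "pc_zero"
        assert r_score(1, 0, 1, 1, 1)[1] == "phi_d_zero"
        assert r_score(1, 1, 1, 0, 1)[1] == "delta_d_zero"

    def test_monotonicity(self):
        base, _ = r_score(5, 3.0, 1.0, 0.5, 0.2)
        more_pc, _ = r_score(6, 3.0, 1.0, 0.5, 0.2)
        worse_control_phi, _ = r_score(5, 3.0, 2.0, 0.5, 0.2)
        worse_control_delta, _ = r_score(5, 3.0, 1.0, 0.5, 0.3)
        assert more_pc > base
        assert worse_control_phi < base and worse_control_delta < base


class TestHubGene:
    def test_star_centre_is_hub(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        net = make_network(adj)
        assert rn.hub_gene(net.genes, net) == net.genes[0]

    def test_clique_tie_breaks_lexicographically(self):
        net = make_network(~np.eye(4, dtype=bool))
        assert rn.hub_gene(net.genes, net) == min(net.genes)

    def test_total_degree_breaks_induced_ties(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1] = adj[1, 0] = True      # induced pair, tied inside
        adj[1, 4] = adj[4, 1] = True      # g001 better connected overall
        net = make_network(adj)
        assert rn.hub_gene(net.genes[:2], net) == net.genes[1]

    def test_edgeless_subgraph_has_no_hub(self):
        net = make_network(np.zeros((4, 4), dtype=bool))
        assert rn.hub_gene(net.genes, net) is None

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(5, 12))
            adj = random_adjacency(rng, n)
            net = make_network(adj)
            hub = rn.hub_gene(net.genes, net)
            degs = adj.sum(axis=1)
            if degs.max() == 0:
                assert hub is None
            else:
                assert degs[net.genes.index(hub)] == degs.max()


class TestScorePathways:
    def test_planted_sets_outrank_decoys(self, standard_analysis):
        truth = standard_analysis["truth"]
        coll = rn.GeneSetCollection(truth.planted_gene_sets,
                                    standard_analysis["data"].genes)
        scores, graph = rn.score_pathways(standard_analysis["zeta"], coll,
                                          standard_analysis["disease"],
                                          standard_analysis["control"])
        planted = [n for n, f in truth.set_flags.items() if f == "planted"]
        enriched = scores[scores["enriched"]]
        assert set(planted) <= set(enriched["pathway"])
        decoys_enriched = enriched["pathway"].str.startswith("DECOY").sum()
        assert decoys_enriched <= 0.05 * 10 + 1e-9
        top = scores["pathway"].tolist()[:len(planted) + 2]
        assert all(p in top for p in planted)
        # every planted set co-members its ring neighbours
        assert (enriched.set_index("pathway").loc[planted, "pc"] >= 1).all()
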