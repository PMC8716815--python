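"""Spearman edges, seasonal/combined networks, graph properties."""

import numpy as np
import networkx as nx
import pytest

from endopersist import (
    EdgeRecord,
    combine_networks,
    network_dissimilarity,
    network_properties,
    ordinate_networks,
    rare_nodes,
    season_network,
    spearman_test,
)
from endopersist.cooccurrence_network import _exact_null_abs_rho

from conftest import make_table

# Published reference rows (node count, edge count, printed edge density)
# for eight combined seasonal co-occurrence networks; they lock in the
# ordered-pair density convention E / (V * (V - 1)).
REFERENCE_NETWORK_ROWS = [
    (38, 58, 0.04125178),
    (174, 347, 0.01152747),
    (27, 33, 0.04700855),
    (80, 88, 0.01392405),
    (57, 94, 0.02944862),
    (43, 71, 0.0393134),
    (49, 56, 0.02380952),
    (48, 50, 0.02216312),
]


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_test([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])
        assert rho == pytest.approx(1.0)

    def test_exact_p_n5_rho1(self):
        """Two-sided exact p at n=5, rho=1 equals 2/120 by full enumeration."""
        rho, p = spearman_test([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], p_method="exact")
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_exact_null_is_symmetric_distribution(self):
        null = _exact_null_abs_rho(5)
        assert null.size == 120
        assert null.max() == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        r1, _ = spearman_test(x, y)
        r2, _ = spearman_test(x, [-v for v in y])
        assert r1 == pytest.approx(-r2)

    def test_matches_scipy_rho_with_ties(self):
        from scipy.stats import spearmanr

        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 3.0, 5.0, 1.0, 8.0, 8.0]
        rho, _ = spearman_test(x, y)
        assert rho == pytest.approx(spearmanr(x, y).statistic, rel=1e-12)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_refused_on_ties(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 2, 3, 4], [1, 2, 3, 4, 5], p_method="exact")


class TestSeasonNetwork:
    def test_planted_proportional_pair_detected(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 5))
        counts[0] = [10, 20, 30, 40, 50]
        counts[1] = [11, 22, 33, 44, 55]
        edges = season_network(make_table(counts))
        pairs = {(e.taxon_a, e.taxon_b) for e in edges}
        assert ("t0", "t1") in pairs
        edge = next(e for e in edges if (e.taxon_a, e.taxon_b) == ("t0", "t1"))
        assert edge.rho == pytest.approx(1.0)
        assert edge.sign == "positive"

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            season_network(make_table(np.ones((4, 3), dtype=int)))

    def test_zero_variance_taxa_skipped(self):
        counts = np.ones((3, 5), dtype=int)
        counts[2] = [1, 2, 3, 4, 5]
        assert season_network(make_table(counts)) == []

    def test_false_edge_rate_matches_exact_null(self):
        """At n=5 only |rho|=1 passes the default gate; the per-pair null
        probability of that event for tie-free vectors is 2/120."""
        rng = np.random.default_rng(1)
        n_pairs = 4000
        hits = 0
        for _ in range(n_pairs):
            x = rng.permutation(5).astype(float)
            y = rng.permutation(5).astype(float)
            rho, p = spearman_test(x, y, p_method="approx")
            hits += abs(rho) > 0.8 and p < 0.01
        expect = n_pairs * 2 / 120
        assert abs(hits - expect) < 4 * np.sqrt(expect)

    def test_invariant_to_sample_and_taxon_order(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(8, 5))
        counts[0] = [5, 10, 15, 20, 25]
        counts[1] = [6, 12, 18, 24, 30]
        t1 = make_table(counts)
        perm_s = rng.permutation(5)
        perm_t = rng.permutation(8)
        t2 = make_table(
            counts[np.ix_(perm_t, perm_s)],
            taxa=[f"t{i}" for i in perm_t],
            samples=[f"s{j}" for j in perm_s],
        )
        e1 = {(e.taxon_a, e.taxon_b, round(e.rho, 12)) for e in season_network(t1)}
        e2 = {(e.taxon_a, e.taxon_b, round(e.rho, 12)) for e in season_network(t2)}
        assert e1 == e2


class TestCombineNetworks:
    def edge(self, a, b, rho=1.0, p=1e-4):
        return EdgeRecord(a, b, rho, p)

    def test_two_season_edge_kept_one_season_dropped(self):
        seasonal = {
            "spring": [self.edge("a", "b"), self.edge("c", "d")],
            "summer": [self.edge("a", "b")],
            "autumn": [],
            "winter": [],
        }
        net = combine_networks(seasonal)
        assert len(net.edges) == 1
        assert net.edges[0].season_set == {"spring", "summer"}
        assert net.nodes == ["a", "b"]
        assert net.kept_ratio == (1, 2)

    def test_sign_mismatch_splits_identity(self):
        seasonal = {
            "spring": [self.edge("a", "b", rho=0.95)],
            "summer": [self.edge("a", "b", rho=-0.95)],
        }
        assert combine_networks(seasonal, match_sign=True).edges == []
        merged = combine_networks(seasonal, match_sign=False)
        assert len(merged.edges) == 1

    def test_combined_edges_reconstructable_from_seasonal(self):
        rng = np.random.default_rng(3)
        names = [f"t{i}" for i in range(12)]
        seasonal = {}
        for s in ("spring", "summer", "autumn", "winter"):
            edges = []
            for _ in range(6):
                a, b = rng.choice(12, 2, replace=False)
                edges.append(self.edge(*sorted((names[a], names[b]))))
            seasonal[s] = edges
        net = combine_networks(seasonal, min_seasons=2)
        for e in net.edges:
            n_present = sum(
                any(
                    {x.taxon_a, x.taxon_b} == {e.taxon_a, e.taxon_b}
                    and x.sign == e.sign
                    for x in edges
                )
                for edges in seasonal.values()
            )
            assert n_present >= 2
            assert e.season_count == n_present

    def test_duplicate_seasons_rejected(self):
        with pytest.raises(ValueError):
            combine_networks({"spring": []}, min_seasons=1)


class TestNetworkProperties:
    @pytest.mark.parametrize("v, e, density", REFERENCE_NETWORK_ROWS)
    def test_density_convention_reproduces_reference_rows(self, v, e, density):
        assert e / (v * (v - 1)) == pytest.approx(density, rel=5e-7)

    def test_triangle(self):
        props = network_properties(nx.complete_graph(3))
        assert props.transitivity == pytest.approx(1.0)
        assert props.diameter == 1
        assert props.edge_density == pytest.approx(0.5)

    def test_path_graph(self):
        props = network_properties(nx.path_graph(3))
        assert props.transitivity == 0.0
        assert props.diameter == 2

    def test_star_graph_maximal_centralization(self):
        props = network_properties(nx.star_graph(7))
        assert props.centralized_closeness == pytest.approx(1.0)
        assert props.centralized_betweenness == pytest.approx(1.0)

    def test_matches_igraph_centralizations(self):
        """Freeman centralizations agree with the igraph lineage."""
        ig = pytest.importorskip("igraph")
        for trial in range(4):
            g = nx.connected_watts_strogatz_graph(20, 4, 0.3, seed=trial)
            props = network_properties(g)
            G = ig.Graph.from_networkx(g)
            n = G.vcount()

            def centr(scores, tmax):
                return sum(max(scores) - s for s in scores) / tmax

            assert props.centralized_closeness == pytest.approx(
                centr(G.closeness(), (n - 1) * (n - 2) / (2 * n - 3)), rel=1e-8
            )
            assert props.centralized_betweenness == pytest.approx(
                centr(G.betweenness(), (n - 1) ** 2 * (n - 2) / 2), rel=1e-8
            )
            assert props.centralized_eigenvector == pytest.approx(
                centr(G.eigenvector_centrality(scale=True), n - 1), rel=1e-6
            )
            assert props.diameter == G.diameter()
            assert props.transitivity == pytest.approx(
                G.transitivity_undirected(), rel=1e-10
            )

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning, match="empty graph"):
            props = network_properties(nx.Graph())
        assert props.node_no == 0


class TestDissimilarityAndOrdination:
    def edge(self, a, b):
        return EdgeRecord(a, b, 1.0, 1e-4)

    def test_set_arithmetic(self):
        e1, e2, e3 = self.edge("a", "b"), self.edge("b", "c"), self.edge("c", "d")
        assert network_dissimilarity([e1, e2], [e1, e2]) == 0.0
        assert network_dissimilarity([e1], [e3]) == 1.0
        assert network_dissimilarity([e1, e2], [e2, e3]) == pytest.approx(2 / 3)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            network_dissimilarity([], [])

    def test_ordination_separates_clusters(self):
        base1 = [self.edge(f"x{i}", f"x{i + 1}") for i in range(6)]
        base2 = [self.edge(f"y{i}", f"y{i + 1}") for i in range(6)]
        nets = {
            "a1": base1,
            "a2": base1[:5] + [self.edge("x9", "x10")],
            "b1": base2,
            "b2": base2[:5] + [self.edge("y9", "y10")],
        }
        res = ordinate_networks(nets, seed=1)
        xy = res.coords.to_numpy()
        within = np.linalg.norm(xy[0] - xy[1]) + np.linalg.norm(xy[2] - xy[3])
        between = np.linalg.norm(xy[:2].mean(axis=0) - xy[2:].mean(axis=0))
        assert between > within
        assert np.isfinite(res.stress)

    def test_rare_node_annotation(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[0] = 1000
        counts[1] = 2
        counts[2] = 3
        table = make_table(counts)
        seasonal = {
            "spring": [self.edge("t1", "t2")],
            "summer": [self.edge("t1", "t2")],
        }
        net = combine_networks(seasonal)
        flags = rare_nodes(net, table)
        assert flags == {"t1": True, "t2": True}


class TestFDRGate:
    def test_bh_correction_is_stricter_than_raw_gate(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, size=(30, 5))
        counts[0] = [10, 20, 30, 40, 50]
        counts[1] = [12, 24, 36, 48, 60]
        table = make_table(counts)
        raw = season_network(table)
        corrected = season_network(table, fdr_bh=True)
        raw_pairs = {(e.taxon_a, e.taxon_b) for e in raw}
        bh_pairs = {(e.taxon_a, e.taxon_b) for e in corrected}
        assert bh_pairs <= raw_pairs
        assert ("t0", "t1") in bh_pairs  # perfect correlation survives (p = 0)
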