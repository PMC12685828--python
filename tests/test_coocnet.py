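import networkx as nx
import numpy as np
import pytest

from micronet.coocnet import (
    build_network,
    complexity_index,
    global_efficiency,
    robustness,
    topology,
    vulnerability,
)
from micronet.exceptions import ValidationError
from micronet.synthetic import module_recovery_design, simulate_dataset
from micronet.tables_io import FeatureTable
from oracles import (
    brute_clustering,
    brute_global_efficiency,
    brute_vulnerability,
    star_robustness_expectation,
)


def graph_from_edges(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, r=0.9, q=0.01, sign="positive")
    return g


class TestBuildNetwork:
    def test_identical_vectors_make_one_positive_edge(self):
        rng = np.random.default_rng(42)
        noise = rng.integers(20, 200, size=(6, 6))
        counts = np.vstack([
            [5, 1, 8, 2, 9, 3],
            [5, 1, 8, 2, 9, 3],
            noise,
        ])
        table = FeatureTable(
            ["a", "b"] + [f"n{i}" for i in range(6)],
            [f"s{i}" for i in range(6)], counts,
        )
        net = build_network(table, min_prevalence=0.0)
        assert {frozenset(e) for e in net.graph.edges} == {
            frozenset(("a", "b"))
        }
        assert net.graph["a"]["b"]["sign"] == "positive"
        assert net.graph["a"]["b"]["r"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        counts = np.random.default_rng(0).integers(1, 9, (5, 3))
        table = FeatureTable([f"t{i}" for i in range(5)],
                             ["a", "b", "c"], counts)
        with pytest.raises(ValidationError):
            build_network(table)

    def test_edge_set_invariant_to_orderings(self):
        rng = np.random.default_rng(8)
        sim = simulate_dataset(module_recovery_design(), seed=8)
        table = sim.feature_tables["bacterial"]
        meta = sim.metadata
        sw = list(meta.index[meta["treatment"] == "SW"])
        base = build_network(table, sw)

        taxon_perm = rng.permutation(len(table.taxon_ids))
        shuffled = FeatureTable(
            [table.taxon_ids[i] for i in taxon_perm],
            table.sample_ids,
            table.counts[taxon_perm],
        )
        sample_perm = list(rng.permutation(sw))
        other = build_network(shuffled, sample_perm)
        edges = lambda n: {frozenset(e) for e in n.graph.edges}
        assert edges(base) == edges(other)

    def test_null_false_edges_controlled(self):
        """BH keeps the expected number of false edges far below
        q * n_pairs under independence."""
        rng = np.random.default_rng(101)
        n_taxa, n_samples, n_networks = 40, 20, 60
        total_edges = 0
        for _ in range(n_networks):
            counts = rng.poisson(50, size=(n_taxa, n_samples)) + 1
            table = FeatureTable(
                [f"t{i}" for i in range(n_taxa)],
                [f"s{i}" for i in range(n_samples)],
                counts,
            )
            net = build_network(table, min_prevalence=0.0)
            total_edges += net.n_edges
        n_pairs = n_taxa * (n_taxa - 1) / 2
        assert total_edges / n_networks <= 0.05 * n_pairs

    def test_module_recovery_precision_recall(self):
        sim = simulate_dataset(module_recovery_design(), seed=0)
        meta = sim.metadata
        sw = list(meta.index[meta["treatment"] == "SW"])
        net = build_network(sim.feature_tables["bacterial"], sw)
        true_pairs = {frozenset(p) for p in sim.truth.modules[0].pairs()}
        found = {frozenset(e) for e in net.graph.edges}
        tp = len(found & true_pairs)
        assert tp / max(len(found), 1) >= 0.9
        assert tp / len(true_pairs) >= 0.6


class TestTopology:
    def test_printed_average_degree(self):
        g = nx.gnm_random_graph(197, 1179, seed=1)
        summary = topology(g)
        assert round(summary.average_degree, 2) == 11.97

    def test_triangle(self):
        summary = topology(graph_from_edges([("a", "b"), ("b", "c"),
                                             ("a", "c")]))
        assert summary.average_degree == 2.0
        assert summary.clustering_coefficient == 1.0
        assert summary.n_positive_edges == 3

    def test_star_clustering_zero(self):
        star = graph_from_edges([("h", f"l{i}") for i in range(4)])
        assert topology(star).clustering_coefficient == 0.0

    def test_empty_graph_all_zero(self):
        summary = topology(nx.Graph())
        assert summary.n_vertices == 0
        assert summary.average_degree == 0.0

    def test_clustering_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8),
                                    seed=int(rng.integers(1 << 30)))
            adj = nx.to_numpy_array(g)
            assert topology(g).clustering_coefficient == pytest.approx(
                brute_clustering(adj), abs=1e-12
            )


class TestComplexity:
    def test_maximal_network_scores_one(self):
        a = topology(graph_from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                       ("c", "d")]))
        b = topology(graph_from_edges([("x", "y")]))
        composite = complexity_index({"big": a, "small": b})
        assert composite["big"] == pytest.approx(1.0)
        assert composite["small"] < 1.0

    def test_identical_networks_both_one(self):
        t = topology(graph_from_edges([("a", "b"), ("b", "c")]))
        composite = complexity_index({"n1": t, "n2": t})
        assert composite == {"n1": pytest.approx(1.0),
                             "n2": pytest.approx(1.0)}

    def test_hand_computed_ratios(self):
        path2 = topology(graph_from_edges([("a", "b"), ("b", "c")]))
        tri = topology(graph_from_edges([("a", "b"), ("b", "c"),
                                         ("a", "c")]))
        composite = complexity_index(
            {"path": path2, "tri": tri},
            index_set=("n_vertices", "n_edges", "average_degree",
                       "clustering_coefficient"),
        )
        # path: vertices 3/3, edges 2/3, avg degree (4/3)/2, clustering 0/1
        assert composite["path"] == pytest.approx(
            np.mean([1.0, 2 / 3, (4 / 3) / 2, 0.0])
        )
        assert composite["tri"] == pytest.approx(1.0)

    def test_scale_consistency(self):
        a = topology(graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        b = topology(graph_from_edges([("x", "y"), ("y", "z")]))
        base = complexity_index({"a": a, "b": b})
        import dataclasses

        scaled = {
            k: dataclasses.replace(
                v,
                n_vertices=v.n_vertices * 10,
                n_edges=v.n_edges * 10,
                n_positive_edges=v.n_positive_edges * 10,
                n_negative_edges=v.n_negative_edges * 10,
                average_degree=v.average_degree * 10,
                clustering_coefficient=v.clustering_coefficient * 10,
            )
            for k, v in {"a": a, "b": b}.items()
        }
        again = complexity_index(scaled)
        for k in base:
            assert again[k] == pytest.approx(base[k])


class TestRobustness:
    def test_edgeless_zero_everywhere(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        curve = robustness(g, repetitions=10, seed=0)
        assert (curve["mean"] == 0.0).all()

    def test_complete_graph_mean_half_at_half(self):
        curve = robustness(
            nx.complete_graph(100), removal_fractions=(0.5,),
            repetitions=50, seed=1,
        )
        # every kept node still has edges, so the value is exactly 1 - p
        assert curve["mean"].iloc[0] == pytest.approx(0.5)
        assert curve["sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_star_matches_exhaustive_expectation(self):
        n_leaves = 5
        star = nx.star_graph(n_leaves)
        for p in (0.3, 0.5):
            exact = star_robustness_expectation(n_leaves, p)
            curve = robustness(star, removal_fractions=(p,),
                               repetitions=4000, seed=2)
            mc = curve["mean"].iloc[0]
            se = curve["sd"].iloc[0] / np.sqrt(4000)
            assert abs(mc - exact) < max(4 * se, 0.01)

    def test_monotone_non_increasing(self):
        g = nx.gnm_random_graph(40, 80, seed=3)
        curve = robustness(g, repetitions=200, seed=4)
        means = curve["mean"].to_numpy()
        ses = curve["sd"].to_numpy() / np.sqrt(200)
        assert (np.diff(means) <= 2 * (ses[:-1] + ses[1:]) + 1e-12).all()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            robustness(nx.complete_graph(5), removal_fractions=(1.0,),
                       seed=0)


class TestVulnerability:
    def test_path_of_three_matches_brute_force(self):
        g = nx.path_graph(3)
        adj = nx.to_numpy_array(g)
        assert vulnerability(g) == pytest.approx(brute_vulnerability(adj))
        # removing the middle node disconnects everything
        assert vulnerability(g) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5])
    def test_complete_graph_closed_form(self, n):
        # deleting any node of K_n leaves K_{n-1}, still fully efficient
        assert vulnerability(nx.complete_graph(n)) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_star_more_vulnerable_than_cycle(self):
        star = nx.star_graph(7)  # 8 nodes
        cycle = nx.cycle_graph(8)
        assert vulnerability(star) > vulnerability(cycle)

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        with pytest.raises(ValidationError):
            vulnerability(g)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 20:
            n = int(rng.integers(3, 10))
            g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.9),
                                    seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(g)
            assert global_efficiency(g) == pytest.approx(
                brute_global_efficiency(adj), abs=1e-12
            )
            assert vulnerability(g) == pytest.approx(
                brute_vulnerability(adj), abs=1e-12
            )
            checked += 1
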