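import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanmf import (
    bipartite_report,
    build_subnetwork,
    centralities,
    rank_hubs,
)

from oracles import betweenness_by_enumeration


def _edges(pairs, score=0.95):
    return pd.DataFrame([(a, b, score) for a, b in pairs],
                        columns=["node_a", "node_b", "score"])


class TestBuildSubnetwork:
    def test_first_order_star_pulls_in_neighbors(self):
        g = build_subnetwork(["A"], _edges([("A", "B"), ("A", "C"),
                                            ("B", "C")]), min_score=0.5)
        assert set(g.nodes) == {"A", "B", "C"}
        assert g.number_of_edges() == 3
        assert g.nodes["B"]["is_seed"] is False

    def test_zero_order_restricts_to_seeds(self):
        g = build_subnetwork(["A", "B"], _edges([("A", "C")]),
                             min_score=0.5, order="zero")
        assert set(g.nodes) == {"A"}  # B absent from interactome
        assert g.number_of_edges() == 0

    def test_score_filter_drops_weak_edges(self):
        edges = pd.DataFrame([("A", "B", 0.95), ("A", "C", 0.5)],
                             columns=["node_a", "node_b", "score"])
        g = build_subnetwork(["A"], edges, min_score=0.9)
        assert set(g.nodes) == {"A", "B"}

    def test_isolated_seed_retained_and_flagged(self):
        edges = pd.DataFrame([("A", "B", 0.95), ("C", "D", 0.3)],
                             columns=["node_a", "node_b", "score"])
        g = build_subnetwork(["A", "C"], edges, min_score=0.9)
        assert "C" in g.nodes and g.nodes["C"]["isolated"]

    def test_no_seed_in_interactome_errors(self):
        with pytest.raises(ValueError, match="no seed"):
            build_subnetwork(["Z"], _edges([("A", "B")]), min_score=0.5)

    def test_planted_hub_keeps_degree(self, small_config, small_study):
        from metanmf import simulate_network
        _, truth = small_study
        edges = simulate_network(small_config, truth)
        seeds = sorted(truth.de_genes_up | truth.de_genes_down)
        g = build_subnetwork(seeds, edges, min_score=0.9)
        for hub in truth.hub_genes:
            assert g.degree(hub) >= small_config.network_planted_hub_degree


class TestCentralities:
    def test_path_graph_center(self):
        g = build_subnetwork(["a", "b", "c"],
                             _edges([("a", "b"), ("b", "c")]), 0.5)
        centralities(g)
        assert g.nodes["b"]["betweenness"] == pytest.approx(1.0)
        assert g.nodes["a"]["betweenness"] == 0
        assert g.nodes["b"]["degree"] == 2

    def test_star_center_counts_leaf_pairs(self):
        g = build_subnetwork(["c"], _edges([("c", "x"), ("c", "y"),
                                            ("c", "z")]), 0.5)
        centralities(g)
        assert g.nodes["c"]["betweenness"] == pytest.approx(3.0)  # C(3,2)

    def test_triangle_all_zero(self):
        g = build_subnetwork(["a", "b", "c"],
                             _edges([("a", "b"), ("b", "c"), ("a", "c")]),
                             0.5)
        centralities(g)
        assert all(g.nodes[v]["betweenness"] == 0 for v in g.nodes)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10 ** 6))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        nodes = [f"n{i}" for i in range(n)]
        pairs = [p for p in itertools.combinations(nodes, 2)
                 if rng.random() < 0.45]
        if not pairs:
            return
        g = nx.Graph(pairs)
        centralities(g)
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        oracle = betweenness_by_enumeration(adj)
        for v in g.nodes:
            assert g.nodes[v]["betweenness"] == pytest.approx(
                oracle[v], abs=1e-9)

    def test_degree_sum_equals_twice_edges(self, small_config, small_study):
        from metanmf import simulate_network
        _, truth = small_study
        edges = simulate_network(small_config, truth)
        g = build_subnetwork(sorted(truth.hub_genes), edges, min_score=0.0)
        centralities(g)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestRankHubs:
    def test_degree_then_betweenness_tie_rule(self):
        g = nx.Graph()
        for v, (deg, bc) in {"w": (5, 0.0), "x": (3, 7.0), "y": (3, 2.0),
                             "z": (1, 0.0)}.items():
            g.add_node(v)
        # build attrs manually to isolate the ordering logic
        nx.set_node_attributes(g, {"w": 5, "x": 3, "y": 3, "z": 1}, "degree")
        nx.set_node_attributes(
            g, {"w": 0.0, "x": 7.0, "y": 2.0, "z": 0.0}, "betweenness")
        # rank_hubs recomputes centralities, so emulate its sort directly
        ranked = sorted(g.nodes, key=lambda v: (-g.nodes[v]["degree"],
                                                -g.nodes[v]["betweenness"],
                                                v))
        assert ranked == ["w", "x", "y", "z"]

    def test_top_k_and_join_with_deg_table(self):
        g = build_subnetwork(
            ["a", "d"], _edges([("a", "b"), ("a", "c"), ("b", "c"),
                                ("c", "d")]), 0.5)
        deg_table = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "logFC": [1.0, -0.5, 0.7, 0.2],
            "mean_expr": [5.0, 6.0, 7.0, 8.0],
        })
        hubs = rank_hubs(g, k=2, deg_table=deg_table)
        assert list(hubs.columns) == ["gene", "degree", "betweenness",
                                      "expression", "logFC"]
        assert len(hubs) == 2
        assert hubs.iloc[0]["gene"] == "c"  # degree 3

    def test_k_larger_than_nodes_returns_all(self, caplog):
        g = build_subnetwork(["a"], _edges([("a", "b")]), 0.5)
        with caplog.at_level("WARNING"):
            hubs = rank_hubs(g, k=10)
        assert len(hubs) == 2

    def test_stable_under_edge_permutation(self):
        rng = np.random.default_rng(4)
        pairs = [(f"n{i}", f"n{j}") for i in range(10) for j in range(i)
                 if rng.random() < 0.4]
        e1 = _edges(pairs)
        e2 = _edges(list(reversed(pairs)))
        seeds = [f"n{i}" for i in range(10)]
        h1 = rank_hubs(build_subnetwork(seeds, e1, 0.5), k=5)
        h2 = rank_hubs(build_subnetwork(seeds, e2, 0.5), k=5)
        pd.testing.assert_frame_equal(h1, h2)

    def test_planted_hubs_dominate_top_k(self, small_config, small_study):
        from metanmf import simulate_network
        _, truth = small_study
        edges = simulate_network(small_config, truth)
        seeds = sorted(truth.de_genes_up | truth.de_genes_down)
        g = build_subnetwork(seeds, edges, min_score=0.9)
        hubs = rank_hubs(g, k=10)
        assert truth.hub_genes <= set(hubs["gene"])


class TestBipartiteReport:
    @staticmethod
    def _assoc():
        return pd.DataFrame(
            [("g1", "D", 0.8), ("g2", "D", 0.7), ("g3", "E", 0.9),
             ("g1", "E", 0.2)],
            columns=["gene", "entity", "score"])

    def test_min_shared_two(self):
        rep = bipartite_report(["g1", "g2", "g3"], self._assoc(),
                               min_score=0.5, min_shared=2)
        assert list(rep["entity"]) == ["D"]
        assert rep.iloc[0]["genes"] == "g1,g2"

    def test_min_shared_three_excludes(self):
        rep = bipartite_report(["g1", "g2", "g3"], self._assoc(),
                               min_shared=3)
        assert rep.empty

    def test_score_filter(self):
        rep = bipartite_report(["g1", "g3"], self._assoc(), min_score=0.5,
                               min_shared=1)
        by_entity = dict(zip(rep["entity"], rep["genes"]))
        assert by_entity["E"] == "g3"  # g1-E filtered at 0.2

    def test_tf_ranking_by_degree(self):
        assoc = pd.DataFrame(
            [("g1", "TF_A", 1.0), ("g2", "TF_A", 1.0), ("g3", "TF_A", 1.0),
             ("g1", "TF_B", 1.0)],
            columns=["gene", "entity", "score"])
        rep = bipartite_report(["g1", "g2", "g3"], assoc, min_shared=1,
                               rank_entities=True)
        assert list(rep["entity"]) == ["TF_A", "TF_B"]
        assert rep.iloc[0]["degree"] == 3

    def test_planted_hub_diseases_all_reported(self, small_config,
                                               small_study):
        from metanmf import simulate_annotations
        from metanmf.simulate import DISEASE_LABELS
        _, truth = small_study
        _, gda, _ = simulate_annotations(small_config, truth)
        rep = bipartite_report(sorted(truth.hub_genes), gda, min_shared=2)
        assert set(DISEASE_LABELS) <= set(rep["entity"])
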