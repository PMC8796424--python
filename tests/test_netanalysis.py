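import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rnanet.coexpression import ModulePartition
from rnanet.errors import ValidationError
from rnanet.netanalysis import (
    UNASSIGNED_COLOR,
    aggregate_deg_to_genes,
    compute_metrics,
    correlation_module_graph,
    encode_visual_attributes,
    gene_effect_summary,
    hub_genes,
    module_colored_graph,
    overlap_deg,
    read_graphml,
    reduce_edges,
    write_graphml,
)


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Brute-force betweenness: enumerate all shortest paths per pair."""
    result = {n: 0.0 for n in graph.nodes}
    nodes = sorted(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for node in graph.nodes:
            if node in (s, t):
                continue
            through = sum(node in p for p in paths)
            result[node] += through / len(paths)
    return result


def closeness_oracle(graph: nx.Graph) -> dict:
    """All-pairs BFS distances with the component-scaled closeness formula."""
    n = graph.number_of_nodes()
    out = {}
    for node in graph.nodes:
        dist = nx.single_source_shortest_path_length(graph, node)
        reachable = len(dist) - 1
        if reachable == 0:
            out[node] = 0.0
        else:
            total = sum(dist.values())
            out[node] = (reachable / total) * (reachable / (n - 1))
    return out


class TestReduceEdges:
    def test_duplicates_and_reversals_collapse(self):
        graph, report = reduce_edges([("a", "b"), ("b", "a"), ("a", "b")])
        assert graph.number_of_edges() == 1
        assert report.input_rows == 3 and report.kept_edges == 1

    def test_self_loop_dropped_and_reported(self):
        graph, report = reduce_edges([("a", "a"), ("a", "b")])
        assert not graph.has_edge("a", "a")
        assert report.self_loops_dropped == 1

    def test_keep_self_loops_flag(self):
        graph, _ = reduce_edges([("a", "a")], keep_self_loops=True)
        assert graph.has_edge("a", "a")

    def test_random_multigraph_matches_set_oracle(self, rng):
        nodes = [f"n{i}" for i in range(15)]
        rows = [
            (rng.choice(nodes), rng.choice(nodes)) for _ in range(200)
        ]
        graph, report = reduce_edges(rows)
        want = {frozenset(r) for r in rows if r[0] != r[1]}
        got = {frozenset(e) for e in graph.edges}
        assert got == want
        assert report.kept_edges <= report.input_rows

    def test_idempotent(self, rng):
        rows = [("a", "b"), ("b", "c"), ("c", "a"), ("b", "a")]
        graph, _ = reduce_edges(rows)
        again, _ = reduce_edges(list(graph.edges))
        assert {frozenset(e) for e in graph.edges} == {frozenset(e) for e in again.edges}

    def test_malformed_rows_rejected(self):
        graph, report = reduce_edges([("a", ""), ("", "b"), ("a", "b")])
        assert graph.number_of_edges() == 1
        assert len(report.rejects) == 2


class TestOverlapDeg:
    def _deg(self, genes, effects=None):
        effects = effects or [1.0] * len(genes)
        return pd.DataFrame(
            {"effect": effects, "p_value": 0.001, "q_value": 0.01, "mean_count": 10.0},
            index=pd.Index(genes, name="id"),
        )

    def test_induced_subgraph(self):
        graph, _ = reduce_edges([("a", "b"), ("b", "c")])
        sub, empty = overlap_deg(graph, self._deg(["a", "b"]))
        assert set(sub.nodes) == {"a", "b"}
        assert list(sub.edges) == [("a", "b")]
        assert not empty

    def test_disjoint_deg_flags_empty(self):
        graph, _ = reduce_edges([("a", "b")])
        sub, empty = overlap_deg(graph, self._deg(["x", "y"]))
        assert empty and sub.number_of_nodes() == 0

    def test_superset_is_identity(self):
        graph, _ = reduce_edges([("a", "b"), ("b", "c")])
        sub, _ = overlap_deg(graph, self._deg(["a", "b", "c", "d"]))
        assert set(sub.nodes) == set(graph.nodes)

    def test_idempotent(self):
        graph, _ = reduce_edges([("a", "b"), ("b", "c"), ("c", "d")])
        deg = self._deg(["a", "b", "c"])
        once, _ = overlap_deg(graph, deg)
        twice, _ = overlap_deg(once, deg)
        assert set(once.nodes) == set(twice.nodes)
        assert set(once.edges) == set(twice.edges)


class TestGeneEffectSummary:
    def test_mean_of_isoforms(self):
        effect, _, conflict = gene_effect_summary([1.0, 3.0])
        assert effect == 2.0 and not conflict

    def test_single_isoform_identity(self):
        effect, count, _ = gene_effect_summary([1.5], [20.0])
        assert effect == 1.5 and count == 20.0

    def test_opposite_signs_flagged(self):
        effect, _, conflict = gene_effect_summary([2.0, -2.0])
        assert effect == 0.0 and conflict

    def test_aggregate_table_by_suffix(self):
        deg = pd.DataFrame(
            {
                "effect": [1.0, 3.0, -2.0],
                "p_value": [0.01, 0.02, 0.005],
                "q_value": [0.1, 0.2, 0.05],
                "mean_count": [10.0, 30.0, 5.0],
            },
            index=pd.Index(["G1.1", "G1.2", "G2.1"], name="id"),
        )
        out = aggregate_deg_to_genes(deg)
        assert out.loc["G1", "effect"] == 2.0
        assert out.loc["G1", "p_value"] == 0.01
        assert not out.loc["G1", "sign_conflict"]


class TestVisualAttributes:
    def _graph(self, effects, counts):
        g = nx.Graph()
        for i, (e, c) in enumerate(zip(effects, counts)):
            g.add_node(f"n{i}", effect=e, mean_count=c)
        return g

    def test_sign_determines_shape(self):
        g = encode_visual_attributes(self._graph([-1.0, 2.0], [5.0, 10.0]))
        shapes = {g.nodes[n]["shape"] for n in g.nodes}
        assert len(shapes) == 2

    def test_single_node_degenerate_scaling(self):
        g = encode_visual_attributes(self._graph([1.0], [5.0]), size_range=(10, 50))
        node = g.nodes["n0"]
        assert node["opacity"] == 1.0 and node["size"] == 50.0

    def test_opacities_in_unit_interval(self, rng):
        effects = rng.normal(size=20)
        counts = rng.uniform(1, 100, size=20)
        g = encode_visual_attributes(self._graph(effects, counts))
        ops = [g.nodes[n]["opacity"] for n in g.nodes]
        assert min(ops) >= 0.0 and max(ops) <= 1.0


class TestMetrics:
    def test_path_graph(self):
        graph = nx.path_graph(["a", "b", "c"])
        metrics = compute_metrics(graph)
        assert metrics.node_table["degree"].tolist() == [1, 2, 1]
        assert metrics.diameter_per_component[0] == 2
        assert metrics.mean_clustering == 0.0

    def test_triangle(self):
        metrics = compute_metrics(nx.complete_graph(3))
        assert metrics.mean_clustering == 1.0
        assert metrics.diameter_per_component[0] == 1

    def test_degree_sum_is_twice_edges(self, rng):
        graph = nx.gnp_random_graph(25, 0.2, seed=7)
        metrics = compute_metrics(graph)
        assert metrics.node_table["degree"].sum() == 2 * graph.number_of_edges()

    def test_betweenness_closeness_match_bruteforce(self, rng):
        for seed in range(3):
            graph = nx.gnp_random_graph(30, 0.12, seed=seed)
            metrics = compute_metrics(graph)
            want_b = betweenness_oracle(graph)
            want_c = closeness_oracle(graph)
            for node in graph.nodes:
                assert metrics.node_table.loc[node, "betweenness"] == pytest.approx(
                    want_b[node], abs=1e-9
                )
                assert metrics.node_table.loc[node, "closeness"] == pytest.approx(
                    want_c[node], abs=1e-9
                )

    def test_empty_graph_raises(self):
        with pytest.raises(ValidationError):
            compute_metrics(nx.Graph())


class TestHubGenes:
    def _partition(self, mapping):
        return ModulePartition(assignment=pd.Series(mapping))

    def test_star_center_is_hub(self):
        graph = nx.star_graph(["hub", "a", "b", "c", "d", "e"])
        partition = self._partition({n: 1 for n in graph.nodes})
        hubs, merged, _ = hub_genes(graph, partition, top_k=1)
        assert hubs[1] == ["hub"]
        assert merged == ["hub"]

    def test_two_star_modules_merged_centers(self):
        g1 = nx.star_graph(["h1", "a1", "b1", "c1"])
        g2 = nx.star_graph(["h2", "a2", "b2", "c2"])
        graph = nx.union(g1, g2)
        mapping = {n: 1 for n in g1.nodes} | {n: 2 for n in g2.nodes}
        hubs, merged, _ = hub_genes(graph, self._partition(mapping), top_k=1)
        assert set(merged) == {"h1", "h2"}

    def test_cycle_tiebreak_lexicographic(self):
        graph = nx.cycle_graph(["c", "a", "b", "d"])
        hubs, _, _ = hub_genes(graph, self._partition({n: 1 for n in graph.nodes}), top_k=1)
        assert hubs[1] == ["a"]

    def test_go_intersection(self):
        graph = nx.star_graph(["hub", "a", "b"])
        hubs, merged, inter = hub_genes(
            graph, self._partition({n: 1 for n in graph.nodes}), top_k=2,
            go_genes={"hub", "zzz"},
        )
        assert inter == {"hub"}

    def test_disconnected_modules_locality(self):
        g1 = nx.path_graph(["a", "b", "c"])
        g2 = nx.path_graph(["x", "y", "z"])
        graph = nx.union(g1, g2)
        mapping = {n: 1 for n in g1.nodes} | {n: 2 for n in g2.nodes}
        joint, _, _ = hub_genes(graph, self._partition(mapping), top_k=1)
        solo1, _, _ = hub_genes(g1, self._partition({n: 1 for n in g1.nodes}), top_k=1)
        assert joint[1] == solo1[1]


class TestColoring:
    def test_two_modules_plus_unassigned(self):
        graph = nx.path_graph(["a", "b", "c"])
        partition = ModulePartition(assignment=pd.Series({"a": 1, "b": 2}))
        colored = module_colored_graph(graph, partition)
        assert colored.nodes["c"]["color"] == UNASSIGNED_COLOR
        assert colored.nodes["a"]["color"] != colored.nodes["b"]["color"]

    def test_deterministic(self):
        graph = nx.path_graph(["a", "b"])
        partition = ModulePartition(assignment=pd.Series({"a": 1, "b": 2}))
        c1 = module_colored_graph(graph, partition)
        c2 = module_colored_graph(graph, partition)
        assert all(c1.nodes[n]["color"] == c2.nodes[n]["color"] for n in graph.nodes)


class TestCorrelationModuleGraph:
    def _similarity(self):
        genes = [f"m1_{i}" for i in range(4)] + [f"m2_{i}" for i in range(4)]
        s = np.full((8, 8), 0.2)
        s[:4, :4] = 0.9
        s[4:, 4:] = 0.9
        np.fill_diagonal(s, 1.0)
        frame = pd.DataFrame(s, index=genes, columns=genes)
        labels = pd.Series([1] * 4 + [2] * 4, index=genes)
        return frame, ModulePartition(assignment=labels)

    def test_planted_blocks_no_cross_edges(self):
        s, partition = self._similarity()
        graph = correlation_module_graph(s, partition, [1, 2], threshold=0.5)
        assert graph.number_of_edges() == 2 * 6  # two K4 cliques
        for u, v in graph.edges:
            assert u[:2] == v[:2]

    def test_threshold_zero_complete(self):
        s, partition = self._similarity()
        graph = correlation_module_graph(s, partition, [1, 2], threshold=0.0)
        assert graph.number_of_edges() == 8 * 7 // 2

    def test_invalid_threshold(self):
        s, partition = self._similarity()
        with pytest.raises(ValidationError):
            correlation_module_graph(s, partition, [1], threshold=1.5)

    def test_node_size_is_degree(self):
        s, partition = self._similarity()
        graph = correlation_module_graph(s, partition, [1], threshold=0.5)
        for n in graph.nodes:
            assert graph.nodes[n]["size"] == graph.degree(n)


def test_graphml_roundtrip_preserves_attributes(tmp_path):
    graph = nx.Graph()
    graph.add_node("a", effect=1.5, shape="triangle-up", module=2)
    graph.add_node("b", effect=-0.5, shape="triangle-down", module=1)
    graph.add_edge("a", "b", weight=0.9)
    path = tmp_path / "g.graphml"
    write_graphml(graph, path)
    back = read_graphml(path)
    assert back.nodes["a"]["effect"] == 1.5
    assert back.nodes["b"]["shape"] == "triangle-down"
    assert back.edges["a", "b"]["weight"] == 0.9
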