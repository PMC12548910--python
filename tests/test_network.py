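import itertools

import numpy as np
import pytest

from causyn.io import CellLineProfile, PPINetwork
from causyn.network import (
    build_specific_network,
    induced_expression_graph,
    shortest_paths_from,
)


def make_net(edges):
    net = PPINetwork()
    for u, v in edges:
        net.add_edge(u, v)
    return net


def enumerate_simple_paths(net, source, target):
    """Brute-force all simple paths via DFS (test oracle)."""
    adj = {n: net.neighbors(n) for n in net.nodes}
    paths = []

    def walk(node, seen, path):
        if node == target:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                walk(nxt, seen | {nxt}, path + [nxt])

    walk(source, {source}, [source])
    return paths


class TestShortestPaths:
    def test_path_graph(self, path_graph):
        out = shortest_paths_from(path_graph, "a")
        assert out["c"] == (["a", "b", "c"], 2)

    def test_two_routes_takes_shorter(self):
        net = make_net([("a", "b"), ("b", "c"), ("c", "d"), ("a", "e"), ("e", "d")])
        path, length = shortest_paths_from(net, "a")["d"]
        assert length == 2 and path == ["a", "e", "d"]

    def test_disconnected_component_absent(self):
        net = make_net([("a", "b"), ("x", "y")])
        out = shortest_paths_from(net, "a")
        assert set(out) == {"a", "b"}

    def test_unknown_source_rejected(self, path_graph):
        with pytest.raises(ValueError):
            shortest_paths_from(path_graph, "zz")

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_simple_path_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 9))
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.35
        ]
        if not edges:
            edges = [(nodes[0], nodes[1])]
        net = make_net(edges)
        source = sorted(net.nodes)[0]
        out = shortest_paths_from(net, source)
        for target in sorted(net.nodes):
            brute = enumerate_simple_paths(net, source, target)
            if not brute:
                assert target not in out
                continue
            path, length = out[target]
            assert length == min(len(p) - 1 for p in brute)
            assert path in brute  # returned path is a real simple path


class TestBuildSpecificNetwork:
    def test_star_graph_two_leaves(self):
        net = make_net([("c", f"l{i}") for i in range(1, 5)])
        sp = build_specific_network(net, {"l1", "l2"})
        assert set(sp.nodes) == {"l1", "c", "l2"}
        assert len(sp.edges) == 2

    def test_single_seed_is_trivial(self):
        net = make_net([("v", "w")])
        sp = build_specific_network(net, {"v"})
        assert sp.nodes == ["v"] and sp.edges == set()

    def test_triangle_spanning_tree(self):
        net = make_net([("a", "b"), ("b", "c"), ("a", "c")])
        sp = build_specific_network(net, {"a", "b", "c"})
        assert set(sp.nodes) == {"a", "b", "c"}
        assert len(sp.edges) == 2  # brute force: spanning tree is optimal

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            build_specific_network(make_net([("a", "b")]), set())

    def test_unknown_seeds_dropped(self):
        net = make_net([("a", "b")])
        sp = build_specific_network(net, {"a", "zz"})
        assert sp.nodes == ["a"]

    def test_multi_component_keeps_majority(self):
        net = make_net([("a", "b"), ("b", "c"), ("x", "y")])
        sp = build_specific_network(net, {"a", "c", "x"})
        assert set(sp.nodes) == {"a", "b", "c"}

    def test_subgraph_property_and_determinism(self):
        rng = np.random.default_rng(7)
        nodes = [f"g{i}" for i in range(12)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(12) for j in range(i + 1, 12)
            if rng.random() < 0.25
        ] + [(nodes[i], nodes[i + 1]) for i in range(11)]
        net = make_net(edges)
        seeds = {"g0", "g5", "g11"}
        first = build_specific_network(net, seeds)
        assert set(first.nodes) <= net.nodes
        assert first.edges <= net.edges
        assert seeds <= set(first.nodes)
        again = build_specific_network(net, set(seeds))
        assert again.nodes == first.nodes and again.edges == first.edges

    def test_induced_edges_flag_adds_shortcuts(self):
        net = make_net([("a", "b"), ("b", "c"), ("a", "c")])
        tree = build_specific_network(net, {"a", "b", "c"})
        full = build_specific_network(net, {"a", "b", "c"}, induced_edges=True)
        assert len(full.edges) == 3 > len(tree.edges)


class TestInducedExpressionGraph:
    def _profile(self, expr):
        return CellLineProfile("c", targets=set(expr), expression=expr)

    def test_feature_vector_in_node_order(self):
        net = make_net([("g1", "g2"), ("g2", "g3")])
        sp = build_specific_network(net, {"g1", "g3"})
        eg = induced_expression_graph(
            sp, self._profile({"g1": 0.5, "g2": -0.5, "g3": 0.0})
        )
        expected = {"g1": 0.5, "g2": -0.5, "g3": 0.0}
        assert eg.features.shape == (3, 1)
        for node, value in zip(eg.nodes, eg.features.ravel()):
            assert value == expected[node]

    def test_adjacency_consistent_with_node_order(self):
        net = make_net([("g1", "g2"), ("g2", "g3")])
        sp = build_specific_network(net, {"g1", "g3"})
        eg = induced_expression_graph(
            sp, self._profile({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        )
        i = {n: k for k, n in enumerate(eg.nodes)}
        assert eg.adjacency[i["g1"], i["g2"]] == 1
        assert eg.adjacency[i["g1"], i["g3"]] == 0

    def test_missing_expression_names_gene(self):
        net = make_net([("g1", "g2"), ("g2", "g3")])
        sp = build_specific_network(net, {"g1", "g3"})
        with pytest.raises(ValueError, match="g3"):
            induced_expression_graph(sp, self._profile({"g1": 0.1, "g2": 0.2}))


def brute_force_steiner_edges(adj_sets, seeds, n):
    """Minimum edge count of a connected subgraph containing the seeds."""
    best = None
    node_ids = list(range(n))
    others = [v for v in node_ids if v not in seeds]
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            sel = set(seeds) | set(extra)
            # connectivity of induced subgraph
            start = next(iter(sel))
            seen = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj_sets[u] & sel:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if seen >= set(seeds) and seen == sel:
                cost = len(sel) - 1  # a spanning tree of the selection
                if best is None or cost < best:
                    best = cost
        if best is not None:
            return best  # costs grow with r; first feasible level is optimal
    return best


class TestSteinerHeuristicQuality:
    @pytest.mark.parametrize("trial", range(30))
    def test_between_optimum_and_pairwise_bound(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(4, 9))
        names = [f"v{i}" for i in range(n)]
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.4]
        edges += [(i, i + 1) for i in range(n - 1)]  # ensure connected
        net = make_net([(names[i], names[j]) for i, j in sorted(set(edges))])
        adj_sets = {i: set() for i in range(n)}
        for i, j in set(edges):
            adj_sets[i].add(j)
            adj_sets[j].add(i)
        k = int(rng.integers(2, 4))
        seeds = rng.choice(n, size=k, replace=False).tolist()
        result = build_specific_network(net, {names[s] for s in seeds})
        opt = brute_force_steiner_edges(adj_sets, set(seeds), n)
        upper = 0
        for a, b in itertools.combinations(sorted(seeds), 2):
            upper += shortest_paths_from(net, names[a])[names[b]][1]
        assert opt <= len(result.edges) <= upper
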