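"""Habitat graph construction, CFBC scoring and prioritization."""

import itertools

import networkx as nx
import numpy as np
import pytest

import connectgene as cg
from connectgene.network import HabitatGraph, HabitatNodes


def make_graph(n, edges, cost, threshold=10.0):
    nodes = HabitatNodes(
        np.zeros((n, 2), dtype=int), np.arange(n, dtype=float), np.zeros(n), np.ones(n)
    )
    return HabitatGraph(nodes, np.asarray(edges), np.asarray(cost, dtype=float),
                        threshold, 100.0)


def dense_cfbc(n, edges, cost, cap=None, beta=0.0):
    """Independent oracle: Laplacian pseudoinverse, explicit pair loop."""
    cap = np.ones(n) if cap is None else cap
    L = np.zeros((n, n))
    cond = 1.0 / np.asarray(cost, dtype=float)
    for (i, j), c in zip(edges, cond):
        L[i, i] += c
        L[j, j] += c
        L[i, j] -= c
        L[j, i] -= c
    G = np.linalg.pinv(L)
    comp = {}
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edges))
    for ci, members in enumerate(nx.connected_components(g)):
        for v in members:
            comp[v] = ci
    scores = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if comp[s] != comp[t]:
                continue
            v = G[:, s] - G[:, t]
            T = np.zeros(n)
            for (i, j), c in zip(edges, cond):
                cur = abs((v[i] - v[j]) * c)
                T[i] += cur
                T[j] += cur
            T *= 0.5
            T[s] = T[t] = 1.0
            scores += (cap[s] * cap[t]) ** beta * T
    return scores


class TestExtractHabitatNodes:
    def test_counts_and_strict_cutoff(self):
        committee = cg.Raster(np.array([[0.6, 0.5], [0.8, 0.2]]))
        mask = committee.like((committee.values > 0.5).astype(float))
        nodes = cg.extract_habitat_nodes_from_mask(mask)
        assert len(nodes) == 2  # the 0.5 cell is excluded by the strict rule
        x, y = mask.cell_center(nodes.cells[:, 0], nodes.cells[:, 1])
        assert np.allclose(nodes.x, x) and np.allclose(nodes.y, y)

    def test_zero_suitable_cells_rejected(self):
        with pytest.raises(ValueError):
            cg.extract_habitat_nodes_from_mask(cg.Raster(np.zeros((3, 3))))


class TestBuildThresholdGraph:
    @pytest.fixture()
    def surface(self):
        rng = np.random.default_rng(2)
        suit = cg.Raster(rng.random((12, 12)), cell_size=50.0)
        roads = suit.like(np.zeros(suit.shape))
        return cg.compose_resistance(suit, roads)

    def test_extreme_thresholds(self, surface):
        mask = surface.cost.like((surface.cost.values < 10).astype(float))
        if mask.values.sum() < 2:
            mask.values[0, 0] = mask.values[-1, -1] = 1.0
        nodes = cg.extract_habitat_nodes_from_mask(mask)
        empty = cg.build_threshold_graph(nodes, surface, 1e-6, 1e6)
        assert len(empty.edges) == 0
        full = cg.build_threshold_graph(nodes, surface, 1e6, 1e6)
        assert len(full.edges) == len(nodes) * (len(nodes) - 1) // 2

    def test_edge_set_matches_pairwise_dijkstra_oracle(self, surface):
        rng = np.random.default_rng(3)
        rc = rng.choice(144, size=10, replace=False)
        cells = np.column_stack([rc // 12, rc % 12])
        x, y = surface.cost.cell_center(cells[:, 0], cells[:, 1])
        nodes = HabitatNodes(cells, x, y, np.ones(10))
        thr = 4000.0
        graph = cg.build_threshold_graph(nodes, surface, thr, 250000.0)
        lattice = cg.build_lattice(surface)
        sites = cg.PointSet(np.array([f"n{i}" for i in range(10)], dtype=object), x, y)
        lcd = cg.lcd_matrix(lattice, sites)
        expected = {
            (i, j)
            for i, j in itertools.combinations(range(10), 2)
            if lcd.values[i, j] < thr
        }
        got = {tuple(e) for e in graph.edges}
        assert got == expected

    def test_monotone_threshold_nesting(self, surface):
        rng = np.random.default_rng(4)
        rc = rng.choice(144, size=8, replace=False)
        cells = np.column_stack([rc // 12, rc % 12])
        x, y = surface.cost.cell_center(cells[:, 0], cells[:, 1])
        nodes = HabitatNodes(cells, x, y, np.ones(8))
        e_small = {tuple(e) for e in cg.build_threshold_graph(nodes, surface, 2000.0, 1e6).edges}
        e_big = {tuple(e) for e in cg.build_threshold_graph(nodes, surface, 6000.0, 1e6).edges}
        assert e_small <= e_big

    def test_threshold_above_cap_rejected(self, surface):
        nodes = HabitatNodes(np.array([[0, 0]]), np.array([25.0]), np.array([575.0]), np.ones(1))
        with pytest.raises(ValueError):
            cg.build_threshold_graph(nodes, surface, 10.0, 5.0)


class TestCfbc:
    def test_path_graph_values(self):
        g = make_graph(3, [[0, 1], [1, 2]], [1.0, 1.0])
        assert np.allclose(cg.cfbc(g).scores, [2.0, 3.0, 2.0])

    def test_star_center_dominates(self):
        g = make_graph(5, [[0, i] for i in range(1, 5)], np.ones(4))
        s = cg.cfbc(g).scores
        assert np.all(s[0] > s[1:])
        assert np.allclose(s[1:], s[1])

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 26))
            edges = {(int(rng.integers(0, i)), i) for i in range(1, n)}
            for a, b in rng.integers(0, n, (n, 2)):
                if a != b:
                    edges.add((min(a, b), max(a, b)))
            edges = np.array(sorted(edges))
            cost = rng.uniform(0.5, 5.0, len(edges))
            g = make_graph(n, edges, cost)
            assert np.allclose(cg.cfbc(g).scores, dense_cfbc(n, edges, cost), atol=1e-8)

    def test_capacity_beta_weighting_matches_oracle(self):
        rng = np.random.default_rng(8)
        n = 7
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [0, 6], [2, 5]])
        cost = rng.uniform(0.5, 3.0, len(edges))
        cap = rng.uniform(0.5, 4.0, n)
        nodes = HabitatNodes(np.zeros((n, 2), int), np.arange(n, dtype=float), np.zeros(n), cap)
        g = HabitatGraph(nodes, edges, cost, 10.0, 100.0)
        assert np.allclose(
            cg.cfbc(g, beta=1.0).scores, dense_cfbc(n, edges, cost, cap, beta=1.0), atol=1e-8
        )

    def test_disconnected_components_and_isolated_nodes(self):
        g = make_graph(5, [[0, 1], [2, 3]], [1.0, 1.0])
        s = cg.cfbc(g).scores
        assert s[4] == 0.0
        assert np.allclose(s[:4], 1.0)  # each 2-node component: one pair, endpoints 1
        # per-component equals whole-graph computation
        g01 = make_graph(2, [[0, 1]], [1.0])
        assert np.allclose(cg.cfbc(g01).scores, s[:2])

    def test_score_floor_in_connected_components(self):
        rng = np.random.default_rng(9)
        n = 10
        edges = np.array([[i, (i + 1) % n] for i in range(n)])
        g = make_graph(n, edges, rng.uniform(0.5, 2.0, n))
        assert np.all(cg.cfbc(g).scores >= 1.0 - 1e-9)


class TestAssignAndPrioritize:
    def test_nearest_node_with_tie_rule(self):
        nodes = HabitatNodes(
            np.zeros((3, 2), int), np.array([0.0, 2.0, 4.0]), np.zeros(3), np.ones(3)
        )
        g = HabitatGraph(nodes, np.empty((0, 2), int), np.empty(0), 5.0, 10.0)
        pops = cg.PointSet(np.array(["a", "b"], dtype=object), np.array([0.1, 1.0]), np.zeros(2))
        got = cg.assign_population_nodes(pops, g)
        assert got[0] == 0
        assert got[1] == 0  # equidistant between nodes 0 and 1 -> lowest index

    def test_assignment_matches_brute_force(self):
        rng = np.random.default_rng(10)
        nodes = HabitatNodes(
            np.zeros((20, 2), int), rng.random(20) * 100, rng.random(20) * 100, np.ones(20)
        )
        g = HabitatGraph(nodes, np.empty((0, 2), int), np.empty(0), 5.0, 10.0)
        pops = cg.PointSet(
            np.array([f"p{i}" for i in range(6)], dtype=object),
            rng.random(6) * 100, rng.random(6) * 100,
        )
        got = cg.assign_population_nodes(pops, g)
        for k in range(6):
            d = np.hypot(nodes.x - pops.x[k], nodes.y - pops.y[k])
            assert got[k] == int(np.argmin(d))

    def test_top_quantile_with_distinct_scores(self):
        rng = np.random.default_rng(11)
        scores = rng.permutation(100).astype(float)
        res = cg.CentralityResult(scores, 0.0, 5000.0)
        top = cg.prioritize_nodes(res, 0.05)
        assert len(top) == 5
        assert sorted(top["cfbc"]) == [95.0, 96.0, 97.0, 98.0, 99.0]
        assert list(top["cfbc"]) == sorted(top["cfbc"], reverse=True)

    def test_all_equal_scores_returns_everything(self):
        res = cg.CentralityResult(np.full(10, 3.0), 0.0, 5000.0)
        assert len(cg.prioritize_nodes(res, 0.05)) == 10

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(12)
        scores = rng.random(57)
        res = cg.CentralityResult(scores, 0.0, 5000.0)
        top = cg.prioritize_nodes(res, 0.1)
        cut = np.quantile(scores, 0.9)
        expected = {i for i, s in enumerate(scores) if s >= cut}
        assert set(top["node"]) == expected
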