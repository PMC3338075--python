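"""Graph construction and the four centralities against brute force."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kolminer.comention_sna import (
    CentralityError,
    betweenness_centrality,
    build_graph,
    centrality_table,
    closeness_centrality,
    connected_components,
    degree_centrality,
    eigenvector_centrality,
    rank_experts,
)


# --- independent oracles ----------------------------------------------------


def all_simple_paths(g, s, t):
    """Every simple s-t path, by plain DFS."""
    paths, stack = [], [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nbr in g[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))
    return paths


def brute_betweenness(g):
    nodes = sorted(g.nodes)
    cb = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(g, s, t)
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == dmin]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            cb[v] += through / len(geodesics)
    return cb


def brute_closeness(g, v):
    dists = []
    comp = nx.node_connected_component(g, v)
    for t in comp:
        if t != v:
            dmin = min(len(p) - 1 for p in all_simple_paths(g, v, t))
            dists.append(dmin)
    return 1.0 / sum(dists) if dists else math.nan


def dense_eigenvector(g):
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, np.argmax(w)])
    return {n: x / v.max() for n, x in zip(nodes, v)}, float(w.max())


def random_graph(seed, max_n=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.45:
            g.add_edge(i, j)
    return g


# --- graph construction -----------------------------------------------------


class TestBuildGraph:
    def test_article_forms_clique(self):
        g = build_graph({"a1": {"A", "B", "C"}})
        assert set(map(frozenset, g.edges)) == {
            frozenset("AB"), frozenset("AC"), frozenset("BC")
        }

    def test_repeat_comention_stays_unweighted_single_edge(self):
        g = build_graph({"a1": {"A", "B"}, "a2": {"A", "B"}})
        assert g.number_of_edges() == 1
        assert not nx.is_weighted(g)

    def test_lone_person_is_vertex_without_edges(self):
        g = build_graph({"a1": {"A"}})
        assert set(g.nodes) == {"A"} and g.number_of_edges() == 0

    def test_no_self_loops(self):
        g = build_graph({"a1": ["A", "A", "B"]})
        assert nx.number_of_selfloops(g) == 0

    def test_permutation_invariance_over_articles(self):
        arts = {f"a{i}": {f"P{i % 5}", f"P{(i * 3) % 7}"} for i in range(12)}
        g1 = build_graph(arts)
        g2 = build_graph(dict(reversed(list(arts.items()))))
        assert set(g1.nodes) == set(g2.nodes)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


class TestComponents:
    def test_two_triangles(self):
        g = build_graph({"a": {"A", "B", "C"}, "b": {"X", "Y", "Z"}})
        comps = connected_components(g)
        assert [len(c) for c in comps] == [3, 3]
        assert comps[0][0] < comps[1][0]  # size tie broken by smallest id

    def test_empty_graph(self):
        assert connected_components(nx.Graph()) == []

    def test_path_is_single_component(self):
        assert len(connected_components(nx.path_graph(5))) == 1


# --- closed forms -----------------------------------------------------------


class TestClosedForms:
    path3 = nx.path_graph(["a", "b", "c"])
    star = nx.star_graph(3)  # center 0, leaves 1..3
    k4 = nx.complete_graph(4)
    c4 = nx.cycle_graph(4)

    def test_degree(self):
        d = degree_centrality(self.path3)
        assert d["b"] == 1.0 and d["a"] == 0.5
        s = degree_centrality(self.star)
        assert s[0] == 1.0 and s[1] == pytest.approx(1 / 3)
        assert all(v == 1.0 for v in degree_centrality(self.k4).values())

    def test_degree_undefined_below_two_vertices(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(CentralityError):
            degree_centrality(g)

    def test_betweenness(self):
        b = betweenness_centrality(self.path3)
        assert b["b"] == 1.0 and b["a"] == 0.0
        assert betweenness_centrality(self.star)[0] == 3.0
        # 4-cycle: each opposite pair has two geodesics, one through each
        # intermediate vertex
        assert all(v == pytest.approx(0.5)
                   for v in betweenness_centrality(self.c4).values())

    def test_closeness(self):
        c = closeness_centrality(self.path3)
        assert c["b"] == 0.5 and c["a"] == pytest.approx(1 / 3)
        assert all(v == 1.0 for v in closeness_centrality(nx.complete_graph(2)).values())
        s = closeness_centrality(self.star)
        assert s[0] == pytest.approx(1 / 3) and s[1] == pytest.approx(0.2)

    def test_closeness_isolated_vertex_missing(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("a", "b")
        g.add_node("z")
        assert math.isnan(closeness_centrality(g)["z"])

    def test_eigenvector_cycle_uniform(self):
        scores, lam = eigenvector_centrality(nx.cycle_graph(5))
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in scores.values())
        assert lam == pytest.approx(2.0, abs=1e-8)

    def test_eigenvector_path3(self):
        scores, lam = eigenvector_centrality(self.path3)
        assert lam == pytest.approx(math.sqrt(2), abs=1e-8)
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == pytest.approx(math.sqrt(0.5), abs=1e-6)

    def test_eigenvector_star(self):
        scores, _ = eigenvector_centrality(self.star)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(1 / math.sqrt(3), abs=1e-6)

    def test_eigenvector_requires_connected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("z")
        with pytest.raises(CentralityError):
            eigenvector_centrality(g)

    def test_eigenvector_fixed_point_residual(self):
        g = random_graph(71)  # connected draw on 8 vertices
        g = g.subgraph(max(nx.connected_components(g), key=len))
        scores, lam = eigenvector_centrality(g)
        nodes = sorted(g.nodes)
        a = nx.to_numpy_array(g, nodelist=nodes)
        c = np.array([scores[v] for v in nodes])
        assert np.abs(a @ c - lam * c).max() < 1e-8


# --- randomized oracle equivalence -----------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_centralities_match_brute_force(seed):
    g = random_graph(seed)
    bb = brute_betweenness(g)
    for v, got in betweenness_centrality(g).items():
        assert got == pytest.approx(bb[v], abs=1e-6)
    for v, got in closeness_centrality(g).items():
        expected = brute_closeness(g, v)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-6)
    n = g.number_of_nodes()
    for v, got in degree_centrality(g).items():
        assert got == pytest.approx(g.degree(v) / (n - 1))
    comp = max(nx.connected_components(g), key=len)
    if len(comp) >= 2:
        sub = g.subgraph(comp)
        scores, lam = eigenvector_centrality(sub)
        dense, dlam = dense_eigenvector(sub)
        assert lam == pytest.approx(dlam, abs=1e-6)
        for v in comp:
            assert scores[v] == pytest.approx(dense[v], abs=1e-6)


def test_tree_betweenness_sum_counts_interior_vertices_of_all_pairs():
    # on a tree every pair has one geodesic, so summing C_B over vertices
    # counts, for each unordered pair, its d(s,t) - 1 interior vertices
    tree = nx.random_labeled_tree(9, seed=4)
    total = sum(betweenness_centrality(tree).values())
    interior_vertices = sum(
        nx.shortest_path_length(tree, s, t) - 1
        for s, t in itertools.combinations(tree.nodes, 2)
    )
    assert total == pytest.approx(interior_vertices)


# --- ranking ----------------------------------------------------------------


def make_table(n, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "mentions": rng.integers(1, 50, n),
            "c_deg": rng.random(n),
            "c_btw": rng.random(n),
            "c_clo": rng.random(n),
            "c_eig": rng.random(n),
        },
        index=pd.Index(ids, name="person_id"),
    )


class TestRankExperts:
    def test_k_at_least_n_unions_everyone(self):
        table = make_table(7)
        result = rank_experts(table, k=20)
        assert result.union == sorted(table.index)

    def test_identical_orderings_union_is_k(self):
        table = make_table(100)
        for col in ("c_deg", "c_btw", "c_clo", "c_eig"):
            table[col] = table["mentions"].astype(float)
        result = rank_experts(table, k=20)
        assert len(result.union) == 20

    def test_union_matches_set_brute_force(self):
        table = make_table(60, seed=3)
        result = rank_experts(table, k=10)
        expected = set()
        for col in ("mentions", "c_deg", "c_btw", "c_clo", "c_eig"):
            order = sorted(table.index, key=lambda v: (-table.loc[v, col], v))
            expected |= set(order[:10])
        assert set(result.union) == expected
        for pid in result.union:
            assert result.qualifying[pid]

    def test_ties_break_by_person_id(self):
        table = make_table(5)
        table["mentions"] = 7
        result = rank_experts(table, k=2)
        assert result.top_k["mentions"] == sorted(table.index)[:2]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            rank_experts(make_table(3), k=0)


def test_centrality_table_component_scoping():
    g = build_graph({"a": {"A", "B", "C"}, "b": {"X", "Y"}, "c": {"Z"}})
    table = centrality_table(g, {v: 1 for v in g.nodes})
    # degree uses component n: in the triangle each vertex has deg 2 / (3-1)
    assert table.loc["A", "c_deg"] == 1.0
    assert table.loc["X", "c_deg"] == 1.0  # K2 component
    assert math.isnan(table.loc["Z", "c_deg"])  # singleton component
    assert math.isnan(table.loc["Z", "c_clo"])
    glob = centrality_table(g, {v: 1 for v in g.nodes}, use_global_n=True)
    assert glob.loc["A", "c_deg"] == pytest.approx(2 / 5)
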