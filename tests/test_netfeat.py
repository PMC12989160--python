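"""Contact-network construction and centrality checks against brute-force
oracles (explicit path enumeration, dense eigendecomposition)."""

import itertools

import numpy as np
import pytest

import networkx as nx

from missdriver.io import StructureModel
from missdriver.netfeat import (
    ContactNetwork,
    all_centralities,
    build_contact_network,
    centrality_features,
    eigenvector_centrality,
)


# ----------------------------------------------------------- oracle functions

def oracle_shortest_paths(adj, s, t):
    """All shortest paths between s and t by breadth-limited DFS enumeration."""
    n = len(adj)
    # BFS distance
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u][v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[u][v] and dist.get(v) == dist[u] + 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def oracle_centralities(weights):
    """Closeness, betweenness, eigenvector (max-norm), weighted degree by
    brute force on a dense weight matrix."""
    n = len(weights)
    adj = (np.asarray(weights) > 0).astype(int)
    closeness = []
    for u in range(n):
        dist = {}
        for v in range(n):
            paths = oracle_shortest_paths(adj, u, v)
            if paths:
                dist[v] = len(paths[0]) - 1
        reachable = [v for v in dist if v != u]
        if not reachable:
            closeness.append(0.0)
        else:
            total = sum(dist[v] for v in reachable)
            closeness.append(
                (len(reachable) / total) * (len(reachable) / (n - 1))
            )
    betweenness = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = oracle_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    betweenness = betweenness / norm if norm > 0 else betweenness
    w = np.asarray(weights, dtype=float)
    vals, vecs = np.linalg.eigh(w)
    vec = vecs[:, np.argmax(vals)]
    vec = np.abs(vec)
    if vec.max() > 0:
        vec = vec / vec.max()
    degree = w.sum(axis=1)
    return closeness, betweenness.tolist(), vec.tolist(), degree.tolist()


def network_from_weights(weights):
    g = nx.Graph()
    n = len(weights)
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i][j] > 0:
                g.add_edge(i, j, weight=int(weights[i][j]))
    return ContactNetwork(graph=g, cutoff=7.0, node_order=list(range(n)))


def random_connected_weights(rng, n):
    w = np.zeros((n, n), dtype=int)
    order = rng.permutation(n)
    for a, b in zip(order, order[1:]):  # random spanning tree
        w[a, b] = w[b, a] = int(rng.integers(1, 6))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0 and rng.random() < 0.35:
                w[i, j] = w[j, i] = int(rng.integers(1, 6))
    return w


# -------------------------------------------------------- network construction

def test_contact_edge_boundary(two_residue_model_factory):
    net = build_contact_network(two_residue_model_factory(6.9))
    assert net.graph.has_edge(1, 5) and net.edge_weight(1, 5) == 1
    net_far = build_contact_network(two_residue_model_factory(7.1))
    assert net_far.graph.number_of_edges() == 0


def test_contact_edge_weight_counts_atom_pairs():
    # residue 1 has 2 atoms, residue 5 has 2 atoms; brute-force pair count
    res1 = (1, "ALA", [("CA", 0, 0, 0, 90.0), ("CB", 1.0, 0, 0, 90.0)])
    res2 = (5, "GLY", [("CA", 5.0, 0, 0, 90.0), ("N", 6.5, 0, 0, 90.0)])
    model = StructureModel("p", "0", [res1, res2])
    pairs = [
        (a, b)
        for a in res1[2]
        for b in res2[2]
        if np.linalg.norm(np.array(a[1:4]) - np.array(b[1:4])) <= 7.0
    ]
    net = build_contact_network(model)
    assert net.edge_weight(1, 5) == len(pairs) == 4


def test_contact_network_invariant_under_atom_order():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 4.0, size=(6, 3, 3))  # 6 residues x 3 atoms
    def build(perm):
        residues = []
        for i in range(6):
            atoms = [("CA", *map(float, pts[i, k]), 90.0) for k in perm[i]]
            residues.append((i + 1, "ALA", atoms))
        return build_contact_network(StructureModel("p", "0", residues))

    identity = [[0, 1, 2]] * 6
    shuffled = [list(rng.permutation(3)) for _ in range(6)]
    a, b = build(identity), build(shuffled)
    assert sorted(a.graph.edges(data="weight")) == sorted(b.graph.edges(data="weight"))


def test_edge_monotonicity_in_cutoff():
    rng = np.random.default_rng(4)
    residues = [
        (i + 1, "ALA", [("CA", *map(float, rng.normal(0, 5.0, 3)), 90.0)])
        for i in range(15)
    ]
    model = StructureModel("p", "0", residues)
    e5 = set(build_contact_network(model, cutoff=5.0).graph.edges())
    e7 = set(build_contact_network(model, cutoff=7.0).graph.edges())
    e9 = set(build_contact_network(model, cutoff=9.0).graph.edges())
    assert e5 <= e7 <= e9


# ------------------------------------------------------------------ centrality

def test_path_graph_closed_forms():
    net = network_from_weights([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    clo_b, bet_b, _, _ = centrality_features(net, 1)
    clo_a, bet_a, _, _ = centrality_features(net, 0)
    assert clo_b == pytest.approx(1.0)
    assert bet_b == pytest.approx(1.0)
    assert clo_a == pytest.approx(2.0 / 3.0)
    assert bet_a == pytest.approx(0.0)


def test_complete_graph_symmetry():
    w = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
    net = network_from_weights(w)
    feats = [centrality_features(net, v) for v in range(4)]
    for f in feats[1:]:
        assert f == pytest.approx(feats[0])


def test_centralities_match_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(3, 9))
        w = random_connected_weights(rng, n)
        net = network_from_weights(w)
        clo_o, bet_o, eig_o, deg_o = oracle_centralities(w)
        cent = all_centralities(net)
        for v in range(n):
            clo, bet, eig, deg = cent[v]
            assert clo == pytest.approx(clo_o[v], abs=1e-6)
            assert bet == pytest.approx(bet_o[v], abs=1e-6)
            assert eig == pytest.approx(eig_o[v], abs=1e-6)
            assert deg == pytest.approx(deg_o[v], abs=1e-6)


def test_disconnected_node_scores_zero():
    w = np.zeros((4, 4), dtype=int)
    w[0, 1] = w[1, 0] = 1
    net = network_from_weights(w)
    clo, bet, _, deg = centrality_features(net, 3)
    assert clo == 0.0 and bet == 0.0 and deg == 0.0


def test_centrality_unknown_node_errors():
    net = network_from_weights([[0, 1], [1, 0]])
    with pytest.raises(KeyError):
        centrality_features(net, 99)
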