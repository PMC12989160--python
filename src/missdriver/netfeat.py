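"""Weighted amino-acid contact networks and residue centrality features.

Residues are nodes; an edge joins two residues when any atom pair lies
within a distance cutoff (default 7 A), weighted by the number of such atom
pairs. Four per-residue features are derived: closeness, betweenness,
eigenvector centrality and weighted degree. Shortest paths use unit edge
lengths; weights enter only the eigenvector and degree measures (the path
metric is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io import StructureModel


@dataclass
class ContactNetwork:
    """Undirected residue graph with positive-integer atom-pair-count weights."""

    graph: nx.Graph
    cutoff: float
    protein_id: str = ""
    node_order: list[int] = field(default_factory=list)

    @property
    def nodes(self) -> list[int]:
        return self.node_order

    def edge_weight(self, i: int, j: int) -> int:
        return int(self.graph[i][j]["weight"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tweight\n")
            for i, j, w in sorted(self.graph.edges(data="weight")):
                fh.write(f"{i}\t{j}\t{int(w)}\n")


def build_contact_network(model: StructureModel, cutoff: float = 7.0) -> ContactNetwork:
    """Build the weighted contact network of a structure model.

    Edge (i, j), i != j, exists iff at least one atom of residue i is within
    ``cutoff`` of an atom of residue j; its weight is the number of such atom
    pairs. No self-edges; the graph is undirected.
    """
    if len(model.residues) < 2:
        raise ValueError("contact network needs at least 2 residues")
    coords = []
    owner = []
    numbers = []
    for idx, (num, _, atoms) in enumerate(model.residues):
        numbers.append(num)
        for _, x, y, z, _ in atoms:
            coords.append((x, y, z))
            owner.append(idx)
    xyz = np.asarray(coords)
    owner_arr = np.asarray(owner)
    g = nx.Graph()
    g.add_nodes_from(numbers)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        ri = owner_arr[pairs[:, 0]]
        rj = owner_arr[pairs[:, 1]]
        mask = ri != rj
        for a, b in zip(ri[mask], rj[mask]):
            i, j = numbers[min(a, b)], numbers[max(a, b)]
            if g.has_edge(i, j):
                g[i][j]["weight"] += 1
            else:
                g.add_edge(i, j, weight=1)
    return ContactNetwork(
        graph=g, cutoff=cutoff, protein_id=model.protein_id, node_order=numbers
    )


def eigenvector_centrality(
    network: ContactNetwork, tol: float = 1e-9, max_iter: int = 10_000
) -> dict[int, float]:
    """Eigenvector centrality of the weighted adjacency by power iteration.

    Deterministic all-ones start; the result is normalized to max-norm 1.
    """
    nodes = network.nodes
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for i, j, w in network.graph.edges(data="weight"):
        a[index[i], index[j]] = w
        a[index[j], index[i]] = w
    # shift by the max weighted degree: keeps eigenvectors, makes the
    # spectrum positive so bipartite-like graphs cannot oscillate
    shift = float(a.sum(axis=1).max())
    a = a + shift * np.eye(n)
    x = np.ones(n)
    for _ in range(max_iter):
        y = a @ x
        norm = np.max(np.abs(y))
        if norm == 0:
            x = np.zeros(n)
            break
        y = y / norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    return {v: float(x[index[v]]) for v in nodes}


def centrality_features(
    network: ContactNetwork, pos: int
) -> tuple[float, float, float, float]:
    """(closeness, betweenness, eigenvector, weighted_degree) of one residue.

    Closeness is the reciprocal of the mean unit-length shortest path to the
    reachable nodes, scaled by the reachable fraction (the standard
    Wasserman-Faust form, so disconnected components are comparable);
    betweenness is normalized by (n-1)(n-2)/2. An isolated node scores 0 for
    both.
    """
    g = network.graph
    if pos not in g:
        raise KeyError(f"residue {pos} is not a node of the network")
    closeness = nx.closeness_centrality(g, u=pos, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=True)[pos]
    eig = eigenvector_centrality(network)[pos]
    degree = float(g.degree(pos, weight="weight"))
    return float(closeness), float(betweenness), eig, degree


def all_centralities(network: ContactNetwork) -> dict[int, tuple[float, float, float, float]]:
    """Centrality features for every node; one shared betweenness pass."""
    g = network.graph
    closeness = {v: nx.closeness_centrality(g, u=v, wf_improved=True) for v in g}
    betweenness = nx.betweenness_centrality(g, normalized=True)
    eig = eigenvector_centrality(network)
    return {
        v: (
            float(closeness[v]),
            float(betweenness[v]),
            eig[v],
            float(g.degree(v, weight="weight")),
        )
        for v in network.nodes
    }
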