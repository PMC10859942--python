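"""Independent brute-force oracles for the network descriptors.

Everything here is deliberately naive -- exhaustive path enumeration, dense
eigendecomposition, explicit distance matrices, neighbour-pair triplet
counting -- and shares no code path with looa.metrics, so agreement is
evidence rather than tautology.  Only usable on tiny graphs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def _bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _adjacency(graph: nx.Graph) -> dict:
    return {v: set(graph.neighbors(v)) for v in graph.nodes()}


def _all_shortest_paths(adj: dict, dist_from_s: dict, s, t) -> list[tuple]:
    """Enumerate every shortest s-t path by walking the BFS layers."""
    if t not in dist_from_s:
        return []
    paths = []

    def extend(path):
        head = path[-1]
        if head == t:
            paths.append(tuple(path))
            return
        for v in adj[head]:
            if dist_from_s.get(v) == dist_from_s[head] + 1 and dist_from_s[v] <= dist_from_s[t]:
                extend(path + [v])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist_from_s[t]]


def brute_betweenness(graph: nx.Graph) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = _adjacency(graph)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = _bfs_distances(adj, s)
        paths = _all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    scale = (n - 1) * (n - 2) / 2.0
    return {v: s / scale for v, s in score.items()}


def dense_eigencentrality(graph: nx.Graph) -> dict:
    """Per-component dominant eigenvector via dense eigendecomposition."""
    result = {}
    for component in nx.connected_components(graph):
        comp = sorted(component, key=str)
        if len(comp) == 1:
            result[comp[0]] = 0.0
            continue
        a = nx.to_numpy_array(graph, nodelist=comp)
        eigval, eigvec = np.linalg.eigh(a)
        vec = np.abs(eigvec[:, np.argmax(eigval)])
        vec /= vec.max()
        result.update(zip(comp, vec.tolist()))
    return result


def brute_harmonic_closeness(graph: nx.Graph) -> dict:
    """Harmonic closeness from hand-rolled BFS distance maps."""
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = _adjacency(graph)
    if n == 1:
        return {nodes[0]: 0.0}
    result = {}
    for v in nodes:
        dist = _bfs_distances(adj, v)
        result[v] = sum(1.0 / d for u, d in dist.items() if u != v) / (n - 1)
    return result


def brute_gcc(graph: nx.Graph) -> float:
    """Transitivity by checking every centered neighbour pair explicitly."""
    closed = 0
    total = 0
    for center in graph.nodes():
        for u, w in itertools.combinations(sorted(graph.neighbors(center), key=str), 2):
            total += 1
            if graph.has_edge(u, w):
                closed += 1
    return closed / total if total else 0.0
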