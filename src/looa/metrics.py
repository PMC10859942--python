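"""The five network properties (NPs) scored by the leave-one-out analyses.

Per-vertex descriptors: degree (raw interaction count), eigenvector
centrality (per connected component, scaled so the component maximum is 1),
shortest-path betweenness (normalized to [0, 1]), and harmonic closeness
(mean of inverse distances, so disconnected graphs need no special casing).
The graph-level profile collapses these to five scalars: the degree sum (the
network's "total complexity") or optionally Freeman degree centralization,
the mean of each centrality, and the global clustering coefficient.

Betweenness, closeness and transitivity are delegated to igraph's C
implementations; eigenvector centrality is a power iteration written here
so that each connected component is scaled independently (a whole-graph
iteration on a disconnected graph zeroes all but one component, which would
make knockout deltas discontinuous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Literal

import igraph as ig
import networkx as nx
import numpy as np

from looa.errors import ConvergenceError, GraphSizeError

CentralityMap = dict[Hashable, float]

#: Column order of a profile vector and of every delta matrix.
PROFILE_FIELDS = ("dc", "ec", "bc", "cc", "gcc")

DegreeAggregate = Literal["sum", "centralization"]


@dataclass(frozen=True)
class NetworkProfile:
    """Graph-level values of the five network properties for one graph state.

    Attributes
    ----------
    dc : float
        Degree aggregate; in ``sum`` mode the sum of all vertex degrees
        (= 2 x edge count), in ``centralization`` mode Freeman degree
        centralization in [0, 1].
    ec : float
        Mean eigenvector centrality (each component scaled to max 1).
    bc : float
        Mean normalized betweenness, in [0, 1].
    cc : float
        Mean harmonic closeness, in [0, 1].
    gcc : float
        Global clustering coefficient (transitivity), in [0, 1].
    """

    dc: float
    ec: float
    bc: float
    cc: float
    gcc: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dc, self.ec, self.bc, self.cc, self.gcc], dtype=float)


def _require_nonempty(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise GraphSizeError("graph has no vertices")


def _to_igraph(graph: nx.Graph, nodes: list) -> ig.Graph:
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    return ig.Graph(n=len(nodes), edges=edges)


def degree_sum(graph: nx.Graph) -> int:
    """Total complexity of the interactome: sum of all vertex degrees."""
    _require_nonempty(graph)
    return 2 * graph.number_of_edges()


def degree_centrality(graph: nx.Graph) -> CentralityMap:
    """Raw interaction count per vertex (the unit of the hub-class bins)."""
    _require_nonempty(graph)
    return {v: float(d) for v, d in graph.degree()}


def eigenvector_centrality(
    graph: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityMap:
    """Dominant-eigenvector centrality, computed per connected component.

    Power iteration on ``A + I`` (same eigenvectors as ``A``; the shift makes
    the iteration converge on bipartite components) from a uniform positive
    start, with each component's vector rescaled so its maximum entry is 1.
    Vertices in single-vertex components have no interactions to propagate
    influence through and score 0.

    Raises
    ------
    ConvergenceError
        If a component fails to converge within ``max_iter`` iterations.
    """
    _require_nonempty(graph)
    result: CentralityMap = {}
    for component in nx.connected_components(graph):
        comp = sorted(component, key=str)
        if len(comp) == 1:
            result[comp[0]] = 0.0
            continue
        adj = nx.to_scipy_sparse_array(graph, nodelist=comp, dtype=float, format="csr")
        x = np.ones(len(comp))
        for _ in range(max_iter):
            x_new = adj @ x + x
            x_new /= x_new.max()
            delta = np.abs(x_new - x).max()
            x = x_new
            if delta < tol:
                break
        else:
            raise ConvergenceError(
                f"eigenvector centrality did not converge in {max_iter} iterations "
                f"(component size {len(comp)}, last change {delta:.3e})"
            )
        result.update(zip(comp, x.tolist()))
    return result


def betweenness_centrality(graph: nx.Graph) -> CentralityMap:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2.

    Each unordered vertex pair is counted once and credit is split equally
    among equal-length shortest paths.  Graphs with fewer than 3 vertices
    have no intermediate positions, so every value is 0.
    """
    _require_nonempty(graph)
    nodes = list(graph.nodes())
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    raw = _to_igraph(graph, nodes).betweenness()
    scale = (n - 1) * (n - 2) / 2.0
    return {v: b / scale for v, b in zip(nodes, raw)}


def harmonic_closeness(graph: nx.Graph) -> CentralityMap:
    """Harmonic closeness: mean of inverse distances to all other vertices.

    ``cc(v) = (1/(n-1)) * sum_u 1/d(v, u)`` with unreachable pairs
    contributing 0, so the value is well defined on disconnected graphs.
    """
    _require_nonempty(graph)
    nodes = list(graph.nodes())
    if len(nodes) == 1:
        return {nodes[0]: 0.0}
    values = _to_igraph(graph, nodes).harmonic_centrality(normalized=True)
    return dict(zip(nodes, values))


def global_clustering_coefficient(graph: nx.Graph) -> float:
    """Transitivity: 3 x triangles / connected triplets; 0 if no triplet."""
    _require_nonempty(graph)
    nodes = list(graph.nodes())
    return float(_to_igraph(graph, nodes).transitivity_undirected(mode="zero"))


def degree_centralization(graph: nx.Graph) -> float:
    """Freeman degree centralization: 0 for regular graphs, 1 for a star."""
    _require_nonempty(graph)
    n = graph.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = [d for _, d in graph.degree()]
    dmax = max(degrees)
    return sum(dmax - d for d in degrees) / ((n - 1) * (n - 2))


def network_profile(graph: nx.Graph, degree_aggregate: DegreeAggregate = "sum") -> NetworkProfile:
    """Compute all five graph-level network properties for one graph state."""
    _require_nonempty(graph)
    if degree_aggregate == "sum":
        dc = float(degree_sum(graph))
    elif degree_aggregate == "centralization":
        dc = degree_centralization(graph)
    else:
        raise ValueError(f"unknown degree_aggregate mode {degree_aggregate!r}")
    ec = eigenvector_centrality(graph)
    bc = betweenness_centrality(graph)
    cc = harmonic_closeness(graph)
    return NetworkProfile(
        dc=dc,
        ec=float(np.mean(list(ec.values()))),
        bc=float(np.mean(list(bc.values()))),
        cc=float(np.mean(list(cc.values()))),
        gcc=global_clustering_coefficient(graph),
    )
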