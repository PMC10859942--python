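"""Synthetic interactomes with controlled hub structure, plus toy graphs.

No aggregate interactome is bundled with the package, so testing and
demonstration rely on generated networks that emulate the topology of a
crosslinked-aggregate interactome: a heavy-tailed degree distribution from
preferential attachment, a handful of planted hubs boosted into a chosen
degree band (the mega/major/midi/mini hub bins), and uniform noise edges.
The generator returns the planted hub identifiers so recovery of known
influential proteins can be evaluated.  Topology only -- no attempt is made
to model crosslink-detection chemistry or false-positive interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from looa.errors import ParameterError


@dataclass(frozen=True)
class HubGraphSpec:
    """Recipe for one synthetic hub-structured interactome.

    Attributes
    ----------
    n_vertices : int
        Total number of proteins.
    n_planted_hubs : int
        How many vertices are boosted into the hub degree band.
    hub_degree_range : (int, int)
        Inclusive interaction-count band for planted hubs, e.g. (50, 99)
        for major hubs.
    attachment_exponent : float
        Preferential-attachment strength: new vertices attach with
        probability proportional to ``(degree + 1) ** exponent``.  0 gives a
        flat (no heavy tail) network; 1 the classic linear rich-get-richer.
    noise_edges : int
        Uniform random extra edges added last.
    seed : int
        Random seed; the graph is a deterministic function of the spec.
    edges_per_vertex : int
        Edges each newly added vertex brings (the attachment count m).
    """

    n_vertices: int
    n_planted_hubs: int = 0
    hub_degree_range: tuple[int, int] = (50, 99)
    attachment_exponent: float = 1.0
    noise_edges: int = 0
    seed: int = 0
    edges_per_vertex: int = 3

    def validate(self) -> None:
        lo, hi = self.hub_degree_range
        if self.n_vertices < 3:
            raise ParameterError("need at least 3 vertices")
        if not 0 <= self.n_planted_hubs < self.n_vertices:
            raise ParameterError("n_planted_hubs must be in [0, n_vertices)")
        if not 1 <= lo <= hi <= self.n_vertices - 1:
            raise ParameterError(
                f"hub_degree_range {self.hub_degree_range} not within [1, {self.n_vertices - 1}]"
            )
        if self.attachment_exponent < 0:
            raise ParameterError("attachment_exponent must be >= 0")
        if self.noise_edges < 0:
            raise ParameterError("noise_edges must be >= 0")
        if not 1 <= self.edges_per_vertex < self.n_vertices:
            raise ParameterError("edges_per_vertex must be in [1, n_vertices)")


def _vertex_name(i: int) -> str:
    return f"P{i:04d}"


def generate_hub_graph(spec: HubGraphSpec) -> tuple[nx.Graph, list[str]]:
    """Grow a synthetic interactome and plant hubs; returns (graph, hubs).

    Growth: vertices arrive one at a time and attach to ``edges_per_vertex``
    distinct existing vertices with probability proportional to
    ``(degree + 1) ** attachment_exponent`` (the +1 smoothing lets the first
    vertices ever be chosen).  Planted hubs are then drawn uniformly and each
    receives random extra edges until its degree reaches a target drawn from
    ``hub_degree_range``; finally ``noise_edges`` uniform non-duplicate
    edges are added.  Deterministic given the spec (including seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_vertices, spec.edges_per_vertex
    names = [_vertex_name(i) for i in range(n)]

    graph = nx.Graph()
    # seed nucleus: a chain of m+1 vertices so every early vertex has an edge
    nucleus = min(m + 1, n)
    graph.add_nodes_from(names[:nucleus])
    for i in range(nucleus - 1):
        graph.add_edge(names[i], names[i + 1])

    degrees = np.zeros(n, dtype=float)
    for i in range(nucleus - 1):
        degrees[i] += 1
        degrees[i + 1] += 1

    for i in range(nucleus, n):
        existing = i
        weights = (degrees[:existing] + 1.0) ** spec.attachment_exponent
        k = min(m, existing)
        targets = rng.choice(existing, size=k, replace=False, p=weights / weights.sum())
        graph.add_node(names[i])
        for t in targets:
            graph.add_edge(names[i], names[int(t)])
            degrees[int(t)] += 1
            degrees[i] += 1

    hubs: list[str] = []
    if spec.n_planted_hubs:
        lo, hi = spec.hub_degree_range
        hub_idx = rng.choice(n, size=spec.n_planted_hubs, replace=False)
        hubs = sorted(names[int(i)] for i in hub_idx)
        for hub in hubs:
            target = int(rng.integers(lo, hi + 1))
            candidates = [v for v in names if v != hub and not graph.has_edge(hub, v)]
            while graph.degree(hub) < target and candidates:
                pick = int(rng.integers(len(candidates)))
                graph.add_edge(hub, candidates.pop(pick))

    attempts = 0
    added = 0
    while added < spec.noise_edges and attempts < 100 * max(spec.noise_edges, 1):
        u, v = rng.integers(n), rng.integers(n)
        attempts += 1
        if u == v or graph.has_edge(names[int(u)], names[int(v)]):
            continue
        graph.add_edge(names[int(u)], names[int(v)])
        added += 1

    return graph, hubs


def toy_graphs() -> dict[str, nx.Graph]:
    """Canonical known-answer graphs used across the test suite and examples.

    Keys: ``triangle``, ``path3``, ``star4`` (center C, leaves L1-L4),
    ``c6``, ``k5``, ``two_triangles`` (disconnected), ``barbell`` (two K5s
    joined by a single bridge edge), and three seeded 12-vertex random
    graphs ``random12_0 .. random12_2``.
    """
    graphs: dict[str, nx.Graph] = {}
    graphs["triangle"] = nx.cycle_graph(["A", "B", "C"])
    graphs["path3"] = nx.path_graph(["A", "B", "C"])
    star = nx.Graph()
    star.add_edges_from(("C", f"L{i}") for i in range(1, 5))
    graphs["star4"] = star
    graphs["c6"] = nx.cycle_graph([f"N{i}" for i in range(6)])
    graphs["k5"] = nx.complete_graph([f"N{i}" for i in range(5)])
    two = nx.Graph()
    two.add_edges_from([("A", "B"), ("B", "C"), ("C", "A"), ("D", "E"), ("E", "F"), ("F", "D")])
    graphs["two_triangles"] = two
    barbell = nx.Graph()
    left = [f"L{i}" for i in range(5)]
    right = [f"R{i}" for i in range(5)]
    for clique in (left, right):
        barbell.add_edges_from(nx.complete_graph(clique).edges())
    barbell.add_edge("L0", "R0")
    graphs["barbell"] = barbell
    for s in range(3):
        g = nx.gnp_random_graph(12, 0.3, seed=100 + s)
        g.remove_nodes_from(list(nx.isolates(g)))
        graphs[f"random12_{s}"] = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
    return graphs
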