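"""Exhaustive single-element knockouts: LOVO and LOEO delta matrices.

For every vertex (LOVO) or edge (LOEO) the element is removed, the five
network properties are recomputed on the reduced graph, and the influence
row is ``delta_NP = NP_initial - NP_after`` -- positive entries mean the
removal reduced that descriptor.  Recomputation is exact (a full profile per
deletion) rather than incremental; at the scale of aggregate interactomes
(thousands of vertices, tens of thousands of edges) the O(elements x V x E)
cost of exactness is affordable and avoids the bookkeeping of incremental
betweenness maintenance.

The result is a :class:`pandas.DataFrame` with one row per removed element
(index name ``element``) and the five columns ``dDC, dEC, dBC, dCC, dGCC``.
LOVO rows are labelled by protein identifier; LOEO rows by the pair label
``A---B`` with endpoints in lexicographic order.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from looa.errors import GraphSizeError
from looa.metrics import DegreeAggregate, NetworkProfile, network_profile

logger = logging.getLogger(__name__)

#: Delta-matrix column names, in profile-field order.
DELTA_COLUMNS = ("dDC", "dEC", "dBC", "dCC", "dGCC")

#: Separator used to build LOEO edge labels.
EDGE_LABEL_SEP = "---"


def edge_label(u, v) -> str:
    """Canonical label for an undirected edge: endpoints sorted, joined by ---."""
    a, b = sorted((str(u), str(v)))
    return f"{a}{EDGE_LABEL_SEP}{b}"


def _delta_frame(labels: list[str], rows: list[np.ndarray]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, index=pd.Index(labels, name="element"), columns=list(DELTA_COLUMNS))
    return frame.sort_index()


def lovo_deltas(graph: nx.Graph, degree_aggregate: DegreeAggregate = "sum") -> pd.DataFrame:
    """Leave-one-vertex-out influence matrix.

    Removing vertex ``v`` also removes its incident edges; neighbours whose
    degree drops to 0 stay in the reduced graph (they are still observed
    proteins) and contribute 0 to the centrality means.  In ``sum`` mode the
    ``dDC`` entry for ``v`` is exactly ``2 * deg(v)``.

    Raises
    ------
    GraphSizeError
        If the graph has fewer than 3 vertices.
    """
    if graph.number_of_nodes() < 3:
        raise GraphSizeError("LOVO requires at least 3 vertices")
    baseline = network_profile(graph, degree_aggregate).as_array()
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for vertex in graph.nodes():
        reduced = graph.copy()
        reduced.remove_node(vertex)
        after = network_profile(reduced, degree_aggregate).as_array()
        labels.append(str(vertex))
        rows.append(baseline - after)
    return _delta_frame(labels, rows)


def loeo_deltas(graph: nx.Graph, degree_aggregate: DegreeAggregate = "sum") -> pd.DataFrame:
    """Leave-one-edge-out influence matrix.

    The vertex set is unchanged by an edge removal: endpoints persist even if
    their degree drops to 0.  In ``sum`` mode every ``dDC`` entry is exactly 2.

    Raises
    ------
    GraphSizeError
        If the graph has fewer than 2 edges.
    """
    if graph.number_of_edges() < 2:
        raise GraphSizeError("LOEO requires at least 2 edges")
    baseline = network_profile(graph, degree_aggregate).as_array()
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for u, v in graph.edges():
        reduced = graph.copy()
        reduced.remove_edge(u, v)
        after = network_profile(reduced, degree_aggregate).as_array()
        labels.append(edge_label(u, v))
        rows.append(baseline - after)
    return _delta_frame(labels, rows)


def influence_ratio(delta: pd.DataFrame, baseline: NetworkProfile) -> pd.DataFrame:
    """Optional rescaling of deltas to fractions of the initial profile.

    Each column is divided by the corresponding initial network-property
    value, reading influence as "the factor by which deletion reduces" the
    descriptor.  Columns whose baseline is 0 cannot be rescaled and pass
    through as raw deltas with a warning.
    """
    scaled = delta.copy()
    for column, value in zip(delta.columns, baseline.as_array()):
        if value == 0.0:
            logger.warning("baseline %s is 0; column kept as raw delta", column)
            continue
        scaled[column] = delta[column] / value
    return scaled
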