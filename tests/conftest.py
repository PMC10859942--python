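import networkx as nx
import numpy as np
import pandas as pd
import pytest

from looa.fixtures import toy_graphs


@pytest.fixture(scope="session")
def toys() -> dict[str, nx.Graph]:
    return toy_graphs()


def random_connected_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """A random connected graph with string labels and 3..n_max vertices."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """A random (possibly disconnected) graph with no isolated vertices."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.2, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_edges() >= 2:
            return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})


def random_delta_matrix(rng: np.random.Generator) -> pd.DataFrame:
    """A random well-conditioned 5-column delta matrix (not graph-derived)."""
    n = int(rng.integers(10, 41))
    base = rng.normal(size=(n, 2))
    mix = rng.normal(size=(2, 5))
    data = base @ mix + 0.5 * rng.normal(size=(n, 5))
    return pd.DataFrame(
        data,
        index=pd.Index([f"E{i:03d}" for i in range(n)], name="element"),
        columns=["dDC", "dEC", "dBC", "dCC", "dGCC"],
    )
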