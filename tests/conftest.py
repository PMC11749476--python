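"""Shared fixtures: tiny hand-built graphs and the desk-scale synthetic bundle."""

from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from ahgscreen import PPINetwork, build_transition_matrix, toy_config
from ahgscreen.synthetic import generate_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def path_net() -> PPINetwork:
    """Unweighted path A - B - C."""
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net() -> PPINetwork:
    """Star with center H and leaves L1..L3."""
    return PPINetwork.from_edges([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def weighted_edges_path() -> Path:
    return DATA_DIR / "edges_weighted.tsv"


def random_connected_network(n: int, seed: int, weighted: bool = False) -> PPINetwork:
    """Independent random connected graph (preferential attachment + optional weights)."""
    g = nx.barabasi_albert_graph(n, 2, seed=seed)
    rng = np.random.default_rng(seed)
    edges = [
        (f"N{a:04d}", f"N{b:04d}", float(rng.uniform(0.2, 1.0)) if weighted else 1.0)
        for a, b in g.edges
    ]
    return PPINetwork.from_edges(edges)


def dense_rwr_oracle(net: PPINetwork, seeds: list[str], r: float) -> dict[str, float]:
    """Closed-form steady state computed directly with numpy.

    Deliberately re-derives the walk matrix from the edge list instead of
    using the package's TransitionMatrix, so it is an independent check of
    both the normalization and the iteration.
    """
    nodes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b, w in net.edges():
        adj[idx[a], idx[b]] = w
        adj[idx[b], idx[a]] = w
    walk = adj / adj.sum(axis=0, keepdims=True)
    p0 = np.zeros(n)
    present = [s for s in seeds if s in idx]
    p0[[idx[s] for s in present]] = 1.0 / len(present)
    p_star = r * np.linalg.solve(np.eye(n) - (1 - r) * walk, p0)
    return dict(zip(nodes, p_star))


@pytest.fixture(scope="session")
def toy_bundle():
    """Default toy preset, seed 0."""
    return generate_fixture(toy_config(rng_seed=0))
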