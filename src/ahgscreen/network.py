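"""Protein-protein interaction network input, validation and walk-matrix construction.

A PPI network is an undirected gene graph with non-negative edge weights
(confidence scores where the source database provides them, 1 otherwise).
Propagation requires a connected graph, so callers extract the largest
connected component before building the column-stochastic transition matrix
used by the random walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "PPINetwork",
    "TransitionMatrix",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "build_transition_matrix",
    "read_gene_list",
    "read_ortholog_map",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol: strip surrounding space, upper-case.

    Symbols are compared case-insensitively throughout; internal whitespace
    is rejected because it indicates a mis-split input line.
    """
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in sym):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return sym


class PPINetwork:
    """Undirected gene graph with weighted edges.

    Nodes are upper-cased gene symbols; the node ordering used everywhere
    downstream (seed vectors, transition matrices, exports) is the sorted
    symbol order, so results are independent of input row order.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] | None = None,
    ) -> "PPINetwork":
        """Build a canonical network from ``(gene_a, gene_b[, weight])`` tuples.

        Self-loops are dropped with a warning; duplicate pairs are merged
        keeping the maximum weight. Extra ``nodes`` may be supplied to keep
        isolated genes in the graph.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(normalize_symbol(n) for n in nodes)
        for edge in edges:
            if len(edge) == 2:
                a, b = edge
                w = 1.0
            else:
                a, b, w = edge
                w = float(w)
            if w < 0:
                raise ValueError(f"negative edge weight {w} on ({a}, {b})")
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                logger.warning("dropping self-loop on gene %s", a)
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._graph.nodes))

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Canonical edge list: pairs ordered within and across rows."""
        out = []
        for a, b, data in self._graph.edges(data=True):
            a, b = (a, b) if a <= b else (b, a)
            out.append((a, b, float(data.get("weight", 1.0))))
        out.sort()
        return out

    def has_node(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._graph

    def degree(self, gene: str) -> int:
        return self._graph.degree[normalize_symbol(gene)]

    def neighbors(self, gene: str) -> tuple[str, ...]:
        return tuple(sorted(self._graph.neighbors(normalize_symbol(gene))))

    def relabel(self, mapping: Mapping[str, str]) -> "PPINetwork":
        """Rename genes through a symbol map (e.g. species -> human orthologs).

        Unmapped symbols pass through unchanged; if two source genes collapse
        onto one target the merged node keeps the maximum weight per edge.
        """
        full = {n: normalize_symbol(mapping.get(n, n)) for n in self._graph.nodes}
        edges = [(full[a], full[b], w) for a, b, w in self.edges() if full[a] != full[b]]
        nodes = set(full.values())
        return PPINetwork.from_edges(edges, nodes=nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def read_edge_list(path: str | Path, min_weight: float = 0.0) -> PPINetwork:
    """Read a TSV edge list ``gene_a<TAB>gene_b[<TAB>weight]``.

    Lines starting with ``#`` and blank lines are ignored. Edges whose weight
    falls below ``min_weight`` are dropped; duplicate pairs keep the maximum
    weight. Raises :class:`EdgeListError` naming the offending line on
    malformed input, or if no edge survives.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise EdgeListError(
                    f"{path}:{lineno}: expected 2-3 tab-separated fields, got {len(fields)}"
                )
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w < min_weight:
                continue
            edges.append((fields[0], fields[1], w))
    if not edges:
        raise EdgeListError(f"{path}: no edges at or above weight {min_weight}")
    return PPINetwork.from_edges(edges)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the canonical (sorted, deduplicated) edge list as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")  # repr round-trips float weights exactly


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest connected component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest gene. The steady state of a restart walk is
    only well defined within one component, so propagation always runs here;
    dropped genes are reported by the caller with affinity 0.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot take the largest component of an empty network")
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = components[0]
    dropped = net.n_nodes - len(keep)
    if dropped:
        logger.info("largest component keeps %d nodes, drops %d", len(keep), dropped)
    return PPINetwork(net.graph.subgraph(keep).copy())


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic walk matrix over a fixed node ordering.

    ``matrix[i, j]`` is the probability of stepping from gene ``j`` (column)
    to gene ``i`` (row): edge weight divided by the total incident weight of
    ``j``. Columns sum to 1, which makes the walk mass-conserving.
    """

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_transition_matrix(
    net: PPINetwork, normalization: str = "column"
) -> TransitionMatrix:
    """Build the walk matrix W from a connected network.

    ``normalization="column"`` (default) gives W = A D^-1, the standard
    per-source degree normalization for restart walks; ``"symmetric"`` gives
    D^-1/2 A D^-1/2, which is not column-stochastic and is provided only for
    comparison runs.
    """
    if net.n_nodes < 2:
        raise ValueError("transition matrix requires at least 2 nodes")
    if not nx.is_connected(net.graph):
        raise ValueError(
            "network is not connected; take largest_connected_component first"
        )
    nodes = net.nodes
    adj = nx.to_scipy_sparse_array(
        net.graph, nodelist=list(nodes), weight="weight", format="csc", dtype=float
    )
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        raise ValueError(f"gene {nodes[zero[0]]} has zero total incident weight")
    if normalization == "column":
        w = adj @ sp.diags(1.0 / col_sums)
    elif normalization == "symmetric":
        d = sp.diags(1.0 / np.sqrt(col_sums))
        w = d @ adj @ d
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return TransitionMatrix(matrix=sp.csr_matrix(w), nodes=nodes)


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(normalize_symbol(line))
    return tuple(sorted(genes))


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``source_symbol<TAB>human_symbol``."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            mapping[normalize_symbol(fields[0])] = normalize_symbol(fields[1])
    return mapping
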