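"""Protein-protein interaction networks: containers, I/O, splits and synthesis.

A PPI network is an undirected simple graph G = (V, E) over a fixed, ordered
set of protein identifiers.  All matrices downstream (adjacency, evolved
matrix, transition matrix, score matrix) share that node order; indices are
0-based internally while file formats always carry the protein ID strings.

The "golden standard" network is split into a deliberately sparse training
network G_tn — which is typically *disconnected* — and a held-out test edge
set G_tt.  The split keeps the full node set on the training side so that
isolated proteins remain visible as size-1 components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

Edge = tuple[int, int]

__all__ = [
    "ProteinNetwork",
    "AdjacencyMatrix",
    "EdgeSplit",
    "ComponentSummary",
    "read_edge_list",
    "write_edge_list",
    "network_from_edges",
    "to_adjacency",
    "adjacency_to_network",
    "component_summary",
    "split_golden_standard",
    "generate_synthetic_ppi",
]


def _canonical(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class ProteinNetwork:
    """An undirected simple graph over an ordered set of protein IDs.

    Parameters
    ----------
    nodes : tuple of str
        Unique protein identifiers; the order is the canonical node order
        shared by every matrix derived from this network.
    edges : frozenset of (int, int)
        Unordered node-index pairs stored once each with ``i < j``;
        self-pairs are forbidden.
    """

    nodes: tuple[str, ...]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        m = len(self.nodes)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-pair ({i},{i}) not allowed")
            if not (0 <= i < j < m):
                raise ValueError(f"edge ({i},{j}) out of range or not canonical")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbor_sets(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return nbrs

    def to_networkx(self) -> nx.Graph:
        """Graph over node *indices*, including isolated nodes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def replace_edges(self, edges: Iterable[Edge]) -> "ProteinNetwork":
        return ProteinNetwork(self.nodes, frozenset(_canonical(i, j) for i, j in edges))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal plus its node order."""

    values: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.node_order):
            raise ValueError("adjacency size does not match node order")
        object.__setattr__(self, "values", a)


@dataclass(frozen=True)
class ComponentSummary:
    """Connected-component census: count and (min, mean, max) component size."""

    count: int
    min_size: int
    max_size: int
    mean_size: float

    def as_triple(self) -> tuple[int, float, int]:
        """(minC, avgC, maxC) triple as usually tabulated."""
        return (self.min_size, self.mean_size, self.max_size)


@dataclass(frozen=True)
class EdgeSplit:
    """Partition of a golden-standard edge set into G_tn and G_tt.

    ``training`` keeps the full node set; ``test_edges`` are the held-out
    pairs.  ``|training.edges| = floor(ratio_cap * |E|)`` so the achieved
    training fraction never exceeds the cap.
    """

    training: ProteinNetwork
    test_edges: frozenset[Edge]
    ratio_cap: float
    seed: int

    @property
    def all_edges(self) -> frozenset[Edge]:
        return self.training.edges | self.test_edges

    def full_network(self) -> ProteinNetwork:
        return self.training.replace_edges(self.all_edges)


def network_from_edges(
    node_ids: Sequence[str], pairs: Iterable[tuple[str, str] | Edge]
) -> ProteinNetwork:
    """Build a network from ID pairs or index pairs, dropping self-pairs."""
    nodes = tuple(node_ids)
    index = {n: k for k, n in enumerate(nodes)}
    edges: set[Edge] = set()
    for a, b in pairs:
        i = index[a] if isinstance(a, str) else int(a)
        j = index[b] if isinstance(b, str) else int(b)
        if i == j:
            continue
        edges.add(_canonical(i, j))
    return ProteinNetwork(nodes, frozenset(edges))


def read_edge_list(path: str | Path) -> ProteinNetwork:
    """Read a two-column tab-separated edge list.

    Lines starting with ``#`` and blank lines are ignored.  Self-interactions
    are dropped and duplicate edges (either orientation) collapsed; node
    order is first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    nodes: list[str] = []
    index: dict[str, int] = {}
    edges: set[Edge] = set()

    def node_id(name: str) -> int:
        if name not in index:
            index[name] = len(nodes)
            nodes.append(name)
        return index[name]

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            i, j = node_id(fields[0]), node_id(fields[1])
            if i == j:
                continue  # self-interaction removed; node is kept
            edges.add(_canonical(i, j))
    return ProteinNetwork(tuple(nodes), frozenset(edges))


def write_edge_list(net: ProteinNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\n")


def to_adjacency(net: ProteinNetwork) -> AdjacencyMatrix:
    """Dense binary adjacency A with A[i,j]=1 iff (i,j) in E."""
    m = net.n_nodes
    a = np.zeros((m, m), dtype=float)
    for i, j in net.edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    return AdjacencyMatrix(a, net.nodes)


def adjacency_to_network(adj: AdjacencyMatrix) -> ProteinNetwork:
    """Extract the edge set back out of a binary adjacency matrix."""
    ii, jj = np.nonzero(np.triu(adj.values, 1))
    return ProteinNetwork(
        tuple(adj.node_order), frozenset(zip(ii.tolist(), jj.tolist()))
    )


def component_summary(net: ProteinNetwork) -> ComponentSummary:
    """Census of connected components over *all* nodes.

    Isolated proteins count as size-1 components, which is why a sparse
    training network's minimum component size is typically 1.
    """
    if net.n_nodes == 0:
        raise ValueError("component summary of an empty node set")
    sizes = [len(c) for c in nx.connected_components(net.to_networkx())]
    return ComponentSummary(
        count=len(sizes),
        min_size=min(sizes),
        max_size=max(sizes),
        mean_size=float(np.mean(sizes)),
    )


def split_golden_standard(
    net: ProteinNetwork, ratio_cap: float, seed: int
) -> EdgeSplit:
    """Split E into training edges G_tn and test edges G_tt.

    Exactly ``floor(ratio_cap * |E|)`` edges are sampled uniformly without
    replacement (seeded) into the training network, which therefore never
    exceeds the cap and is typically sparse and disconnected.  The node set
    is unchanged on both sides.
    """
    if not 0.0 < ratio_cap < 1.0:
        raise ValueError(f"ratio_cap must be in (0,1), got {ratio_cap}")
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to split")
    all_edges = sorted(net.edges)
    n_train = math.floor(ratio_cap * len(all_edges))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_edges), size=n_train, replace=False)
    chosen = {all_edges[k] for k in idx.tolist()}
    training = net.replace_edges(chosen)
    test = frozenset(net.edges - chosen)
    return EdgeSplit(training=training, test_edges=test, ratio_cap=ratio_cap, seed=seed)


def generate_synthetic_ppi(
    n: int,
    retention_prob: float = 0.4,
    attach_prob: float = 0.1,
    seed: int = 0,
) -> ProteinNetwork:
    """Duplication-divergence synthetic PPI network.

    Starting from a connected 3-node seed triangle, repeatedly pick a random
    existing node, duplicate it, retain each of the parent's edges on the
    duplicate with probability ``retention_prob``, and link duplicate to
    parent with probability ``attach_prob``.  The process yields the
    right-skewed (heavy-tailed) degree distributions characteristic of real
    interactomes, and is fully deterministic under ``seed``.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    for name, p in (("retention_prob", retention_prob), ("attach_prob", attach_prob)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0,1), got {p}")
    rng = np.random.default_rng(seed)
    nbrs: list[set[int]] = [{1, 2}, {0, 2}, {0, 1}]
    for v in range(3, n):
        u = int(rng.integers(0, v))
        nbrs.append(set())
        for w in sorted(nbrs[u]):
            if rng.random() < retention_prob:
                nbrs[v].add(w)
                nbrs[w].add(v)
        if rng.random() < attach_prob:
            nbrs[v].add(u)
            nbrs[u].add(v)
    edges = frozenset(
        (i, j) for i in range(n) for j in nbrs[i] if i < j
    )
    width = max(4, len(str(n - 1)))
    nodes = tuple(f"P{i:0{width}d}" for i in range(n))
    return ProteinNetwork(nodes, edges)
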