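"""Multiplex network domain types, edge-list I/O, and per-layer statistics.

A multiplex network is an ordered collection of layers over one shared node
universe: every layer has the same N nodes (isolated nodes are kept) but its
own set of undirected, unweighted intra-layer edges.  Node labels from input
files are normalized to a contiguous internal index 0..N-1; the label map is
kept on the network so files written back use the original labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


def normalize_pair(u: int, v: int) -> Pair:
    """Canonical unordered pair (min, max)."""
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class LayerGraph:
    """One layer's topology: an undirected simple graph.

    ``nodes`` is the full (shared) node universe, so isolated nodes are
    represented; ``edges`` holds canonical (min, max) pairs.
    """

    nodes: tuple[int, ...]
    edges: frozenset[Pair]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if u > v:
                raise ValueError(f"edge ({u},{v}) not in canonical (min,max) order")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u},{v}) has endpoint outside node set")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]],
                   nodes: Iterable[int] | None = None) -> "LayerGraph":
        canon = frozenset(normalize_pair(u, v) for u, v in edges if u != v)
        if nodes is None:
            node_set: set[int] = set()
            for u, v in canon:
                node_set.update((u, v))
            nodes = node_set
        return cls(nodes=tuple(sorted(nodes)), edges=canon)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> frozenset[int]:
        return self._adjacency().get(i, frozenset())

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def degrees(self) -> dict[int, int]:
        adj = self._adjacency()
        return {i: len(adj.get(i, ())) for i in self.nodes}

    def has_edge(self, u: int, v: int) -> bool:
        return normalize_pair(u, v) in self.edges

    def all_pairs(self) -> list[Pair]:
        return list(combinations(self.nodes, 2))

    def non_edges(self) -> list[Pair]:
        return [p for p in combinations(self.nodes, 2) if p not in self.edges]

    def _adjacency(self) -> dict[int, frozenset[int]]:
        cached = getattr(self, "_adj_cache", None)
        if cached is None:
            adj: dict[int, set[int]] = {i: set() for i in self.nodes}
            for u, v in self.edges:
                adj[u].add(v)
                adj[v].add(u)
            cached = {i: frozenset(s) for i, s in adj.items()}
            object.__setattr__(self, "_adj_cache", cached)
        return cached

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "LayerGraph":
        return cls.from_edges(g.edges(), nodes=g.nodes())


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered layers over a shared node universe of size N.

    ``node_labels[i]`` is the original external label of internal node i;
    layers store internal ids 0..N-1.
    """

    layers: tuple[LayerGraph, ...]
    layer_names: tuple[str, ...] = ()
    node_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("a multiplex network needs at least one layer")
        universe = self.layers[0].nodes
        for k, layer in enumerate(self.layers):
            if layer.nodes != universe:
                raise ValueError(f"layer {k} does not share the node universe")
        if not self.layer_names:
            object.__setattr__(
                self, "layer_names",
                tuple(str(k + 1) for k in range(len(self.layers))))
        if len(self.layer_names) != len(self.layers):
            raise ValueError("one name per layer required")
        if not self.node_labels:
            object.__setattr__(self, "node_labels", tuple(universe))
        if len(self.node_labels) != len(universe):
            raise ValueError("one label per node required")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def nodes(self) -> tuple[int, ...]:
        return self.layers[0].nodes

    def densest_layer(self) -> int:
        """Index of the layer with the highest density (ties: first)."""
        return int(np.argmax([layer.n_edges for layer in self.layers]))


@dataclass(frozen=True)
class GraphStats:
    """Descriptive statistics of one layer."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    heterogeneity: float
    mean_clustering: float


def layer_stats(g: LayerGraph) -> GraphStats:
    """Compute N, E, mean degree 2E/N, density 2E/(N(N-1)), degree
    heterogeneity <k^2>/<k>^2 and mean local clustering.

    Nodes with degree < 2 contribute 0 to the clustering average.
    Heterogeneity is NaN for edgeless graphs (<k> = 0).
    """
    n, e = g.n_nodes, g.n_edges
    if n < 2:
        raise ValueError("layer_stats requires at least 2 nodes")
    k = np.array([g.degree(i) for i in g.nodes], dtype=float)
    mean_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1))
    heterogeneity = float(np.mean(k**2) / np.mean(k) ** 2) if e > 0 else float("nan")
    mean_clustering = float(nx.average_clustering(g.to_networkx(), count_zeros=True))
    return GraphStats(n, e, mean_degree, density, heterogeneity, mean_clustering)


def truncate(x: float, decimals: int) -> float:
    """Truncate (not round) toward zero to the given number of decimals."""
    factor = 10**decimals
    return np.trunc(x * factor) / factor


# ---------------------------------------------------------------------------
# Edge-list I/O
#
# Canonical dialect: whitespace-separated "layer u v" records, one intra-layer
# edge per line, u < v, sorted by (layer, u, v); '#' lines are comments.  A
# 4-column "layer u v weight" dialect is accepted on read (weight validated as
# a number, then discarded).  Two structured comments allow lossless
# round-trips of isolated nodes and empty layers:
#     #nodes: <label> <label> ...
#     #layers: <name> <name> ...
# ---------------------------------------------------------------------------


def read_multiplex(path: str, dialect: str = "auto") -> MultiplexNetwork:
    """Read a multiplex edge list.

    ``dialect`` is one of ``auto`` (accept 3- or 4-column records), ``canonical``
    (exactly 3 columns) or ``weighted`` (exactly 4).  Duplicate records and
    self-loops are dropped with a logged count; edges are undirected.
    """
    if dialect not in ("auto", "canonical", "weighted"):
        raise ValueError(f"unknown dialect {dialect!r}")
    declared_nodes: list[int] = []
    declared_layers: list[str] = []
    records: list[tuple[int, int, int]] = []
    n_dropped = 0
    seen: set[tuple[int, Pair]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("nodes:"):
                    declared_nodes = [int(tok) for tok in body[len("nodes:"):].split()]
                elif body.startswith("layers:"):
                    declared_layers = body[len("layers:"):].split()
                continue
            parts = line.split()
            if dialect == "canonical" and len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            if dialect == "weighted" and len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
            try:
                layer, u, v = int(parts[0]), int(parts[1]), int(parts[2])
                if len(parts) == 4:
                    float(parts[3])  # weight: validated, then ignored
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
            if u == v:
                # the node still joins the universe, isolated
                declared_nodes.append(u)
                n_dropped += 1
                continue
            key = (layer, normalize_pair(u, v))
            if key in seen:
                n_dropped += 1
                continue
            seen.add(key)
            records.append((layer, u, v))
    if not records and not declared_nodes:
        raise ValueError(f"{path}: no edge records found")
    if n_dropped:
        logger.warning("%s: dropped %d duplicate/self-loop records", path, n_dropped)

    labels = sorted({u for _, u, v in records} | {v for _, u, v in records}
                    | set(declared_nodes))
    index = {lab: i for i, lab in enumerate(labels)}
    layer_ids = sorted({layer for layer, _, _ in records})
    if declared_layers:
        known = [name for name in declared_layers]
        for lid in layer_ids:
            if str(lid) not in known:
                known.append(str(lid))
        layer_names = tuple(known)
    else:
        layer_names = tuple(str(lid) for lid in layer_ids)
    per_layer: dict[str, set[Pair]] = {name: set() for name in layer_names}
    for layer, u, v in records:
        per_layer[str(layer)].add(normalize_pair(index[u], index[v]))
    universe = tuple(range(len(labels)))
    layers = tuple(
        LayerGraph(nodes=universe, edges=frozenset(per_layer[name]))
        for name in layer_names)
    return MultiplexNetwork(layers=layers, layer_names=layer_names,
                            node_labels=tuple(labels))


def write_multiplex(net: MultiplexNetwork, path: str,
                    header_lines: Sequence[str] = ()) -> None:
    """Write the canonical "layer u v" dialect: u < v by external label,
    records sorted by (layer, u, v).  Deterministic byte output."""
    labels = net.node_labels
    lines: list[str] = []
    for extra in header_lines:
        lines.append(f"# {extra}")
    lines.append("#nodes: " + " ".join(str(lab) for lab in labels))
    lines.append("#layers: " + " ".join(net.layer_names))
    for name, layer in zip(net.layer_names, net.layers):
        recs = sorted(normalize_pair(labels[u], labels[v]) for u, v in layer.edges)
        for u, v in recs:
            lines.append(f"{name} {u} {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
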