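"""The undirected gene–gene interaction network and its distance queries.

An interactome is represented as a plain :class:`networkx.Graph` whose nodes
are uppercase gene symbols and whose edges are unweighted physical/functional
interactions.  All proximity statistics in this package are hop counts on this
graph.  The module also provides the degree binning used by the
degree-matched randomization null: nodes are grouped into contiguous,
ascending degree ranges so that surrogate nodes can be drawn with the same
connectivity as the nodes they replace.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DegreeBins",
    "load_edge_list",
    "save_edge_list",
    "largest_connected_component",
    "shortest_distances",
    "degree_bins",
    "default_min_bin_size",
]


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def load_edge_list(path, drop_self_loops: bool = True) -> nx.Graph:
    """Read a two-column whitespace-separated edge list into a simple graph.

    Lines starting with ``#`` are comments; columns beyond the second are
    ignored.  Gene symbols are stripped and uppercased.  Duplicate edges
    (including reversed duplicates) collapse; self-loops are dropped when
    ``drop_self_loops`` is set, otherwise rejected.

    Raises
    ------
    ValueError
        If the file contains no edges, or a non-comment line has fewer than
        two fields (the message carries the 1-based line number).
    """
    g = nx.Graph()
    n_edges = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: malformed edge on line {lineno}: {line!r}"
                )
            a, b = _normalize(fields[0]), _normalize(fields[1])
            if a == b:
                if drop_self_loops:
                    continue
                raise ValueError(
                    f"{path}: self-loop {a!r} on line {lineno} "
                    "(pass drop_self_loops=True to ignore)"
                )
            g.add_edge(a, b)
            n_edges += 1
    if n_edges == 0:
        raise ValueError(f"{path}: no edges")
    return g


def save_edge_list(g: nx.Graph, path) -> None:
    """Write the graph as a sorted two-column edge list (round-trips with
    :func:`load_edge_list`)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken in favour of the one
    containing the lexicographically smallest node, so the result is
    deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no connected component")
    components = list(nx.connected_components(g))
    largest = max(len(c) for c in components)
    best = min((c for c in components if len(c) == largest), key=min)
    return g.subgraph(best).copy()


def shortest_distances(g: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS hop distances from ``sources`` to every reachable node.

    Every source present in the graph gets distance 0; nodes unreachable from
    all sources are absent from the mapping (callers treat them as infinite).
    Sources not present in the graph are silently ignored, but at least one
    must map.
    """
    adj = g._adj  # plain dict-of-dict adjacency; hot path for the null model
    dist: dict[str, int] = {s: 0 for s in sources if s in adj}
    if not dist:
        raise ValueError("no source gene present in the interactome")
    queue = deque(dist)
    while queue:
        node = queue.popleft()
        d1 = dist[node] + 1
        for nbr in adj[node]:
            if nbr not in dist:
                dist[nbr] = d1
                queue.append(nbr)
    return dist


@dataclass(frozen=True)
class DegreeBins:
    """Nodes of a graph partitioned into contiguous ascending degree ranges.

    Each bin holds at least ``min_bin_size`` nodes (a short trailing bin is
    merged backwards into its predecessor), so surrogate draws within a bin
    have enough candidates.  ``bin_of`` maps every node to its bin index.
    """

    bins: tuple[tuple[tuple[int, int], tuple[str, ...]], ...]
    min_bin_size: int
    bin_of: Mapping[str, int] = field(repr=False)

    def nodes_in_bin(self, index: int) -> tuple[str, ...]:
        return self.bins[index][1]

    def __len__(self) -> int:
        return len(self.bins)


def default_min_bin_size(g: nx.Graph) -> int:
    """min(100, ceil(n/20)) — the full-scale convention, usable on toy graphs."""
    return min(100, math.ceil(g.number_of_nodes() / 20))


def degree_bins(g: nx.Graph, min_bin_size: int | None = None) -> DegreeBins:
    """Group nodes by degree and merge adjacent degree groups until every bin
    holds at least ``min_bin_size`` nodes.

    Groups are scanned in ascending degree order and accumulated until the
    running bin reaches the minimum size; a final undersized bin is folded
    backwards into its predecessor.  With ``min_bin_size=1`` each distinct
    degree keeps its own bin.  A graph smaller than ``min_bin_size`` yields a
    single all-node bin with a warning.
    """
    if min_bin_size is None:
        min_bin_size = default_min_bin_size(g)
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")

    by_degree: dict[int, list[str]] = {}
    for node, deg in g.degree:
        by_degree.setdefault(deg, []).append(node)

    if g.number_of_nodes() < min_bin_size:
        warnings.warn(
            "graph smaller than min_bin_size; using a single degree bin",
            stacklevel=2,
        )

    bins: list[tuple[tuple[int, int], tuple[str, ...]]] = []
    current: list[str] = []
    lo: int | None = None
    for deg in sorted(by_degree):
        if lo is None:
            lo = deg
        current.extend(sorted(by_degree[deg]))
        if len(current) >= min_bin_size:
            bins.append(((lo, deg), tuple(current)))
            current, lo = [], None
    if current:
        if bins:
            (prev_lo, _), prev_nodes = bins.pop()
            bins.append(((prev_lo, max(by_degree)), prev_nodes + tuple(current)))
        else:
            bins.append(((lo if lo is not None else 0, max(by_degree, default=0)), tuple(current)))

    bin_of = {
        node: idx for idx, (_, nodes) in enumerate(bins) for node in nodes
    }
    return DegreeBins(bins=tuple(bins), min_bin_size=min_bin_size, bin_of=bin_of)
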