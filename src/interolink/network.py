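"""Undirected simple interaction network with per-edge method provenance.

Protein identifiers are opaque strings; an edge is an unordered pair of
distinct identifiers carrying the set of prediction methods that support it.
Self-loops are rejected at insertion time, so every network in the package
is a simple graph by construction.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx

Edge = tuple[str, str]


def canonical_pair(a: str, b: str) -> Edge:
    """Order-normalise an unordered protein pair (lexicographically smaller first)."""
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """A simple undirected graph of protein ids with per-edge support labels."""

    def __init__(self) -> None:
        self._support: dict[Edge, set[str]] = {}
        self._nodes: set[str] = set()

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self._nodes.add(node)

    def add_edge(self, a: str, b: str, label: str | None = None) -> None:
        if a == b:
            raise ValueError(f"self-interaction rejected: {a!r}")
        key = canonical_pair(a, b)
        self._nodes.update(key)
        labels = self._support.setdefault(key, set())
        if label is not None:
            labels.add(label)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Edge], label: str | None = None) -> "InteractionNetwork":
        net = cls()
        for a, b in pairs:
            net.add_edge(a, b, label)
        return net

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        return sorted(self._support)

    def edge_set(self) -> set[Edge]:
        return set(self._support)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self._support

    def support(self, a: str, b: str) -> set[str]:
        return set(self._support[canonical_pair(a, b)])

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._support)

    def __contains__(self, pair: Edge) -> bool:
        return canonical_pair(*pair) in self._support

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self._support)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._support == other._support and self._nodes == other._nodes

    def __repr__(self) -> str:
        return f"InteractionNetwork(nodes={self.n_nodes}, edges={self.n_edges})"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for (a, b), labels in self._support.items():
            g.add_edge(a, b, support=sorted(labels))
        return g
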