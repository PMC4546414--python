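"""Semantic network container and plain-text I/O.

A :class:`SemanticNetwork` is a thin wrapper around a :mod:`networkx` graph
that enforces the invariants shared by every network in this package: no
self-loops, no duplicate edges, and an optional per-edge growth label
(``"differentiation"`` or ``"correlation"``).
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx

EDGE_LABELS = ("differentiation", "correlation")


class SemanticNetwork:
    """Directed or undirected simple graph over hashable node labels."""

    def __init__(self, graph: nx.Graph | nx.DiGraph):
        if nx.number_of_selfloops(graph):
            raise ValueError("semantic networks must not contain self-loops")
        self.graph = graph

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Optional[Iterable] = None,
        directed: bool = True,
        labels: Optional[Iterable[str]] = None,
    ) -> "SemanticNetwork":
        g = nx.DiGraph() if directed else nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        if labels is None:
            g.add_edges_from(edges)
        else:
            for (u, v), lab in zip(edges, labels):
                g.add_edge(u, v, label=lab)
        return cls(g)

    # -- basic accessors ---------------------------------------------------

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list:
        return list(self.graph.nodes())

    def edges(self, data: bool = False) -> list:
        return list(self.graph.edges(data=data))

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    def out_degrees(self) -> dict:
        if self.directed:
            return dict(self.graph.out_degree())
        return dict(self.graph.degree())

    def in_degrees(self) -> dict:
        if self.directed:
            return dict(self.graph.in_degree())
        return dict(self.graph.degree())

    def undirected(self) -> "SemanticNetwork":
        """Undirected projection: x -- y iff x -> y or y -> x."""
        if not self.directed:
            return self
        return SemanticNetwork(nx.Graph(self.graph))

    def subgraph(self, nodes) -> "SemanticNetwork":
        return SemanticNetwork(self.graph.subgraph(nodes).copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "undirected"
        return f"SemanticNetwork({kind}, n={self.n}, m={self.m})"

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path) -> None:
        """Write edges as ``source<TAB>target[<TAB>label]`` lines."""
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in self.graph.edges(data=True):
                lab = data.get("label")
                if lab is None:
                    fh.write(f"{u}\t{v}\n")
                else:
                    fh.write(f"{u}\t{v}\t{lab}\n")

    @classmethod
    def read_tsv(cls, path, directed: bool = True) -> "SemanticNetwork":
        g = nx.DiGraph() if directed else nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) == 2:
                    g.add_edge(parts[0], parts[1])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[1], label=parts[2])
                else:
                    raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        return cls(g)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def as_graph(net) -> nx.Graph | nx.DiGraph:
    """Accept either a SemanticNetwork or a bare networkx graph."""
    return net.graph if isinstance(net, SemanticNetwork) else net
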