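"""Causal-DAG reasoning: d-separation and backdoor adjustment sets.

The learned graph tells us which paths between two variables transmit causal
influence and which carry spurious association. The backdoor criterion picks
the covariate sets that close the spurious paths, and those sets feed the
adjusted regressions that produce the effect table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CausalDAG",
    "AdjustmentSet",
    "IdentificationError",
    "d_separated",
    "backdoor_sets",
    "minimal_backdoor_set",
]


class IdentificationError(ValueError):
    """No backdoor adjustment set exists for the requested effect."""


@dataclass(frozen=True)
class AdjustmentSet:
    """Covariate set satisfying the backdoor criterion for source -> target."""

    source: str
    target: str
    nodes: frozenset[str]
    minimal: bool = False

    def __post_init__(self) -> None:
        if self.source in self.nodes or self.target in self.nodes:
            raise ValueError("adjustment set may not contain source or target")

    def sorted_labels(self) -> list[str]:
        return sorted(self.nodes)

    def __str__(self) -> str:
        return ";".join(self.sorted_labels())


class CausalDAG:
    """Labelled weighted DAG over the study variables.

    Thin wrapper around a :class:`networkx.DiGraph` that enforces acyclicity
    and keeps the optional causal-stage category of each node.
    """

    def __init__(self, graph: nx.DiGraph, categories: dict[str, str] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("graph contains a directed cycle")
        self._g = graph
        self.categories = dict(categories or {})

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges, nodes=None, categories=None) -> "CausalDAG":
        """Build from (source, target[, weight]) tuples; isolated nodes allowed."""
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for e in edges:
            if len(e) == 2:
                s, t = e
                w = 1.0
            else:
                s, t, w = e
            g.add_edge(s, t, weight=float(w))
        return cls(g, categories)

    @classmethod
    def from_weight_matrix(cls, W, labels, categories=None) -> "CausalDAG":
        W = np.asarray(W, dtype=float)
        labels = list(labels)
        edges = [
            (labels[i], labels[j], W[i, j]) for i, j in zip(*np.nonzero(W))
        ]
        return cls.from_edges(edges, nodes=labels, categories=categories)

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self, data: bool = True):
        if data:
            return [(s, t, d.get("weight", 1.0)) for s, t, d in self._g.edges(data=True)]
        return list(self._g.edges)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def weight(self, source: str, target: str) -> float:
        return self._g.edges[source, target]["weight"]

    def descendants(self, node: str) -> set[str]:
        self._check_nodes([node])
        return nx.descendants(self._g, node)

    def parents(self, node: str) -> set[str]:
        self._check_nodes([node])
        return set(self._g.predecessors(node))

    def weight_matrix(self, labels=None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.nodes
        W = np.zeros((len(labels), len(labels)))
        for s, t, w in self.edges():
            W[labels.index(s), labels.index(t)] = w
        return W

    def _check_nodes(self, labels) -> None:
        unknown = [x for x in labels if x not in self._g]
        if unknown:
            raise KeyError(f"unknown node label(s): {unknown}")

    # -- export ------------------------------------------------------------

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(s, t, w) for s, t, w in self.edges()]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_edge_csv(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self._g, path)

    def to_dot(self) -> str:
        lines = ["digraph causal {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for s, t, w in self.edges():
            lines.append(f'  "{s}" -> "{t}" [label="{w:.2f}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_dot_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_dot())

    def plot(self, ax=None):
        """Draw the DAG with edge weights (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        pos = nx.spring_layout(self._g, seed=0)
        nx.draw_networkx(self._g, pos=pos, ax=ax, node_color="#cfe2f3", arrows=True)
        labels = {(s, t): f"{w:.2f}" for s, t, w in self.edges()}
        nx.draw_networkx_edge_labels(self._g, pos=pos, edge_labels=labels, ax=ax)
        ax.set_axis_off()
        return ax


def d_separated(G: CausalDAG, x: str, y: str, Z) -> bool:
    """Whether Z blocks every undirected path between x and y in G.

    Blocking follows the usual semantics: a chain or fork is blocked when its
    middle node is conditioned on; a collider blocks unless the collider or
    one of its descendants is conditioned on. Implemented as a reachability
    sweep (Bayes-ball) over (node, edge-direction) states; the exhaustive
    path-enumeration oracle lives in the test suite.
    """
    Z = frozenset(Z)
    G._check_nodes([x, y, *Z])
    if x == y:
        raise ValueError("x and y must differ")
    if x in Z or y in Z:
        raise ValueError("Z may not contain x or y")
    g = G.graph
    # ancestors of Z unblock colliders
    an_z = set(Z)
    for z in Z:
        an_z |= nx.ancestors(g, z)
    # states: (node, "up") entered via an edge pointing away from the node
    # (we arrived moving against an arrow); (node, "down") entered via an
    # edge pointing into the node.
    visited = set()
    frontier = [(x, "up")]
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y and node not in Z:
            return False
        if direction == "up" and node not in Z:
            # may continue to parents (still "up") and to children ("down")
            for p in g.predecessors(node):
                frontier.append((p, "up"))
            for c in g.successors(node):
                frontier.append((c, "down"))
        elif direction == "down":
            if node not in Z:
                # chain: continue downward to children
                for c in g.successors(node):
                    frontier.append((c, "down"))
            if node in an_z:
                # collider opened by conditioning on node or a descendant
                for p in g.predecessors(node):
                    frontier.append((p, "up"))
    return True


def _backdoor_valid(G: CausalDAG, x: str, y: str, Z: frozenset, de_x: set) -> bool:
    if Z & de_x:
        return False
    # remove x's outgoing edges: the remaining x-y paths are exactly the
    # backdoor paths (those entering x through an arrow)
    pruned = G.graph.copy()
    pruned.remove_edges_from(list(G.graph.out_edges(x)))
    return d_separated(CausalDAG(pruned), x, y, Z)


def backdoor_sets(
    G: CausalDAG, x: str, y: str, max_size: int | None = None
) -> list[AdjustmentSet]:
    """All covariate sets (up to max_size) meeting the backdoor criterion.

    A valid set contains no descendant of x and blocks every path from x to y
    that enters x through an arrow. Candidates are enumerated exhaustively
    (the study graph has 14 nodes, so enumeration is affordable); the result
    is sorted by size, ties broken lexicographically on the sorted labels.
    """
    G._check_nodes([x, y])
    if x == y:
        raise ValueError("x and y must differ")
    de_x = G.descendants(x)
    candidates = sorted(set(G.nodes) - {x, y} - de_x)
    if max_size is None:
        max_size = len(G.nodes) - 2
    out = []
    for size in range(0, min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            Z = frozenset(combo)
            if _backdoor_valid(G, x, y, Z, de_x):
                out.append(AdjustmentSet(x, y, Z))
    out.sort(key=lambda a: (len(a.nodes), a.sorted_labels()))
    if out:
        out[0] = AdjustmentSet(x, y, out[0].nodes, minimal=True)
    return out


def minimal_backdoor_set(G: CausalDAG, x: str, y: str) -> AdjustmentSet:
    """Smallest valid backdoor set (lexicographic tie-break); deterministic.

    Raises :class:`IdentificationError` when no set of any size exists, i.e.
    the effect of x on y is not backdoor-identifiable in G.
    """
    G._check_nodes([x, y])
    if x == y:
        raise ValueError("x and y must differ")
    de_x = G.descendants(x)
    candidates = sorted(set(G.nodes) - {x, y} - de_x)
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            Z = frozenset(combo)
            if _backdoor_valid(G, x, y, Z, de_x):
                return AdjustmentSet(x, y, Z, minimal=True)
    raise IdentificationError(
        f"effect {x} -> {y} is not backdoor-identifiable in this graph"
    )
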