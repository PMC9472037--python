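"""Independent brute-force oracles for the graph-reasoning tests.

These deliberately avoid the package's reachability implementation: paths are
enumerated explicitly over the undirected skeleton and blocking is evaluated
per path, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import networkx as nx


def all_dags(n: int):
    """Every labelled DAG on n nodes (as networkx DiGraphs)."""
    nodes = list(range(n))
    pairs = [(i, j) for i in nodes for j in nodes if i != j]
    for bits in range(2 ** len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if bits >> k & 1]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


def random_dag(n: int, p: float, rng) -> nx.DiGraph:
    """Random DAG: random node order, each admissible edge kept w.p. p."""
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(int(order[i]), int(order[j]))
    return g


def _undirected_simple_paths(g: nx.DiGraph, x, y):
    """All simple paths x..y in the skeleton, with per-step edge direction."""
    adj: dict = {}
    for u, v in g.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for n in g.nodes:
        adj.setdefault(n, set())

    def extend(path):
        last = path[-1]
        if last == y:
            yield list(path)
            return
        for nxt in adj[last]:
            if nxt not in path:
                path.append(nxt)
                yield from extend(path)
                path.pop()

    yield from extend([x])


def _path_blocked(g: nx.DiGraph, path, Z) -> bool:
    """Blocking by Z evaluated triple-by-triple along one skeleton path."""
    Z = set(Z)
    for k in range(1, len(path) - 1):
        prev, mid, nxt = path[k - 1], path[k], path[k + 1]
        into_left = g.has_edge(prev, mid)
        into_right = g.has_edge(nxt, mid)
        if into_left and into_right:  # collider
            col_closure = {mid} | nx.descendants(g, mid)
            if not (col_closure & Z):
                return True
        else:  # chain or fork
            if mid in Z:
                return True
    return False


def d_separated_oracle(g: nx.DiGraph, x, y, Z) -> bool:
    """True iff every skeleton path between x and y is blocked given Z."""
    for path in _undirected_simple_paths(g, x, y):
        if len(path) == 1:
            continue
        if not _path_blocked(g, path, Z):
            return False
    return True


def backdoor_valid_oracle(g: nx.DiGraph, x, y, Z) -> bool:
    """Backdoor criterion by definition: no descendant of x in Z, and every
    skeleton path whose first step enters x through an arrow is blocked."""
    Z = set(Z)
    if Z & nx.descendants(g, x):
        return False
    for path in _undirected_simple_paths(g, x, y):
        if len(path) < 2:
            continue
        if not g.has_edge(path[1], x):
            continue  # not a backdoor path
        if not _path_blocked(g, path, Z):
            return False
    return True


def backdoor_sets_oracle(g: nx.DiGraph, x, y, max_size=None):
    """All valid backdoor sets by exhaustive subset enumeration."""
    candidates = sorted(set(g.nodes) - {x, y}, key=str)
    if max_size is None:
        max_size = len(g.nodes) - 2
    out = []
    for size in range(0, min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            if backdoor_valid_oracle(g, x, y, set(combo)):
                out.append(frozenset(combo))
    return out
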