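"""Problem/solution data model and shared graph machinery.

The Steiner tree problem on an unweighted graph G = (V, E): given a set of
terminal (seed) nodes S ⊆ V, find a connected sub-graph G' = (V', E') with
S ⊆ V' ⊆ V and E' ⊆ E of minimum edge count.  Because G is unweighted, an
optimal G' is always a tree and distances are hop counts throughout.

This module provides:

* :class:`SteinerInstance` / :class:`SteinerTree` /
  :class:`MergedSteinerSubgraph` / :class:`SolutionMetrics` — the data model;
* :func:`bfs_shortest_paths` — multi-source BFS with a predecessor DAG
  encoding *all* geodesics;
* :func:`spanning_tree` — a deterministic spanning tree (every spanning tree
  of an unweighted graph is a minimum spanning tree);
* :func:`prune_nonterminal_leaves` — iterated removal of degree-≤1
  non-terminals (the Rayward-Smith & Clare clean-up step);
* :func:`validate_solution` and :func:`evaluate` — invariant checks and the
  two quality measures (edge count and terminal frequency).
"""

from __future__ import annotations

import json
import os
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .graph_io import Network

__all__ = [
    "SteinerInstance",
    "SteinerTree",
    "SteinerSubgraph",
    "MergedSteinerSubgraph",
    "SolutionMetrics",
    "bfs_shortest_paths",
    "spanning_tree",
    "prune_nonterminal_leaves",
    "validate_solution",
    "evaluate",
]

def canonical_edges(edges) -> frozenset[tuple[str, str]]:
    """Normalize an edge iterable to a frozenset of sorted tuples."""
    return frozenset(tuple(sorted(e)) for e in edges)


@dataclass(frozen=True)
class SteinerInstance:
    """A network plus the terminal set S — the problem input.

    Terminals must be nodes of the network, at least two, and all lie in a
    single connected component (otherwise no Steiner tree exists).
    """

    network: Network
    terminals: frozenset[str]

    def __init__(self, network: Network, terminals) -> None:
        terminals = frozenset(terminals)
        missing = sorted(t for t in terminals if t not in network)
        if missing:
            raise ValueError(f"terminals not in network: {missing}")
        if len(terminals) < 2:
            raise ValueError("need at least 2 terminals")
        dist, _ = bfs_shortest_paths(network, {min(terminals)})
        unreachable = sorted(t for t in terminals if t not in dist)
        if unreachable:
            raise ValueError(
                "terminals span multiple connected components; unreachable "
                f"from {min(terminals)!r}: {unreachable}"
            )
        object.__setattr__(self, "network", network)
        object.__setattr__(self, "terminals", terminals)


@dataclass(frozen=True)
class SteinerTree:
    """A single tree solution (V', E') with S ⊆ V'."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    instance: SteinerInstance = field(compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_graph(self) -> Network:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SteinerSubgraph:
    """A connected terminal-covering sub-graph, not necessarily a tree."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    instance: SteinerInstance = field(compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_graph(self) -> Network:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MergedSteinerSubgraph:
    """Union of several equally sized Steiner trees.

    ``minimal_tree_size`` is the edge count of each contained tree; the
    merged sub-graph acknowledges that minimal Steiner trees are generally
    not unique and that, absent further information, all solutions of the
    same size are equally relevant.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    minimal_tree_size: int
    instance: SteinerInstance = field(compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_graph(self) -> Network:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SolutionMetrics:
    """Quality measures of one solution.

    ``terminal_frequency`` = |S ∩ V'| / |V'| ∈ (0, 1]; higher means a more
    parsimonious solution (fewer auxiliary nodes).
    """

    n_nodes: int
    n_edges: int
    terminal_frequency: float
    runtime_seconds: float


def bfs_shortest_paths(
    net: Network, sources
) -> tuple[dict[str, int], dict[str, set[str]]]:
    """Multi-source breadth-first search with an all-geodesics DAG.

    Returns ``(dist, pred)`` where ``dist[v]`` is the minimum hop count from
    the nearest source and ``pred[v]`` is the set of *all* predecessors of
    ``v`` on geodesics — every ``p`` in ``pred[v]`` satisfies
    ``dist[p] == dist[v] - 1``.  Sources have ``dist 0`` and empty
    predecessor sets.  Unreachable nodes are absent from both maps.
    """
    sources = set(sources)
    if not sources:
        raise ValueError("sources must be non-empty")
    missing = sorted(s for s in sources if s not in net)
    if missing:
        raise ValueError(f"sources not in network: {missing}")
    dist: dict[str, int] = {s: 0 for s in sources}
    pred: dict[str, set[str]] = {s: set() for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in net[u]:
            if v not in dist:
                dist[v] = du + 1
                pred[v] = {u}
                queue.append(v)
            elif dist[v] == du + 1:
                pred[v].add(u)
    return dist, pred


def spanning_tree(net: Network, nodes=None) -> Network:
    """Deterministic spanning tree of a connected (sub-)network.

    BFS tree rooted at the lexicographically smallest node, neighbors
    visited in lexicographic order.  On an unweighted graph every spanning
    tree is a minimum spanning tree, so determinism is the only extra
    property imposed.  With ``nodes`` given, operates on the induced
    sub-network.
    """
    sub = net if nodes is None else net.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        raise ValueError("spanning_tree of an empty network")
    root = min(sub.nodes())
    tree = nx.Graph()
    tree.add_node(root)
    queue = deque([root])
    seen = {root}
    while queue:
        u = queue.popleft()
        for v in sorted(sub[u]):
            if v not in seen:
                seen.add(v)
                tree.add_edge(u, v)
                queue.append(v)
    if len(seen) != sub.number_of_nodes():
        raise ValueError("input sub-network is not connected")
    return tree


def prune_nonterminal_leaves(subgraph: Network, terminals) -> Network:
    """Remove non-terminal nodes of degree ≤ 1, iterated to a fixed point.

    A single pass can expose new degree-1 non-terminals, so removal is
    repeated until none remain.  Terminals are never removed; connectivity
    of the remainder is preserved (only leaves are cut).  Returns a copy.
    """
    terminals = set(terminals)
    out = subgraph.copy()
    frontier = deque(
        n for n in out.nodes() if n not in terminals and out.degree(n) <= 1
    )
    while frontier:
        leaf = frontier.popleft()
        if leaf not in out:
            continue
        neighbors = list(out[leaf])
        out.remove_node(leaf)
        for n in neighbors:
            if n not in terminals and out.degree(n) <= 1:
                frontier.append(n)
    return out


def validate_solution(solution, instance: SteinerInstance) -> list[str]:
    """Check solution invariants; returns the list of violations (empty = valid).

    For any solution: terminal coverage, edge subset of E, connectivity.
    For a :class:`SteinerTree` additionally acyclicity and |E'| = |V'| - 1.
    """
    violations: list[str] = []
    nodes = set(solution.nodes)
    edges = canonical_edges(solution.edges)
    if not nodes:
        return ["empty node set"]
    if not instance.terminals <= nodes:
        violations.append("terminal coverage")
    if not nodes <= set(instance.network.nodes()):
        violations.append("node subset of V")
    net_edges = canonical_edges(instance.network.edges())
    if not edges <= net_edges:
        violations.append("edge subset of E")
    for u, v in edges:
        if u not in nodes or v not in nodes:
            violations.append("edge endpoints in node set")
            break
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_connected(g):
        violations.append("connectivity")
    if isinstance(solution, SteinerTree):
        if len(edges) != len(nodes) - 1:
            violations.append("edge count |V'| - 1")
        if len(edges) >= len(nodes):
            violations.append("acyclicity")
    return violations


def evaluate(
    solution, instance: SteinerInstance, runtime_seconds: float = 0.0
) -> SolutionMetrics:
    """Compute the quality measures of a solution.

    ``n_edges`` = |E'|; ``terminal_frequency`` = |S ∩ V'| / |V'|, which
    equals |S| / |V'| whenever all terminals are covered.
    """
    nodes = set(solution.nodes)
    if not nodes:
        raise ValueError("cannot evaluate a solution with an empty node set")
    return SolutionMetrics(
        n_nodes=len(nodes),
        n_edges=len(set(canonical_edges(solution.edges))),
        terminal_frequency=len(instance.terminals & nodes) / len(nodes),
        runtime_seconds=runtime_seconds,
    )


def write_solution(
    solution,
    instance: SteinerInstance,
    method: str,
    out_prefix: str | os.PathLike,
    runtime_seconds: float = 0.0,
    seed: int | None = None,
) -> tuple[str, str]:
    """Serialize a solution as SIF edges plus a JSON metrics record.

    Returns the (sif_path, json_path) written.
    """
    from .graph_io import write_sif

    metrics = evaluate(solution, instance, runtime_seconds)
    sif_path = f"{out_prefix}.sif"
    json_path = f"{out_prefix}.metrics.json"
    write_sif(solution.as_graph(), sif_path)
    record = {
        "method": method,
        "n_nodes": metrics.n_nodes,
        "n_edges": metrics.n_edges,
        "terminal_frequency": metrics.terminal_frequency,
        "runtime_seconds": metrics.runtime_seconds,
        "seed": seed,
    }
    if isinstance(solution, MergedSteinerSubgraph):
        record["minimal_tree_size"] = solution.minimal_tree_size
    with open(json_path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
    return sif_path, json_path
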