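"""Exact minimum Steiner trees by subset enumeration.

The exact algorithm exploits two facts about unweighted graphs: every
spanning tree is a minimum spanning tree, and a spanning tree over n nodes
has exactly n - 1 edges.  It therefore enumerates candidate sets A of
non-terminal nodes in order of increasing |A| and tests, in linear time via
BFS, whether the sub-graph induced on S ∪ A is connected.  The first
connected candidate yields a globally minimal Steiner tree with
|S| + |A*| - 1 edges.  The search is exponential in |V \\ S| (at most
2^(|V|-|S|) candidate sets), so a configurable node-count guard refuses
networks where it would be hopeless.

Two admissible prunings keep the enumeration tractable on toy scales
without affecting correctness: the candidate universe is restricted to the
connected component containing S, and at size class k any non-terminal
farther than |S| + k - 1 hops from every terminal is excluded (it cannot
appear in a tree with that many edges).

:func:`brute_force_oracle` is an independent cross-check that enumerates
subsets of *edges* instead of nodes and shares no code with the search
above.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from .steiner_core import (
    MergedSteinerSubgraph,
    SteinerInstance,
    SteinerTree,
    bfs_shortest_paths,
    canonical_edges,
    spanning_tree,
)

__all__ = [
    "ExactGuardError",
    "exact_steiner_tree",
    "exact_merged_subgraph",
    "brute_force_oracle",
]

#: Default refusal threshold on the network node count.
DEFAULT_MAX_NODES = 30


class ExactGuardError(ValueError):
    """Raised when an instance exceeds a size guard of an exact routine."""


def _candidate_universe(instance: SteinerInstance) -> list[str]:
    """Non-terminals in the component containing S, with terminal distances."""
    net = instance.network
    dist, _ = bfs_shortest_paths(net, instance.terminals)
    return sorted(v for v in dist if v not in instance.terminals), dist


def _connected_on(net, nodes: set[str]) -> bool:
    """Linear-time connectivity test of the induced sub-graph on ``nodes``."""
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in net[u]:
            if v in nodes and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(nodes)


def _minimal_subsets(instance: SteinerInstance, max_nodes: int, first_only: bool):
    """Yield (k*, list of minimal non-terminal subsets) for the instance.

    Enumerates subsets A of non-terminals by increasing size, lexicographic
    within a size class; stops at the first size class with a connected
    S ∪ A.  ``first_only`` stops at the first hit within that class.
    """
    net = instance.network
    if max_nodes is not None and net.number_of_nodes() > max_nodes:
        raise ExactGuardError(
            f"network has {net.number_of_nodes()} nodes, above the exact-"
            f"algorithm guard of {max_nodes}; raise max_nodes explicitly or "
            "use a heuristic (sp/kb/rsp/stm)"
        )
    terminals = set(instance.terminals)
    universe, dist = _candidate_universe(instance)
    # admissible lower bound: a tree covering s and t has >= dist(s, t)
    # edges, so with |S| + k - 1 edges at class k, k >= dist - |S| + 1
    max_pair = 0
    for s in sorted(terminals):
        sdist, _ = bfs_shortest_paths(instance.network, {s})
        max_pair = max(max_pair, max(sdist[t] for t in terminals))
    k_min = max(0, max_pair - len(terminals) + 1)
    for k in range(k_min, len(universe) + 1):
        budget = len(terminals) + k - 1  # edge count of a tree at this class
        admissible = [v for v in universe if dist[v] <= budget]
        hits: list[tuple[str, ...]] = []
        for subset in combinations(admissible, k):
            if _connected_on(net, terminals | set(subset)):
                hits.append(subset)
                if first_only:
                    return k, hits
        if hits:
            return k, hits
    raise AssertionError("unreachable: instance guarantees connected terminals")


def exact_steiner_tree(
    instance: SteinerInstance, max_nodes: int | None = DEFAULT_MAX_NODES
) -> SteinerTree:
    """Globally minimal Steiner tree by exhaustive subset enumeration.

    Deterministic: the lexicographically first minimal non-terminal subset
    is kept and its BFS spanning tree returned.  ``max_nodes`` guards
    against hopeless inputs (pass ``None`` or a larger value to override).
    """
    k, hits = _minimal_subsets(instance, max_nodes, first_only=True)
    nodes = set(instance.terminals) | set(hits[0])
    tree = spanning_tree(instance.network, nodes)
    return SteinerTree(
        nodes=frozenset(tree.nodes()),
        edges=canonical_edges(tree.edges()),
        instance=instance,
    )


def exact_merged_subgraph(
    instance: SteinerInstance, max_nodes: int | None = DEFAULT_MAX_NODES
) -> MergedSteinerSubgraph:
    """Union of *all* minimal Steiner trees.

    All non-terminal subsets of the minimal size k* whose induced sub-graph
    is connected are collected and their induced sub-graphs merged.  Every
    edge of a connected graph lies on some spanning tree of it, so the union
    of all minimal Steiner trees over a given node set equals that node
    set's induced sub-graph; merging induced sub-graphs therefore loses
    nothing.
    """
    k, hits = _minimal_subsets(instance, max_nodes, first_only=False)
    merged = nx.Graph()
    for subset in hits:
        nodes = set(instance.terminals) | set(subset)
        merged.update(instance.network.subgraph(nodes))
    return MergedSteinerSubgraph(
        nodes=frozenset(merged.nodes()),
        edges=canonical_edges(merged.edges()),
        minimal_tree_size=len(instance.terminals) + k - 1,
        instance=instance,
    )


def brute_force_oracle(
    instance: SteinerInstance, max_nodes: int = 15
) -> tuple[int, set[frozenset[tuple[str, str]]]]:
    """Independent oracle: enumerate edge subsets, keep minimal Steiner trees.

    Checks every subset of E by increasing size; a subset qualifies if it is
    a tree (connected, |E| = |V| - 1 over its endpoints) whose node set
    covers all terminals and contains no node not needed as an endpoint.
    Returns ``(minimal size, set of all minimal trees' edge sets)``.

    Deliberately brute force and code-independent of the subset-enumeration
    search; only usable at toy scale (guarded at ``max_nodes``).
    """
    net = instance.network
    if net.number_of_nodes() > max_nodes:
        raise ExactGuardError(
            f"brute-force oracle limited to {max_nodes} nodes, "
            f"got {net.number_of_nodes()}"
        )
    terminals = set(instance.terminals)
    all_edges = sorted(canonical_edges(net.edges()))
    for size in range(len(terminals) - 1, len(all_edges) + 1):
        winners: set[frozenset[tuple[str, str]]] = set()
        for edge_subset in combinations(all_edges, size):
            g = nx.Graph(edge_subset)
            if not terminals <= set(g.nodes()):
                continue
            if g.number_of_edges() != g.number_of_nodes() - 1:
                continue
            if not nx.is_connected(g):
                continue
            winners.add(frozenset(edge_subset))
        if winners:
            return size, winners
    raise AssertionError("unreachable: instance guarantees connected terminals")
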