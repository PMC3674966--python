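"""Approximation algorithms for the unweighted Steiner tree problem.

Five methods, all operating on hop-count distances:

* **SP** — the shortest-paths heuristic of Takahashi & Matsuyama: grow a
  sub-graph from a start terminal by repeatedly attaching the nearest
  not-yet-included terminal along one shortest path, then take a spanning
  tree and strip non-terminal leaves (the Rayward-Smith & Clare clean-up).
  Restarted from several random start terminals (Winter & Smith), keeping
  the best tree.  Guaranteed within (2 - 2/|S|) of the optimum.
* **KB** — a Kruskal-like heuristic: start with each terminal as its own
  component and repeatedly merge the two closest components along a
  connecting shortest path; same clean-up as SP.
* **RSP** — a randomized scheme: start from the union of *all* geodesics
  between terminal pairs, then repeatedly attempt random non-terminal
  removals (rejected if they disconnect the sub-graph) and random
  insertions, accepting a move only if the spanning tree strictly shrinks.
* **ASP** — the baseline: union of one shortest path per terminal pair; a
  connected sub-graph, in general neither a tree nor small.
* **STM** — the merged-trees variant of SP: at every growth step attach
  *all* terminals tied at the minimum distance, each along *all* of its
  geodesics, and merge the best runs over all start terminals.  Yields a
  sub-graph containing several (heuristically) minimal Steiner trees.

Determinism: every method maps identical ``(instance, config)`` — seed
included — to identical output.  Ties the procedure itself does not fix are
broken lexicographically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .steiner_core import (
    MergedSteinerSubgraph,
    SteinerInstance,
    SteinerSubgraph,
    SteinerTree,
    bfs_shortest_paths,
    canonical_edges,
    prune_nonterminal_leaves,
    spanning_tree,
)

__all__ = [
    "HeuristicConfig",
    "sp_steiner",
    "kb_steiner",
    "rsp_steiner",
    "asp_subgraph",
    "stm_merged",
]

SP_DEFAULT_REPEATS = 10
RSP_DEFAULT_REPEATS = 70


@dataclass(frozen=True)
class HeuristicConfig:
    """Tunables shared by the heuristics.

    ``repeats`` (r): number of restarts for SP/STM (default 10) or of
    move attempts for RSP (default 70); ``None`` selects the per-method
    default.  ``max_len``: RSP insertion radius in hops around the terminal
    set; ``"auto"`` uses the maximum pairwise terminal distance.
    """

    repeats: int | None = None
    seed: int = 0
    max_len: int | str = "auto"

    def __post_init__(self) -> None:
        if self.repeats is not None and self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.max_len != "auto" and int(self.max_len) < 1:
            raise ValueError('max_len must be >= 1 or "auto"')


# ---------------------------------------------------------------------------
# Geodesic extraction from a BFS predecessor DAG


def _geodesic_closure(pred: dict[str, set[str]], target: str):
    """All nodes and DAG edges lying on geodesics from the sources to target."""
    nodes = {target}
    edges: set[tuple[str, str]] = set()
    stack = [target]
    while stack:
        v = stack.pop()
        for p in pred[v]:
            edges.add(tuple(sorted((p, v))))
            if p not in nodes:
                nodes.add(p)
                stack.append(p)
    return nodes, edges


def _lex_geodesic(
    dist: dict[str, int], pred: dict[str, set[str]], target: str
) -> list[str]:
    """Lexicographically smallest node sequence among geodesics to target.

    Walks the backward closure of ``target`` forward from the smallest
    dist-0 node it contains, greedily taking the smallest successor; every
    closure node is an ancestor of ``target`` so the greedy walk cannot
    dead-end.
    """
    closure, _ = _geodesic_closure(pred, target)
    children: dict[str, list[str]] = {v: [] for v in closure}
    for v in closure:
        for p in pred[v]:
            children[p].append(v)
    node = min(v for v in closure if dist[v] == 0)
    path = [node]
    while node != target:
        node = min(children[node])
        path.append(node)
    return path


# ---------------------------------------------------------------------------
# SP — shortest paths heuristic


def _sp_grow(instance: SteinerInstance, start: str, rng: random.Random) -> nx.Graph:
    """One SP growth pass: attach nearest uncovered terminals one at a time."""
    net = instance.network
    grown = nx.Graph()
    grown.add_node(start)
    uncovered = set(instance.terminals) - {start}
    while uncovered:
        dist, pred = bfs_shortest_paths(net, set(grown.nodes()))
        dmin = min(dist[t] for t in uncovered)
        ties = sorted(t for t in uncovered if dist[t] == dmin)
        target = ties[0] if len(ties) == 1 else rng.choice(ties)
        path = _lex_geodesic(dist, pred, target)
        nx.add_path(grown, path)
        uncovered.discard(target)
    return grown


def _finish_tree(
    grown: nx.Graph, instance: SteinerInstance
) -> SteinerTree:
    """Rayward-Smith & Clare step: spanning tree, then strip non-terminal leaves."""
    tree = prune_nonterminal_leaves(spanning_tree(grown), instance.terminals)
    return SteinerTree(
        nodes=frozenset(tree.nodes()),
        edges=canonical_edges(tree.edges()),
        instance=instance,
    )


def _tree_sort_key(tree: SteinerTree):
    # smaller size, then higher terminal frequency, then lexicographic edges
    tf = len(tree.instance.terminals & tree.nodes) / len(tree.nodes)
    return (len(tree.edges), -tf, sorted(tree.edges))


def _start_terminals(
    instance: SteinerInstance, config: HeuristicConfig, default_repeats: int
) -> list[str]:
    r = config.repeats if config.repeats is not None else default_repeats
    terminals = sorted(instance.terminals)
    if r >= len(terminals):
        return terminals
    return random.Random(config.seed).sample(terminals, r)


def sp_steiner(
    instance: SteinerInstance, config: HeuristicConfig = HeuristicConfig()
) -> SteinerTree:
    """Shortest-paths heuristic, best of r random starts.

    Result size is at most (2 - 2/|S|) times the minimum; for |S| = 2 the
    result is exactly optimal (a single shortest path survives the
    clean-up).
    """
    rng = random.Random(config.seed)
    starts = _start_terminals(instance, config, SP_DEFAULT_REPEATS)
    best: SteinerTree | None = None
    for start in starts:
        tree = _finish_tree(_sp_grow(instance, start, rng), instance)
        if best is None or _tree_sort_key(tree) < _tree_sort_key(best):
            best = tree
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# KB — Kruskal-like component merging


def kb_steiner(
    instance: SteinerInstance, config: HeuristicConfig = HeuristicConfig()
) -> SteinerTree:
    """Kruskal-like heuristic: merge the closest terminal components.

    Components start as single terminals; the pair at minimum hop distance
    (minimum over node pairs) is merged along one connecting shortest path
    until a single component remains, after which the spanning-tree /
    leaf-stripping clean-up is applied.  Fully deterministic: distance ties
    pick the smallest pair of component indices, components being ordered
    by their lexicographically smallest terminal.
    """
    del config  # deterministic; accepted for interface uniformity
    net = instance.network
    components: list[nx.Graph] = []
    for t in sorted(instance.terminals):
        g = nx.Graph()
        g.add_node(t)
        components.append(g)

    def anchor(g: nx.Graph) -> str:
        return min(n for n in g.nodes() if n in instance.terminals)

    while len(components) > 1:
        components.sort(key=anchor)
        best = None  # (distance, i, j, dist_map, pred_map)
        for i, gi in enumerate(components):
            dist, pred = bfs_shortest_paths(net, set(gi.nodes()))
            for j, gj in enumerate(components):
                if j <= i:
                    continue
                d = min(dist[v] for v in gj.nodes() if v in dist)
                if best is None or d < best[0]:
                    best = (d, i, j, dist, pred)
        assert best is not None
        d, i, j, dist, pred = best
        targets = sorted(
            v for v in components[j].nodes() if dist.get(v) == d
        )
        path = min(_lex_geodesic(dist, pred, t) for t in targets)
        merged = nx.Graph()
        merged.update(components[i])
        merged.update(components[j])
        nx.add_path(merged, path)
        survivors = []
        for k, gk in enumerate(components):
            if k in (i, j):
                continue
            if set(gk.nodes()) & set(merged.nodes()):
                merged.update(gk)  # path ran through another component
            else:
                survivors.append(gk)
        components = survivors + [merged]
    return _finish_tree(components[0], instance)


# ---------------------------------------------------------------------------
# RSP — randomized all-shortest-paths refinement


def _all_geodesics_subgraph(instance: SteinerInstance) -> nx.Graph:
    """G*: union of all geodesics between every unordered terminal pair."""
    net = instance.network
    terminals = sorted(instance.terminals)
    gstar = nx.Graph()
    for idx, s in enumerate(terminals):
        dist, pred = bfs_shortest_paths(net, {s})
        for t in terminals[idx + 1 :]:
            nodes, edges = _geodesic_closure(pred, t)
            gstar.add_nodes_from(nodes)
            gstar.add_edges_from(edges)
    return gstar


def _max_terminal_distance(instance: SteinerInstance) -> int:
    terminals = sorted(instance.terminals)
    best = 0
    for s in terminals:
        dist, _ = bfs_shortest_paths(instance.network, {s})
        best = max(best, max(dist[t] for t in terminals))
    return best


def rsp_steiner(
    instance: SteinerInstance, config: HeuristicConfig = HeuristicConfig()
) -> SteinerTree:
    """Randomized refinement of the all-geodesics sub-graph.

    Starts from G* (all geodesics between terminal pairs) and its spanning
    tree T, then makes r move attempts: with equal probability either try to
    remove a random non-terminal of G* (rejected if G* would disconnect) or
    to insert a random outside node within ``max_len`` hops of a terminal; a
    move is accepted only if the resulting spanning tree is strictly smaller
    than T.  Under strict improvement an insertion alone can never be
    accepted (it enlarges the node set), so insertions act as no-ops; they
    are still attempted, faithfully to the published procedure.  Ends with
    the usual leaf-stripping.
    """
    rng = random.Random(config.seed)
    r = config.repeats if config.repeats is not None else RSP_DEFAULT_REPEATS
    net = instance.network
    terminals = set(instance.terminals)
    gstar = _all_geodesics_subgraph(instance)
    tree = spanning_tree(gstar)
    if config.max_len == "auto":
        max_len = _max_terminal_distance(instance)
    else:
        max_len = int(config.max_len)
    term_dist, _ = bfs_shortest_paths(net, terminals)

    for _ in range(r):
        if rng.random() < 0.5:  # removal attempt
            candidates = sorted(n for n in gstar.nodes() if n not in terminals)
            if not candidates:
                continue
            v = rng.choice(candidates)
            remaining = [n for n in gstar.nodes() if n != v]
            sub = gstar.subgraph(remaining)
            if not nx.is_connected(sub):
                continue
            new_tree = spanning_tree(sub)
            if new_tree.number_of_edges() < tree.number_of_edges():
                gstar = nx.Graph(sub)
                tree = new_tree
        else:  # insertion attempt
            boundary = sorted(
                {
                    v
                    for u in gstar.nodes()
                    for v in net[u]
                    if v not in gstar and term_dist.get(v, max_len + 1) <= max_len
                }
            )
            if not boundary:
                continue
            v = rng.choice(boundary)
            candidate = nx.Graph(gstar)
            candidate.add_node(v)
            candidate.add_edges_from((v, u) for u in net[v] if u in gstar)
            new_tree = spanning_tree(candidate)
            if new_tree.number_of_edges() < tree.number_of_edges():
                gstar = candidate
                tree = new_tree

    pruned = prune_nonterminal_leaves(tree, terminals)
    return SteinerTree(
        nodes=frozenset(pruned.nodes()),
        edges=canonical_edges(pruned.edges()),
        instance=instance,
    )


# ---------------------------------------------------------------------------
# ASP — all shortest paths between terminals


def asp_subgraph(instance: SteinerInstance) -> SteinerSubgraph:
    """Union of one deterministic geodesic per unordered terminal pair.

    The baseline method: connected and terminal-covering but in general
    neither a tree nor close to minimal.  For each pair the
    lexicographically smallest geodesic (as a node sequence from the
    smaller terminal) is taken.
    """
    net = instance.network
    terminals = sorted(instance.terminals)
    union = nx.Graph()
    for idx, s in enumerate(terminals):
        dist, pred = bfs_shortest_paths(net, {s})
        for t in terminals[idx + 1 :]:
            nx.add_path(union, _lex_geodesic(dist, pred, t))
    return SteinerSubgraph(
        nodes=frozenset(union.nodes()),
        edges=canonical_edges(union.edges()),
        instance=instance,
    )


# ---------------------------------------------------------------------------
# STM — merged Steiner trees via the SP scheme


def _stm_grow(instance: SteinerInstance, start: str) -> nx.Graph:
    """STM growth pass: attach ALL tied terminals via ALL their geodesics."""
    net = instance.network
    grown = nx.Graph()
    grown.add_node(start)
    uncovered = set(instance.terminals) - {start}
    while uncovered:
        dist, pred = bfs_shortest_paths(net, set(grown.nodes()))
        dmin = min(dist[t] for t in uncovered)
        for target in sorted(t for t in uncovered if dist[t] == dmin):
            nodes, edges = _geodesic_closure(pred, target)
            grown.add_nodes_from(nodes)
            grown.add_edges_from(edges)
            uncovered.discard(target)
    return grown


def stm_merged(
    instance: SteinerInstance, config: HeuristicConfig = HeuristicConfig()
) -> MergedSteinerSubgraph:
    """Merged Steiner trees by the modified SP scheme.

    Runs the STM growth pass from every terminal (or from r random ones
    when |S| > r), scores each run by the edge count of its cleaned-up
    spanning tree, and merges the sub-graphs of all runs attaining the
    minimum score.  ``minimal_tree_size`` is that score — the size of the
    (heuristically) minimal trees the merger contains.
    """
    starts = _start_terminals(instance, config, SP_DEFAULT_REPEATS)
    runs: list[tuple[int, nx.Graph]] = []
    for start in starts:
        grown = _stm_grow(instance, start)
        pruned = prune_nonterminal_leaves(
            spanning_tree(grown), instance.terminals
        )
        runs.append((pruned.number_of_edges(), grown))
    best_size = min(size for size, _ in runs)
    merged = nx.Graph()
    for size, grown in runs:
        if size == best_size:
            merged.update(grown)
    return MergedSteinerSubgraph(
        nodes=frozenset(merged.nodes()),
        edges=canonical_edges(merged.edges()),
        minimal_tree_size=best_size,
        instance=instance,
    )
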