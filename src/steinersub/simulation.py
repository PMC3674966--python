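"""Benchmarking protocol: terminal sampling, synthetic networks, batch runs
and paired statistical comparison.

Terminal (seed) sets are sampled by a random walk on the network: starting
from a uniformly random node, the walk moves to uniformly random neighbors
and, on the *first* visit to each node, declares it a terminal with
probability theta; it stops once the requested number of terminals has been
collected.  Larger theta therefore packs terminals closer together along
the walk.  For comparisons against the exact algorithm, small sub-networks
are sampled by a random walk that absorbs each visited node's closed
neighborhood until a minimum node count is reached.

Method comparisons use the two-sided paired Wilcoxon signed-rank test,
pairing replicates that share a terminal set, with Holm's step-down
correction across the method pairs at the same terminal-set size.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .exact_steiner import exact_merged_subgraph, exact_steiner_tree
from .graph_io import Network, largest_connected_component
from .heuristics import (
    HeuristicConfig,
    asp_subgraph,
    kb_steiner,
    rsp_steiner,
    sp_steiner,
    stm_merged,
)
from .steiner_core import SolutionMetrics, SteinerInstance, evaluate

__all__ = [
    "RandomWalkConfig",
    "BenchmarkRecord",
    "METHODS",
    "random_walk_terminals",
    "sample_subgraph",
    "generate_synthetic_network",
    "run_benchmark",
    "records_to_dataframe",
    "compare_methods",
    "holm_adjust",
]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Random-walk terminal sampling parameters.

    ``theta``: probability in (0, 1] that a first-visited node becomes a
    terminal; ``n_terminals``: how many terminals to collect (>= 2).
    """

    n_terminals: int
    theta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.n_terminals < 2:
            raise ValueError("n_terminals must be >= 2")


@dataclass(frozen=True)
class BenchmarkRecord:
    """One (method, instance) evaluation within a benchmark run."""

    method: str
    n_terminals: int
    replicate: int
    seed: int
    metrics: SolutionMetrics | None
    error: str | None = None
    minimal_tree_size: int | None = None


def _method_registry():
    return {
        "sp": lambda inst, cfg: sp_steiner(inst, cfg),
        "kb": lambda inst, cfg: kb_steiner(inst, cfg),
        "rsp": lambda inst, cfg: rsp_steiner(inst, cfg),
        "asp": lambda inst, cfg: asp_subgraph(inst),
        "stm": lambda inst, cfg: stm_merged(inst, cfg),
        "exact": lambda inst, cfg: exact_steiner_tree(inst),
        "exact-merged": lambda inst, cfg: exact_merged_subgraph(inst),
    }


METHODS = tuple(_method_registry())


def random_walk_terminals(net: Network, config: RandomWalkConfig) -> set[str]:
    """Sample a terminal set by a theta-thinned random walk.

    The walk starts at a uniformly random node and is confined to that
    node's connected component; revisited nodes are not re-considered as
    terminal candidates.  Returns exactly ``n_terminals`` node IDs.
    """
    rng = random.Random(config.seed)
    nodes = sorted(net.nodes())
    if not nodes:
        raise ValueError("empty network")
    start = rng.choice(nodes)
    component = nx.node_connected_component(net, start)
    if len(component) < config.n_terminals:
        raise ValueError(
            f"component of start node {start!r} has {len(component)} nodes, "
            f"fewer than n_terminals={config.n_terminals}"
        )
    terminals: set[str] = set()
    visited: set[str] = set()
    current = start
    while True:
        if current not in visited:
            visited.add(current)
            if rng.random() < config.theta:
                terminals.add(current)
                if len(terminals) == config.n_terminals:
                    return terminals
        current = rng.choice(sorted(net[current]))


def sample_subgraph(
    net: Network, min_nodes: int = 30, seed: int = 0
) -> Network:
    """Sample a small connected sub-network by neighborhood-absorbing walk.

    A random walk adds each visited node together with all its incident
    edges and neighbor nodes, stopping as soon as the accumulated node
    count reaches ``min_nodes``.  If the walk's component is exhausted
    first, the whole component is returned.
    """
    rng = random.Random(seed)
    nodes = sorted(net.nodes())
    if not nodes:
        raise ValueError("empty network")
    start = rng.choice(nodes)
    component = nx.node_connected_component(net, start)
    sampled = nx.Graph()
    current = start
    while True:
        sampled.add_node(current)
        for nb in net[current]:
            sampled.add_edge(current, nb)
        if sampled.number_of_nodes() >= min_nodes:
            break
        if sampled.number_of_nodes() >= len(component):
            break  # component exhausted below min_nodes
        current = rng.choice(sorted(net[current]))
    return sampled


def generate_synthetic_network(
    kind: str,
    n_nodes: int,
    n_edges: int | None = None,
    attachment: int = 3,
    seed: int = 0,
) -> Network:
    """Generate a synthetic interaction network, LCC-trimmed.

    ``kind`` is ``"scale-free"`` (Barabási–Albert preferential attachment
    with ``attachment`` edges per new node, giving the heavy-tailed degree
    distribution typical of protein-interaction networks) or
    ``"erdos-renyi"`` (G(n, m) with ``n_edges`` edges).  Node IDs are
    opaque strings; only the largest connected component is returned.
    Deterministic under ``seed``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if kind == "scale-free":
        if not 1 <= attachment < n_nodes:
            raise ValueError("attachment must be in [1, n_nodes)")
        raw = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)
    elif kind == "erdos-renyi":
        if n_edges is None or n_edges < 1:
            raise ValueError("erdos-renyi requires n_edges >= 1")
        raw = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    else:
        raise ValueError(f"unknown network kind: {kind!r}")
    width = len(str(n_nodes))
    relabeled = nx.relabel_nodes(raw, {i: f"g{i:0{width}d}" for i in raw.nodes()})
    return largest_connected_component(relabeled)


def _replicate_seed(master_seed: int, n_terminals: int, replicate: int) -> int:
    # deterministic, collision-free across the grid, below 2**31
    return (master_seed * 1_000_003 + n_terminals * 1_009 + replicate) % (2**31 - 1)


def run_benchmark(
    net: Network,
    methods,
    terminal_sizes,
    replicates: int = 50,
    theta: float = 0.5,
    seed: int = 0,
    repeats: int | None = None,
) -> list[BenchmarkRecord]:
    """Run every method on shared random-walk terminal sets.

    For each terminal-set size and replicate one terminal set is sampled
    (seeded deterministically from the master seed) and solved by every
    requested method; a failing method yields a record with ``error`` set
    and the run continues.  Runtime is wall-clock and excluded from any
    statistics downstream.
    """
    registry = _method_registry()
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {METHODS}")
    records: list[BenchmarkRecord] = []
    for n_terminals in terminal_sizes:
        for replicate in range(replicates):
            rep_seed = _replicate_seed(seed, n_terminals, replicate)
            walk = RandomWalkConfig(
                n_terminals=n_terminals, theta=theta, seed=rep_seed
            )
            terminals = random_walk_terminals(net, walk)
            instance = SteinerInstance(net, terminals)
            config = HeuristicConfig(repeats=repeats, seed=rep_seed)
            for method in methods:
                t0 = time.perf_counter()
                try:
                    solution = registry[method](instance, config)
                except Exception as exc:  # noqa: BLE001 - recorded, not raised
                    records.append(
                        BenchmarkRecord(
                            method=method,
                            n_terminals=n_terminals,
                            replicate=replicate,
                            seed=rep_seed,
                            metrics=None,
                            error=f"{type(exc).__name__}: {exc}",
                        )
                    )
                    continue
                runtime = time.perf_counter() - t0
                records.append(
                    BenchmarkRecord(
                        method=method,
                        n_terminals=n_terminals,
                        replicate=replicate,
                        seed=rep_seed,
                        metrics=evaluate(solution, instance, runtime),
                        minimal_tree_size=getattr(
                            solution, "minimal_tree_size", None
                        ),
                    )
                )
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    """Tidy DataFrame, one benchmark record per row."""
    rows = []
    for rec in records:
        row = {
            "method": rec.method,
            "n_terminals": rec.n_terminals,
            "replicate": rec.replicate,
            "seed": rec.seed,
            "error": rec.error,
            "minimal_tree_size": rec.minimal_tree_size,
        }
        if rec.metrics is not None:
            row.update(
                n_nodes=rec.metrics.n_nodes,
                n_edges=rec.metrics.n_edges,
                terminal_frequency=rec.metrics.terminal_frequency,
                runtime_seconds=rec.metrics.runtime_seconds,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment; monotone and never below the raw p."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def compare_methods(
    records, metric: str = "n_edges", alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise paired Wilcoxon signed-rank comparisons of methods.

    Replicates are matched by (replicate, n_terminals); each unordered
    method pair at each terminal-set size is tested two-sided, and Holm's
    correction is applied across the pairs sharing a size.  A pair with
    all-zero differences is marked ``identical`` and excluded from the
    correction.  Requires at least 6 complete pairs per comparison.

    Returns a DataFrame with columns n_terminals, method_a, method_b, n,
    statistic, p_raw, p_holm, direction, significant.
    """
    df = records_to_dataframe(records)
    df = df[df["error"].isna()]
    out_rows = []
    for n_terminals, group in df.groupby("n_terminals"):
        wide = group.pivot(index="replicate", columns="method", values=metric)
        methods = sorted(wide.columns)
        tested = []
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                paired = wide[[a, b]].dropna()
                if len(paired) < 6:
                    raise ValueError(
                        f"need >= 6 paired replicates for {a} vs {b} at "
                        f"|S|={n_terminals}, got {len(paired)}"
                    )
                diffs = paired[a] - paired[b]
                row = {
                    "n_terminals": n_terminals,
                    "method_a": a,
                    "method_b": b,
                    "n": len(paired),
                }
                if (diffs == 0).all():
                    row.update(
                        statistic=float("nan"),
                        p_raw=float("nan"),
                        direction="identical",
                    )
                else:
                    res = stats.wilcoxon(
                        paired[a], paired[b], alternative="two-sided"
                    )
                    median_diff = float(diffs.median())
                    if median_diff < 0:
                        direction = "first smaller"
                    elif median_diff > 0:
                        direction = "first larger"
                    else:
                        direction = "mixed"
                    row.update(
                        statistic=float(res.statistic),
                        p_raw=float(res.pvalue),
                        direction=direction,
                    )
                    tested.append(row)
                out_rows.append(row)
        raw = [row["p_raw"] for row in tested]
        for row, adj in zip(tested, holm_adjust(raw)):
            row["p_holm"] = adj
            row["significant"] = adj < alpha
    result = pd.DataFrame(out_rows)
    if "p_holm" not in result.columns and len(result):
        result["p_holm"] = float("nan")
        result["significant"] = False
    return result
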