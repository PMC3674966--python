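import math

import networkx as nx
import pytest

from steinersub import simulation as sim
from steinersub.fixtures import path5_graph


@pytest.fixture(scope="module")
def small_net():
    return sim.generate_synthetic_network("scale-free", 120, attachment=2, seed=3)


class TestRandomWalkTerminals:
    def test_theta_one_takes_first_distinct_visits(self):
        g = path5_graph()
        cfg = sim.RandomWalkConfig(n_terminals=3, theta=1.0, seed=4)
        terminals = sim.random_walk_terminals(g, cfg)
        assert len(terminals) == 3
        # theta=1 marks every first visit, so terminals form a contiguous
        # stretch of the walk: they induce a connected sub-path here
        assert nx.is_connected(g.subgraph(terminals))

    def test_deterministic_under_seed(self, small_net):
        cfg = sim.RandomWalkConfig(n_terminals=5, theta=0.5, seed=11)
        assert sim.random_walk_terminals(small_net, cfg) == sim.random_walk_terminals(
            small_net, cfg
        )

    def test_exact_count_and_single_component(self, small_net):
        for seed in range(10):
            cfg = sim.RandomWalkConfig(n_terminals=5, theta=0.5, seed=seed)
            terminals = sim.random_walk_terminals(small_net, cfg)
            assert len(terminals) == 5
            comp = nx.node_connected_component(small_net, min(terminals))
            assert terminals <= comp

    def test_component_too_small_rejected(self):
        g = path5_graph()
        cfg = sim.RandomWalkConfig(n_terminals=6, theta=1.0, seed=0)
        with pytest.raises(ValueError, match="fewer than"):
            sim.random_walk_terminals(g, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            sim.RandomWalkConfig(n_terminals=5, theta=0.0)
        with pytest.raises(ValueError):
            sim.RandomWalkConfig(n_terminals=1)

    def test_thinning_doubles_walk_length(self):
        """With theta = 0.5 collecting n terminals needs about twice the
        distinct visits needed at theta = 1 (geometric thinning)."""
        g = sim.generate_synthetic_network("scale-free", 100, attachment=3, seed=9)

        def visits_needed(theta, seed):
            import random

            rng = random.Random(seed)
            start = rng.choice(sorted(g.nodes()))
            terminals, visited, current, steps = set(), set(), start, 0
            while len(terminals) < 5:
                if current not in visited:
                    visited.add(current)
                    if rng.random() < theta:
                        terminals.add(current)
                current = rng.choice(sorted(g[current]))
                steps += 1
            return len(visited)

        mean_half = sum(visits_needed(0.5, s) for s in range(300)) / 300
        mean_full = sum(visits_needed(1.0, s) for s in range(300)) / 300
        assert mean_half == pytest.approx(2 * mean_full, rel=0.25)


class TestSampleSubgraph:
    def test_min_nodes_one_gives_closed_neighborhood(self, small_net):
        sub = sim.sample_subgraph(small_net, min_nodes=1, seed=2)
        center = [n for n in sub.nodes() if sub.degree(n) == sub.number_of_nodes() - 1]
        assert sub.number_of_nodes() >= 1
        assert nx.is_connected(sub)
        assert center  # the start node touches everything added

    def test_reproducible(self, small_net):
        a = sim.sample_subgraph(small_net, min_nodes=30, seed=5)
        b = sim.sample_subgraph(small_net, min_nodes=30, seed=5)
        assert nx.utils.graphs_equal(a, b)
        assert a.number_of_nodes() >= 30

    def test_component_exhaustion_guard(self):
        g = path5_graph()
        sub = sim.sample_subgraph(g, min_nodes=30, seed=1)
        assert set(sub.nodes()) == set(g.nodes())

    def test_edges_are_subset_of_network(self, small_net):
        sub = sim.sample_subgraph(small_net, min_nodes=25, seed=8)
        assert all(small_net.has_edge(u, v) for u, v in sub.edges())


class TestGenerateSyntheticNetwork:
    def test_scale_free_heavy_tail(self):
        net = sim.generate_synthetic_network("scale-free", 2000, attachment=3, seed=7)
        assert nx.is_connected(net)
        degrees = sorted(d for _, d in net.degree())
        assert degrees[-1] > 10 * degrees[len(degrees) // 2]

    def test_erdos_renyi_below_threshold_returns_lcc(self):
        net = sim.generate_synthetic_network("erdos-renyi", 50, n_edges=25, seed=1)
        assert nx.is_connected(net)
        assert net.number_of_nodes() < 50

    def test_deterministic(self):
        a = sim.generate_synthetic_network("scale-free", 200, attachment=2, seed=4)
        b = sim.generate_synthetic_network("scale-free", 200, attachment=2, seed=4)
        assert nx.utils.graphs_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sim.generate_synthetic_network("scale-free", 10, attachment=10)
        with pytest.raises(ValueError):
            sim.generate_synthetic_network("erdos-renyi", 10)
        with pytest.raises(ValueError):
            sim.generate_synthetic_network("watts", 10)


class TestRunBenchmark:
    def test_record_count(self, small_net):
        records = sim.run_benchmark(
            small_net, ["sp"], terminal_sizes=[4], replicates=2, seed=0
        )
        assert len(records) == 2
        assert all(r.error is None for r in records)

    def test_deterministic_but_for_runtime(self, small_net):
        kwargs = dict(
            methods=["sp", "asp"], terminal_sizes=[4], replicates=3, seed=9
        )
        a = sim.records_to_dataframe(sim.run_benchmark(small_net, **kwargs))
        b = sim.records_to_dataframe(sim.run_benchmark(small_net, **kwargs))
        cols = [c for c in a.columns if c != "runtime_seconds"]
        assert a[cols].equals(b[cols])

    def test_sp_never_larger_than_asp(self, small_net):
        records = sim.run_benchmark(
            small_net, ["sp", "asp"], terminal_sizes=[8], replicates=20, seed=2
        )
        df = sim.records_to_dataframe(records)
        wide = df.pivot(index="replicate", columns="method", values="n_edges")
        assert (wide["sp"] <= wide["asp"]).all()

    def test_unknown_method_rejected(self, small_net):
        with pytest.raises(ValueError, match="unknown methods"):
            sim.run_benchmark(small_net, ["pcst"], [4], replicates=1)

    def test_method_failure_recorded_not_raised(self, small_net):
        # exact refuses the 120-node network via its guard
        records = sim.run_benchmark(
            small_net, ["exact", "sp"], terminal_sizes=[4], replicates=2, seed=0
        )
        exact = [r for r in records if r.method == "exact"]
        assert all(r.error is not None for r in exact)
        assert all(r.error is None for r in records if r.method == "sp")


class TestCompareMethods:
    def _records(self, pairs, method_names=("m1", "m2")):
        from steinersub.steiner_core import SolutionMetrics

        records = []
        for rep, (a, b) in enumerate(pairs):
            for name, value in zip(method_names, (a, b)):
                records.append(
                    sim.BenchmarkRecord(
                        method=name,
                        n_terminals=5,
                        replicate=rep,
                        seed=rep,
                        metrics=SolutionMetrics(
                            n_nodes=value + 1,
                            n_edges=value,
                            terminal_frequency=0.5,
                            runtime_seconds=0.0,
                        ),
                    )
                )
        return records

    def test_identical_vectors_marked(self):
        table = sim.compare_methods(self._records([(3, 3)] * 6))
        assert table.loc[0, "direction"] == "identical"
        assert math.isnan(table.loc[0, "p_raw"])

    def test_one_signed_n6_matches_closed_form(self):
        """Six all-negative differences: two-sided exact p = 2/2^6."""
        pairs = [(1, 2), (1, 3), (1, 4), (1, 5), (1, 6), (1, 7)]
        table = sim.compare_methods(self._records(pairs))
        assert table.loc[0, "direction"] == "first smaller"
        assert table.loc[0, "p_raw"] == pytest.approx(0.03125)

    def test_holm_arithmetic(self):
        assert sim.holm_adjust([0.01, 0.02, 0.20]) == pytest.approx(
            [0.03, 0.04, 0.20]
        )

    def test_holm_monotone_and_at_least_raw(self):
        raw = [0.04, 0.001, 0.03, 0.5, 0.2]
        adj = sim.holm_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        order = sorted(range(len(raw)), key=raw.__getitem__)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] for i in range(len(raw) - 1)
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            sim.compare_methods(self._records([(1, 2)] * 5))
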