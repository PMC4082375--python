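"""Forward simulator, reduction protocol and degradation."""

import math
import random

import pytest

from historygraph import (SimParams, apply_reduction, bounds_report,
                          degrade, is_avg, reduce_to_leaves,
                          simple_history_costs, simulate_history,
                          simulate_pair, validate_simple_history)


class TestSimulateHistory:
    def test_zero_epochs_gives_the_initial_thread(self):
        g = simulate_history(SimParams(epochs=0), seed=1)
        assert len(g.threads()) == 1
        assert len(g.vertices()) == 5

    def test_selection_predicate_holds_across_seeds(self):
        for seed in range(30):
            h = simulate_history(seed=seed)
            ok, epochs, reason = validate_simple_history(h)
            assert ok, reason
            assert sum(1 for e in epochs
                       if e.kind == "replication") >= 2
            s, r = simple_history_costs(h)
            assert s > 0 and r > 0

    def test_simulated_histories_are_tight_avgs(self):
        for seed in range(20):
            h = simulate_history(seed=seed)
            b = bounds_report(h)
            assert b.is_avg
            assert (b.s_l, b.r_l) == simple_history_costs(h)

    def test_determinism_per_seed(self):
        a = simulate_history(seed=5)
        b = simulate_history(seed=5)
        assert a.labels == b.labels
        assert a.adjacencies() == b.adjacencies()
        assert a.branches() == b.branches()


class TestReduceToLeaves:
    def test_result_keeps_only_leaf_threads_and_homology_stubs(self):
        h = simulate_history(seed=3)
        res = reduce_to_leaves(h)
        g = res.graph
        leaves = {v for v in h.vertices() if h.is_leaf(v)}
        assert {v for v in g.vertices() if g.is_labeled(v)} <= leaves
        for v in g.vertices():
            if v not in leaves:  # surviving ancestors are bare stubs
                assert not g.is_labeled(v)
                assert not g.is_attached(v)
                assert g.parent(v) is None

    def test_log_replays_to_the_same_graph(self):
        for seed in range(5):
            h = simulate_history(seed=seed)
            res = reduce_to_leaves(h)
            g = h.copy()
            for op in res.log:
                g = apply_reduction(g, op)
            assert g.labels == res.graph.labels
            assert g.adjacencies() == res.graph.adjacencies()
            assert g.branches() == res.graph.branches()

    def test_reduction_bounds_sandwich_the_history(self, sim_pairs):
        for h, g in sim_pairs[:100]:
            s, r = simple_history_costs(h)
            b = bounds_report(g)
            assert b.s_l <= s
            assert b.r_l <= r


class TestDegrade:
    def test_fraction_zero_is_identity(self):
        h = simulate_history(seed=2)
        g = reduce_to_leaves(h).graph
        out = degrade(g, 0.0, random.Random(0)).graph
        assert out.labels == g.labels
        assert out.adjacencies() == g.adjacencies()

    def test_fraction_one_strips_everything(self):
        h = simulate_history(seed=2)
        g = reduce_to_leaves(h).graph
        out = degrade(g, 1.0, random.Random(0)).graph
        assert all(not out.is_labeled(v) for v in out.vertices())
        assert out.adjacencies() == []

    def test_mean_removal_share_matches_the_rate(self):
        """Monte-Carlo: the mean share of removed leaf vertices (each
        removed only by its own coin) stays within three binomial
        standard errors of the nominal 10%.  Labels and adjacencies are
        additionally removed as dependents of removed vertices, so
        their effective rate sits at or above the nominal one."""
        h = simulate_history(seed=4)
        g = reduce_to_leaves(h).graph
        leaves = {v for v in g.vertices() if g.is_leaf(v)}
        removed_vertices = removed_adjacencies = 0
        trials = 100
        for seed in range(trials):
            out = degrade(g, 0.10, random.Random(seed)).graph
            removed_vertices += len(leaves - set(out.vertices()))
            removed_adjacencies += (len(g.adjacencies())
                                    - len(out.adjacencies()))
        mean_share = removed_vertices / (trials * len(leaves))
        se = math.sqrt(0.1 * 0.9 / (trials * len(leaves)))
        assert abs(mean_share - 0.10) < 3 * se
        adj_share = removed_adjacencies / (trials * len(g.adjacencies()))
        assert adj_share >= 0.10 - 3 * se

    def test_degraded_graphs_remain_valid(self, sim_pairs):
        for _, g in sim_pairs[:50]:
            assert g.is_valid()
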