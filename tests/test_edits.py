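"""Operator algebra: reductions, classification, G-boundedness, moves."""

import random

import pytest

from historygraph import (HEAD, TAIL, Fix, apply_g_bounded_op,
                          apply_reduction, bounds_report, build_graph,
                          classify_adjacency, classify_label,
                          composite_minimisation, g_bounded_ops,
                          is_g_bounded, lbrc, lbsc, legal_reductions,
                          ping_pong_pairs, unbridged_graph)
from historygraph.core import adjacency_key
from historygraph.edits import NON_MINIMAL_ADJ, NON_MINIMAL_LABEL
from historygraph.fixtures import fixture


class TestReductions:
    def test_deleting_the_only_adjacency_splits_a_thread(self):
        g = build_graph(vertices=[("a", "A"), ("b", "C")],
                        adjacencies=[((("a", HEAD)), ("b", TAIL))])
        g2 = apply_reduction(g, {"kind": "delete_adjacency",
                                 "sides": [("a", HEAD), ("b", TAIL)]})
        assert len(g2.threads()) == 2

    def test_free_child_contraction_reroots_grandchildren(self):
        g = build_graph(vertices=[("p", "A"), ("c", None), ("g1", "C"),
                                  ("g2", "G")],
                        branches=[("p", "c"), ("c", "g1"), ("c", "g2")])
        g2 = apply_reduction(g, {"kind": "contract_branch",
                                 "parent": "p", "child": "c"})
        assert "c" not in g2.labels
        assert g2.parent("g1") == "p" and g2.parent("g2") == "p"

    def test_contracting_an_attached_child_is_rejected(self):
        g = build_graph(vertices=[("p", "A"), ("c", None), ("w", "A")],
                        adjacencies=[((("c", HEAD)), ("w", HEAD))],
                        branches=[("p", "c")])
        with pytest.raises(ValueError, match="free"):
            apply_reduction(g, {"kind": "contract_branch",
                                "parent": "p", "child": "c"})

    def test_label_deletion_reroutes_lifts(self):
        f = fixture("fig2b")
        before = bounds_report(f.graph)
        g2 = apply_reduction(f.graph, {"kind": "delete_label",
                                       "vertex": "X"})
        after = bounds_report(g2)
        # the two identical lifted labels move up to the relabeled
        # ancestor where one matches another non-trivial lift
        assert after.u_s != before.u_s or after.s_l <= before.s_l

    def test_every_reduction_yields_a_valid_graph(self, sim_pairs):
        """Lemma-style closure: the result of any legal reduction
        operation is itself a history graph."""
        rng = random.Random(7)
        for _, g in sim_pairs[:10]:
            for op in rng.sample(legal_reductions(g),
                                 min(10, len(legal_reductions(g)))):
                assert apply_reduction(g, op).is_valid(), op

    def test_reductions_never_increase_lower_bounds(self, sim_pairs):
        """Applying a single reduction operation never increases LBSC
        or LBRC (1000 random graph/operation pairs)."""
        rng = random.Random(99)
        checked = 0
        graphs = [g for _, g in sim_pairs]
        while checked < 1000:
            g = rng.choice(graphs)
            ops = legal_reductions(g)
            if not ops:
                continue
            op = rng.choice(ops)
            g2 = apply_reduction(g, op)
            assert lbsc(g2) <= lbsc(g), op
            assert lbrc(g2) <= lbrc(g), op
            checked += 1
            if rng.random() < 0.5:
                graphs.append(g2)  # walk deeper into the reduction order


class TestClassification:
    def test_junction_label(self):
        f = fixture("fig6a")
        assert classify_label(f.graph, "x") == "junction", f.note

    def test_bridge_label(self):
        f = fixture("fig6b")
        assert classify_label(f.graph, "x") == "bridge", f.note

    def test_redundant_label(self):
        g = build_graph(vertices=[("p", "A"), ("c", "A")],
                        branches=[("p", "c")])
        assert classify_label(g, "c") == "leaf"
        assert classify_label(g, "p") == "redundant"

    def test_junction_adjacency(self):
        f = fixture("fig6c")
        adj = adjacency_key(("r", HEAD), ("s", HEAD))
        assert classify_adjacency(f.graph, adj) == "junction", f.note

    def test_bridge_adjacency(self):
        f = fixture("fig6d")
        adj = adjacency_key(("x", HEAD), ("y", HEAD))
        assert classify_adjacency(f.graph, adj) == "bridge", f.note

    def test_leaf_adjacency(self):
        g = build_graph(vertices=[("a", "A"), ("b", "C")],
                        adjacencies=[((("a", HEAD)), ("b", HEAD))])
        adj = adjacency_key(("a", HEAD), ("b", HEAD))
        assert classify_adjacency(g, adj) == "leaf"

    def test_classification_is_total(self, sim_pairs):
        for _, g in sim_pairs[:5]:
            for v in g.vertices():
                if g.is_labeled(v):
                    cls = classify_label(g, v)
                    assert cls in {"junction", "bridge"} | NON_MINIMAL_LABEL
            for adj in g.adjacencies():
                cls = classify_adjacency(g, adj)
                assert cls in {"junction", "bridge"} | NON_MINIMAL_ADJ


class TestUnbridgedAndPingPong:
    def test_graph_without_reducible_bridges_is_unchanged(self):
        g = fixture("fig2b").graph
        fix = Fix.identity(g)
        g2 = unbridged_graph(g, fix)
        assert g2.adjacencies() == g.adjacencies()

    def test_reducible_bridge_cascade_is_deleted(self):
        f = fixture("fig6d")
        fix = Fix.identity(f.graph)
        fix.adjacencies.discard(adjacency_key(("x", HEAD), ("y", HEAD)))
        g2 = unbridged_graph(f.graph, fix)
        assert adjacency_key(("x", HEAD), ("y", HEAD)) \
            not in set(g2.adjacencies())

    def test_simple_histories_have_no_ping_pong(self):
        assert ping_pong_pairs(fixture("fig2d").graph) == []

    def test_published_ping_pong_configurations(self):
        f = fixture("fig6e")
        pairs = ping_pong_pairs(f.graph)
        assert pairs == [((("c", HEAD), ("d", HEAD)),
                          (("a", HEAD), ("b", HEAD)))], f.note
        assert len(ping_pong_pairs(fixture("fig15a").graph)) == 1
        assert len(ping_pong_pairs(fixture("fig15b").graph)) == 2
        assert len(ping_pong_pairs(fixture("fig15c").graph)) == 2


class TestGBounded:
    def test_seed_with_identity_fix_is_bounded(self):
        g = fixture("fig2b").graph
        ok, diags = is_g_bounded(g, Fix.identity(g))
        assert ok, diags

    def test_reducible_redundant_label_breaks_boundedness(self):
        g = build_graph(vertices=[("p", "A"), ("c", "A")],
                        branches=[("p", "c")])
        fix = Fix.identity(g)
        fix.labels.discard("p")
        ok, diags = is_g_bounded(g, fix)
        assert not ok
        assert any("redundant" in d and "'p'" in d for d in diags)

    def test_composite_minimisation_cleans_a_detached_chain(self):
        g = build_graph(
            vertices=[("r", None), ("m", None), ("leaf", "A")],
            branches=[("r", "m"), ("m", "leaf")])
        fix = Fix(vertices={"leaf"}, labels={"leaf"})
        g2 = composite_minimisation(g, fix, "m")
        assert set(g2.vertices()) == {"leaf", "r"} or \
            set(g2.vertices()) == {"leaf"}

    def test_labeled_vertex_is_left_alone(self):
        g = build_graph(vertices=[("p", "A"), ("c", "C")],
                        branches=[("p", "c")])
        g2 = composite_minimisation(g, Fix.identity(g), "c")
        assert set(g2.vertices()) == {"p", "c"}

    def test_isolated_reducible_vertex_is_deleted(self):
        g = build_graph(vertices=[("a", "A"), ("x", None)])
        fix = Fix(vertices={"a"}, labels={"a"})
        g2 = composite_minimisation(g, fix, "x")
        assert set(g2.vertices()) == {"a"}


class TestGBoundedOps:
    def test_seed_graph_offers_only_attachments(self):
        g = fixture("fig2b").graph
        fix = Fix.identity(g)
        ops = g_bounded_ops(g, fix)
        assert ops, "a non-AVG seed must have applicable moves"
        assert all(op["kind"] not in ("label_detachment",
                                      "adjacency_detachment",
                                      "lateral_detachment")
                   for op in ops)

    def test_every_listed_op_preserves_boundedness(self):
        g = fixture("fig2b").graph
        fix = Fix.identity(g)
        for op in g_bounded_ops(g, fix)[:8]:
            g2 = apply_g_bounded_op(g, fix, op)
            ok, diags = is_g_bounded(g2, fix)
            assert ok, (op, diags)

    def test_detachments_reach_the_seed_again(self):
        """Navigability: label/adjacency detachments undo an extension
        step by step until the seed graph returns."""
        g = fixture("fig2b").graph
        fix = Fix.identity(g)
        rng = random.Random(5)
        cur = g
        for _ in range(4):  # extend four moves up
            from historygraph.edits import random_g_bounded_attachment
            step = random_g_bounded_attachment(cur, fix, rng)
            if step is None:
                break
            _, cur = step
        guard = 0
        while True:
            guard += 1
            assert guard < 50
            det = [op for op in g_bounded_ops(cur, fix)
                   if op["kind"] in ("label_detachment",
                                     "adjacency_detachment")]
            if not det:
                break
            cur = apply_g_bounded_op(cur, fix, det[0])
        assert set(cur.vertices()) == set(g.vertices())
        assert cur.adjacencies() == g.adjacencies()
        assert {v: cur.label(v) for v in cur.vertices()} == \
            {v: g.label(v) for v in g.vertices()}

    def test_detach_then_inverse_attachment_restores_graph(self):
        """A label detachment followed by relabeling restores an
        id-identical graph."""
        g = fixture("fig2b").graph
        fix = Fix.identity(g)
        fix.labels.discard("X")  # make X's label reducible
        g2 = apply_g_bounded_op(
            g, fix, {"kind": "label_detachment", "vertex": "X"})
        assert g2.label("X") is None
        g3 = apply_g_bounded_op(
            g2, fix, {"kind": "root_labeling", "vertex": "X",
                      "label": "G"})
        assert g3.labels == g.labels
        assert g3.adjacencies() == g.adjacencies()
        assert g3.branches() == g.branches()


class TestLateralDetachment:
    def _nested_junction_graph(self):
        g = build_graph(
            vertices=[(v, "A") for v in
                      ("p", "q", "x", "x2", "y", "y2",
                       "c1", "c2", "d1", "d2")],
            adjacencies=[((("p", HEAD)), ("q", HEAD)),
                         ((("x", HEAD)), ("y", HEAD)),
                         ((("x2", HEAD)), ("y2", HEAD)),
                         ((("c1", HEAD)), ("d1", HEAD)),
                         ((("c2", HEAD)), ("d2", HEAD))],
            branches=[("p", "x"), ("p", "x2"), ("q", "y"), ("q", "y2"),
                      ("x", "c1"), ("x", "c2"), ("y", "d1"), ("y", "d2")])
        return g

    def test_lateral_detachment_removes_exactly_one_adjacency(self):
        from historygraph.edits import candidate_detachments
        g = self._nested_junction_graph()
        fix = Fix()  # everything reducible
        laterals = [op for op in candidate_detachments(g, fix)
                    if op["kind"] == "lateral_detachment"]
        assert laterals, "nested junction pair should admit lateral moves"
        applied = 0
        for op in laterals:
            try:
                g2 = apply_g_bounded_op(g, fix, op)
            except ValueError:
                continue
            assert len(g2.adjacencies()) == len(g.adjacencies()) - 1
            assert g2.is_valid()
            applied += 1
        assert applied > 0
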