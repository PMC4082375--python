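"""Core data model: validation, threads, sequences, event graph."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from historygraph import (HEAD, TAIL, HistoryGraph, build_graph, opposite,
                          reverse_complement)
from historygraph.fixtures import (TOP_THREAD_RC_PREFIX,
                                   TOP_THREAD_SEQUENCE, fixture)


class TestValidation:
    def test_empty_graph_is_valid(self):
        assert HistoryGraph().validate() == []

    def test_parallel_adjacencies_flag_each_overattached_side(self):
        g = build_graph(
            vertices=[("x", "A"), ("y", "C")],
            adjacencies=[((("x", HEAD)), ("y", HEAD)),
                         ((("x", HEAD)), ("y", HEAD))],
            strict=False)
        codes = [v.code for v in g.validate()]
        assert codes.count("side-multiply-attached") == 2

    def test_event_graph_cycle_detected(self):
        # two threads x--y and x'--y' with branches closing a directed
        # loop between the two thread components
        g = build_graph(
            vertices=[("x", "A"), ("y", "C"), ("xp", "A"), ("yp", "C")],
            adjacencies=[((("x", HEAD)), ("y", TAIL)),
                         ((("xp", HEAD)), ("yp", TAIL))],
            branches=[("x", "yp"), ("xp", "y")])
        assert any(v.code == "event-graph-cycle" for v in g.validate())

    def test_multiple_parents_reported(self):
        g = build_graph(vertices=[("a", None), ("b", None), ("c", None)],
                        branches=[("a", "c"), ("b", "c")], strict=False)
        assert any(v.code == "multiple-parents" for v in g.validate())

    def test_self_pairing_side_rejected(self):
        g = build_graph(vertices=[("a", "A")])
        with pytest.raises(ValueError):
            g.add_adjacency(("a", HEAD), ("a", HEAD))

    def test_loop_between_both_sides_of_one_vertex_is_legal(self):
        g = build_graph(vertices=[("a", "A")],
                        adjacencies=[((("a", HEAD)), ("a", TAIL))])
        assert g.validate() == []
        (t,) = g.threads()
        assert t.is_circular


class TestThreads:
    def test_isolated_vertices_are_singleton_linear_threads(self):
        g = build_graph(vertices=[("a", "A"), ("b", "C"), ("c", "G")])
        threads = g.threads()
        assert len(threads) == 3
        assert all(t.is_linear and len(t.vertices) == 1 for t in threads)

    def test_two_vertex_cycle_is_circular(self):
        g = build_graph(vertices=[("a", "A"), ("b", "C")],
                        adjacencies=[((("a", HEAD)), ("b", TAIL)),
                                     ((("b", HEAD)), ("a", TAIL))])
        (t,) = g.threads()
        assert t.is_circular

    def test_published_thread_graph_has_three_linear_threads(self):
        f = fixture("fig1")
        threads = f.graph.threads()
        assert len(threads) == 3, f.note
        assert all(t.is_linear for t in threads)

    def test_event_graph_nodes_match_thread_parts(self):
        for name in ("fig1", "fig2b", "fig2d", "fig5"):
            g = fixture(name).graph
            assert g.event_graph().number_of_nodes() == len(g.threads())


class TestSequences:
    def test_single_vertex_reads_forward_and_reverse(self):
        g = build_graph(vertices=[("v", "ACG")])
        (t,) = g.threads()
        assert g.thread_sequence(t, ("v", TAIL)) == "ACG"
        assert g.thread_sequence(t, ("v", HEAD)) == "CGT"

    def test_published_top_thread_sequence(self):
        f = fixture("fig1")
        top = f.graph.thread_of("t1a")
        seq = f.graph.thread_sequence(top, ("t1a", TAIL))
        assert seq == TOP_THREAD_SEQUENCE, f.note
        rev = f.graph.thread_sequence(top, ("t1c", HEAD))
        assert rev.startswith(TOP_THREAD_RC_PREFIX), f.note
        assert rev == reverse_complement(seq)

    def test_missing_label_is_an_error(self):
        g = build_graph(vertices=[("a", "A"), ("b", None)],
                        adjacencies=[((("a", HEAD)), ("b", TAIL))])
        (t,) = g.threads()
        with pytest.raises(ValueError, match="missing label"):
            g.thread_sequence(t, ("a", TAIL))

    def test_circular_thread_needs_a_start(self):
        g = build_graph(vertices=[("a", "A")],
                        adjacencies=[((("a", HEAD)), ("a", TAIL))])
        (t,) = g.threads()
        with pytest.raises(ValueError, match="no canonical start"):
            g.thread_sequence(t)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=5),
                    min_size=1, max_size=5),
           st.lists(st.booleans(), min_size=5, max_size=5))
    def test_reading_both_ends_gives_reverse_complements(self, labels,
                                                         flips):
        g = HistoryGraph()
        side_out = None
        first_in = None
        for i, (lab, flip) in enumerate(zip(labels, flips)):
            vid = g.add_vertex(f"v{i}", lab)
            enter, leave = (TAIL, HEAD) if not flip else (HEAD, TAIL)
            if side_out is not None:
                g.add_adjacency(side_out, (vid, enter))
            else:
                first_in = (vid, enter)
            side_out = (vid, leave)
        (t,) = g.threads()
        fwd = g.thread_sequence(t, first_in)
        rev = g.thread_sequence(t, side_out)
        assert rev == reverse_complement(fwd)


def test_opposite_is_an_involution():
    assert opposite(HEAD) == TAIL and opposite(TAIL) == HEAD
    with pytest.raises(ValueError):
        opposite("sideways")
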