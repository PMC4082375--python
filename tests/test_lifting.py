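"""Lifted graph machinery: ancestors, multisets, junctions, modules."""

from historygraph import HEAD, TAIL, build_graph
from historygraph.fixtures import fixture
from historygraph.lifting import Lifting, free_root_id, is_free_root


def chain_graph():
    """x(labeled) -> y(unlabeled) -> z(labeled); only x attached."""
    return build_graph(
        vertices=[("x", "A"), ("y", None), ("z", "C"), ("w", "G")],
        adjacencies=[((("x", HEAD)), ("w", TAIL))],
        branches=[("x", "y"), ("y", "z")])


class TestLiftingAncestors:
    def test_nearest_labeled_ancestor_skips_unlabeled(self):
        lift = Lifting(chain_graph())
        assert lift.lifting_ancestor_vertex("z") == "x"
        assert lift.lifting_ancestor_vertex("y") == "x"

    def test_root_lifts_to_its_free_root(self):
        lift = Lifting(chain_graph())
        assert lift.lifting_ancestor_vertex("x") == free_root_id("x")

    def test_all_unlabeled_tree_lifts_to_free_root(self):
        g = build_graph(vertices=[("r", None), ("c", None), ("d", None)],
                        branches=[("r", "c"), ("c", "d")])
        lift = Lifting(g)
        fr = free_root_id("r")
        assert {lift.lifting_ancestor_vertex(v)
                for v in ("c", "d")} == {fr}

    def test_side_ancestor_uses_attachment_not_labels(self):
        lift = Lifting(chain_graph())
        assert lift.lifting_ancestor_side(("z", HEAD)) == ("x", HEAD)
        # tail of x is unattached, so z's tail lifts to the free root
        assert lift.lifting_ancestor_side(("z", TAIL)) == \
            (free_root_id("x"), TAIL)


class TestLiftedLabels:
    def test_labeled_leaf_owns_no_lifted_labels(self):
        lift = Lifting(chain_graph())
        assert lift.labels_at("z") == []

    def test_trivial_and_nontrivial_children(self):
        g = build_graph(vertices=[("p", "A"), ("u", "A"), ("v", "C")],
                        branches=[("p", "u"), ("p", "v")])
        lift = Lifting(g)
        by_label = {ll.label: ll.trivial for ll in lift.labels_at("p")}
        assert by_label == {"A": True, "C": False}

    def test_single_lift_at_free_root_is_trivial(self):
        g = build_graph(vertices=[("r", None), ("c", "A")],
                        branches=[("r", "c")])
        lift = Lifting(g)
        (ll,) = lift.labels_at(free_root_id("r"))
        assert ll.trivial

    def test_label_conservation(self, sim_pairs):
        """Every labeled vertex contributes exactly one lifted label."""
        for h, g in sim_pairs[:10]:
            for graph in (h, g):
                lift = Lifting(graph)
                labeled = sum(1 for v in graph.vertices()
                              if graph.is_labeled(v))
                assert len(lift.lifted_labels) == labeled

    def test_triviality_stable_under_isolated_vertex(self):
        g = fixture("fig2b").graph
        before = {(ll.owner, ll.source, ll.trivial)
                  for ll in Lifting(g).lifted_labels}
        g2 = g.copy()
        g2.add_vertex("isolated_extra", None)
        after = {(ll.owner, ll.source, ll.trivial)
                 for ll in Lifting(g2).lifted_labels}
        assert before == after


class TestJunctionsAndAdjacencies:
    def test_single_thread_without_branches_has_no_junctions(self):
        g = fixture("fig1").graph
        assert Lifting(g).junctions == set()

    def test_root_with_two_attached_children_is_a_junction(self):
        g = build_graph(
            vertices=[("r", "A"), ("c1", "A"), ("c2", "A")],
            adjacencies=[((("c1", HEAD)), ("c2", HEAD))],
            branches=[("r", "c1"), ("r", "c2")])
        assert ("r", HEAD) in Lifting(g).junctions

    def test_adjacency_between_roots_lifts_trivially_to_free_roots(self):
        g = build_graph(vertices=[("a", "A"), ("b", "C")],
                        adjacencies=[((("a", HEAD)), ("b", TAIL))])
        lift = Lifting(g)
        (edge,) = lift.lifted_edges
        assert edge.trivial
        assert all(is_free_root(end[0]) for end in edge.ends)

    def test_mirrored_child_adjacency_lifts_trivially(self):
        g = build_graph(
            vertices=[("p", "A"), ("q", "C"), ("pc", "A"), ("qc", "C")],
            adjacencies=[((("p", HEAD)), ("q", HEAD)),
                         ((("pc", HEAD)), ("qc", HEAD))],
            branches=[("p", "pc"), ("q", "qc")])
        lift = Lifting(g)
        by_src = {e.source: e for e in lift.lifted_edges}
        child = by_src[(("pc", HEAD), ("qc", HEAD))]
        assert child.trivial
        assert set(child.ends) == {("p", HEAD), ("q", HEAD)}

    def test_side_conservation(self, sim_pairs):
        """Each real adjacency produces exactly one lifted edge (two
        incidences)."""
        for h, g in sim_pairs[:10]:
            lift = Lifting(g)
            assert len(lift.lifted_edges) == len(g.adjacencies())
            inc = sum(len(lift.edges_at(s)) for s in lift._edges_by_side)
            assert inc == 2 * len(g.adjacencies())


class TestModules:
    def test_branchless_thread_modules_are_attached_pairs(self):
        g = fixture("fig1").graph
        lift = Lifting(g)
        mods = lift.modules()
        # each real adjacency forms a 2-side module, each free-root pair
        # another one
        assert all(len(m) == 2 for m in mods)
        assert sum(1 for m in mods if m.real) == len(g.adjacencies())

    def test_empty_graph_has_no_modules(self):
        from historygraph import HistoryGraph
        assert Lifting(HistoryGraph()).modules() == []

    def test_lifted_edge_endpoints_share_a_module(self, sim_pairs):
        for _, g in sim_pairs[:10]:
            lift = Lifting(g)
            side_mod = {s: i for i, m in enumerate(lift.modules())
                        for s in m.sides}
            for e in lift.lifted_edges:
                assert side_mod[e.ends[0]] == side_mod[e.ends[1]]
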