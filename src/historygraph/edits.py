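"""Reduction/extension operator algebra and the G-bounded machinery.

A *reduction operation* deletes an adjacency, an isolated vertex or a
label, or contracts a branch with a free-child or free-parent; its
inverse is an *extension operation*.  Extensions of a seed graph G are
explored through a *fix*: a tracked embedded copy of G inside the
extension.  Elements outside the fix play the role of G-reducible
elements; this trades the (possibly intractable) question of
G-reducibility for membership in one equivalence class of reduction
sequences.

On top of the algebra sit the classification of labels and adjacencies
(junction / bridge / the non-minimal taxonomy), the unbridged graph,
ping-pong adjacency detection, the G-boundedness test, and the
enumeration of G-bounded detachment/attachment moves used to navigate
the G-bounded poset.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import (HEAD, ORIENTATIONS, TAIL, Adjacency, HistoryGraph, Side,
                   adjacency_key)
from .lifting import Lifting, is_free_root

LABEL_CLASSES = ("junction", "bridge", "leaf", "redundant", "complicating",
                 "unnecessary_bridge")
ADJ_CLASSES = ("junction", "bridge", "leaf", "complex", "redundant",
               "complicating", "unnecessary_bridge", "removable_bridge")
NON_MINIMAL_LABEL = {"leaf", "redundant", "complicating", "unnecessary_bridge"}
NON_MINIMAL_ADJ = {"leaf", "complex", "redundant", "complicating",
                   "unnecessary_bridge", "removable_bridge"}


# ----------------------------------------------------------------------
# the fix
# ----------------------------------------------------------------------
@dataclass
class Fix:
    """The embedded copy of the seed graph G inside an extension.

    Elements recorded here are treated as G-irreducible; everything else
    is reducible.  Seed branches are kept as (ancestor, descendant)
    pairs: any branch path between the images realises them.
    """

    vertices: set[str] = field(default_factory=set)
    adjacencies: set[Adjacency] = field(default_factory=set)
    labels: set[str] = field(default_factory=set)  # vertex ids
    branch_pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def identity(cls, graph: HistoryGraph) -> "Fix":
        return cls(
            vertices=set(graph.vertices()),
            adjacencies=set(graph.adjacencies()),
            labels={v for v in graph.vertices() if graph.is_labeled(v)},
            branch_pairs=set(graph.branches()),
        )

    def copy(self) -> "Fix":
        return Fix(set(self.vertices), set(self.adjacencies),
                   set(self.labels), set(self.branch_pairs))

    # reducibility predicates -----------------------------------------
    def reducible_vertex(self, vid: str) -> bool:
        return vid not in self.vertices

    def reducible_label(self, vid: str) -> bool:
        return vid not in self.labels

    def reducible_adjacency(self, adj: Adjacency) -> bool:
        return adj not in self.adjacencies

    def check_embedded(self, graph: HistoryGraph) -> list[str]:
        """Why the fix is (not) still embedded in ``graph``; [] if intact."""
        problems = []
        for v in sorted(self.vertices):
            if v not in graph.labels:
                problems.append(f"fix vertex {v!r} missing")
        for v in sorted(self.labels):
            if v in graph.labels and graph.label(v) is None:
                problems.append(f"fix label on {v!r} missing")
        for adj in sorted(self.adjacencies):
            if adj not in set(graph.adjacencies()):
                problems.append(f"fix adjacency {adj} missing")
        for p, c in sorted(self.branch_pairs):
            if p in graph.labels and c in graph.labels:
                if p not in set(graph.ancestors(c)):
                    problems.append(f"fix branch {p!r}->{c!r} broken")
        return problems


# ----------------------------------------------------------------------
# reduction operations
# ----------------------------------------------------------------------
def _contract_free_child(g: HistoryGraph, parent: str, child: str) -> None:
    if g.is_labeled(child) or g.is_attached(child):
        raise ValueError(f"child {child!r} is not free "
                         "(it is labeled or attached)")
    for gc in g.children(child):
        g.delete_branch(child, gc)
        g.add_branch(parent, gc)
    g.delete_branch(parent, child)
    g.delete_vertex(child)


def _contract_free_parent(g: HistoryGraph, parent: str, child: str) -> None:
    if (g.is_labeled(parent) or g.is_attached(parent)
            or g.parent(parent) is not None or len(g.children(parent)) != 1):
        raise ValueError(f"parent {parent!r} is not free (must be an "
                         "unlabeled, unattached root with a single child)")
    g.delete_branch(parent, child)
    g.delete_vertex(parent)


def apply_reduction(graph: HistoryGraph, op: dict,
                    fix: Optional[Fix] = None) -> HistoryGraph:
    """Apply one reduction operation (a small JSON-able op record).

    Kinds: ``delete_adjacency`` (sides), ``delete_label`` (vertex),
    ``delete_vertex`` (vertex), ``contract_branch`` (parent, child).
    The side conditions of each operation are checked; with a ``fix``
    the operation is additionally rejected if it would damage the fix.
    """
    g = graph.copy()
    kind = op["kind"]
    if kind == "delete_adjacency":
        a, b = (tuple(op["sides"][0]), tuple(op["sides"][1]))
        key = adjacency_key(a, b)
        if fix is not None and not fix.reducible_adjacency(key):
            raise ValueError(f"adjacency {key} is in the fix")
        g.delete_adjacency(a, b)
    elif kind == "delete_label":
        v = op["vertex"]
        if not g.is_labeled(v):
            raise ValueError(f"vertex {v!r} has no label")
        if fix is not None and not fix.reducible_label(v):
            raise ValueError(f"label of {v!r} is in the fix")
        g.labels[v] = None
    elif kind == "delete_vertex":
        v = op["vertex"]
        if fix is not None and not fix.reducible_vertex(v):
            raise ValueError(f"vertex {v!r} is in the fix")
        g.delete_vertex(v)
    elif kind == "contract_branch":
        p, c = op["parent"], op["child"]
        if g.parent(c) != p:
            raise ValueError(f"no branch {(p, c)}")
        if not g.is_labeled(c) and not g.is_attached(c):
            if fix is not None and not fix.reducible_vertex(c):
                raise ValueError(f"fix vertex {c!r} cannot be contracted away")
            _contract_free_child(g, p, c)
        elif (not g.is_labeled(p) and not g.is_attached(p)
              and g.parent(p) is None and len(g.children(p)) == 1):
            if fix is not None and not fix.reducible_vertex(p):
                raise ValueError(f"fix vertex {p!r} cannot be contracted away")
            _contract_free_parent(g, p, c)
        else:
            raise ValueError(
                f"branch {(p, c)} has neither a free-child nor a free-parent")
    else:
        raise ValueError(f"unknown reduction kind {kind!r}")
    return g


def legal_reductions(graph: HistoryGraph,
                     fix: Optional[Fix] = None) -> list[dict]:
    """All single reduction operations applicable to ``graph``."""
    ops: list[dict] = []
    for adj in graph.adjacencies():
        if fix is None or fix.reducible_adjacency(adj):
            ops.append({"kind": "delete_adjacency", "sides": list(adj)})
    for v in graph.vertices():
        if graph.is_labeled(v) and (fix is None or fix.reducible_label(v)):
            ops.append({"kind": "delete_label", "vertex": v})
        if graph.is_isolated(v) and (fix is None or fix.reducible_vertex(v)):
            ops.append({"kind": "delete_vertex", "vertex": v})
    for p, c in graph.branches():
        free_child = not graph.is_labeled(c) and not graph.is_attached(c)
        free_parent = (not graph.is_labeled(p) and not graph.is_attached(p)
                       and graph.parent(p) is None
                       and len(graph.children(p)) == 1)
        gone = c if free_child else p
        if (free_child or free_parent) and (
                fix is None or fix.reducible_vertex(gone)):
            ops.append({"kind": "contract_branch", "parent": p, "child": c})
    return ops


# ----------------------------------------------------------------------
# classification (the non-minimal taxonomy)
# ----------------------------------------------------------------------
def classify_label(graph: HistoryGraph, vertex: str,
                   lifting: Optional[Lifting] = None) -> str:
    """Class of the label of ``vertex`` per the decision tree:
    junction > bridge > {leaf, redundant, complicating, unnecessary_bridge}.
    """
    if not graph.is_labeled(vertex):
        raise ValueError(f"vertex {vertex!r} is unlabeled")
    lift = lifting or Lifting(graph)
    lls = lift.labels_at(vertex)
    if len(lls) > 1:
        return "junction"
    anc = lift.lifting_ancestor_vertex(vertex)
    anc_label = None if is_free_root(anc) else graph.label(anc)
    if len(lls) == 1:
        (ll,) = lls
        if not ll.trivial and anc_label == graph.label(vertex) and any(
                not a.trivial for a in lift.labels_at(anc)):
            return "bridge"
        if ll.trivial:
            return "redundant"
        if anc_label != graph.label(vertex):
            return "complicating"
        return "unnecessary_bridge"
    return "leaf"


def _is_bridge_side(graph: HistoryGraph, lift: Lifting, side: Side) -> bool:
    if side in lift.junctions:
        return False
    if lift.nontrivial_incidences(side) != 1:
        return False
    partner = graph.partner(side)
    if partner is None:
        return False
    edge = next(e for e in lift.lifted_edges
                if e.source == adjacency_key(side, partner))
    if not edge.trivial:
        return False
    anc = lift.lifting_ancestor_side(side)
    if anc not in lift.junctions or lift.nontrivial_incidences(anc) < 1:
        return False
    # tentative deletion: one endpoint of the lifted edge must remain a
    # junction side once the adjacency is gone
    g2 = graph.copy()
    g2.delete_adjacency(side, partner)
    juncs2 = Lifting(g2).junctions
    return any(end in juncs2 for end in edge.ends)


def classify_adjacency(graph: HistoryGraph, adjacency: Adjacency,
                       lifting: Optional[Lifting] = None) -> str:
    """Class of an adjacency: junction > bridge > {leaf, complex,
    redundant, complicating, unnecessary_bridge, removable_bridge}."""
    lift = lifting or Lifting(graph)
    a, b = adjacency
    if a in lift.junctions or b in lift.junctions:
        return "junction"
    if _is_bridge_side(graph, lift, a) or _is_bridge_side(graph, lift, b):
        return "bridge"
    ia = len(lift.edges_at(a))
    ib = len(lift.edges_at(b))
    if ia + ib == 0:
        return "leaf"
    if ia > 1 or ib > 1:
        return "complex"
    received = {frozenset(e.ends) for s in (a, b) for e in lift.edges_at(s)}
    if received == {frozenset(adjacency)}:
        return "redundant"
    own = next(e for e in lift.lifted_edges if e.source == adjacency)
    if not own.trivial:
        return "complicating"
    anc_nontrivial = any(lift.nontrivial_incidences(end) > 0
                         for end in own.ends)
    if not anc_nontrivial:
        return "unnecessary_bridge"
    return "removable_bridge"


# ----------------------------------------------------------------------
# unbridged graph, ping-pong, G-boundedness
# ----------------------------------------------------------------------
def unbridged_graph(graph: HistoryGraph, fix: Fix) -> HistoryGraph:
    """Fixpoint of deleting G-reducible bridge adjacencies."""
    g = graph.copy()
    while True:
        lift = Lifting(g)
        target = None
        for adj in g.adjacencies():
            if fix.reducible_adjacency(adj) and \
                    classify_adjacency(g, adj, lift) == "bridge":
                target = adj
                break
        if target is None:
            return g
        g.delete_adjacency(*target)


def _hanging_sides(graph: HistoryGraph) -> set[Side]:
    """Sides with no attached proper descendants."""
    out: set[Side] = set()
    has_attached: dict[Side, bool] = {}
    order: list[str] = []
    for r in graph.roots():
        order.append(r)
        order.extend(graph.descendants(r))
    for v in reversed(order):
        for o in ORIENTATIONS:
            below = any(has_attached[(c, o)] for c in graph.children(v))
            has_attached[(v, o)] = below or graph.is_side_attached((v, o))
            if not below:
                out.add((v, o))
    return out


def ping_pong_pairs(graph: HistoryGraph,
                    lifting: Optional[Lifting] = None
                    ) -> list[tuple[Adjacency, Adjacency]]:
    """All (ping, pong) adjacency pairs.

    Both adjacencies have a hanging side, and the ping has an endpoint
    whose most recent attached ancestor is an endpoint of the pong.
    """
    lift = lifting or Lifting(graph)
    hanging = _hanging_sides(graph)
    with_hanging = [adj for adj in graph.adjacencies()
                    if adj[0] in hanging or adj[1] in hanging]
    pong_candidates = set(with_hanging)
    pairs = []
    for ping in with_hanging:
        for end in ping:
            anc = lift.lifting_ancestor_side(end)
            if is_free_root(anc[0]):
                continue
            partner = graph.partner(anc)
            if partner is None:
                continue
            pong = adjacency_key(anc, partner)
            if pong in pong_candidates and pong != ping:
                pairs.append((ping, pong))
    return sorted(set(pairs))


def is_g_bounded(graph: HistoryGraph, fix: Fix,
                 lifting: Optional[Lifting] = None,
                 collect: bool = True) -> tuple[bool, list[str]]:
    """Whether ``graph`` is a G-bounded extension of the fix's seed.

    G-bounded: the graph extends G, contains no G-reducible non-minimal
    element, and its G-unbridged graph contains no G-reducible ping
    adjacency.  Returns (flag, diagnostics).
    """
    problems = fix.check_embedded(graph)
    if problems:
        return False, problems
    lift = lifting or Lifting(graph)
    diags: list[str] = []

    def bad(msg: str) -> Optional[tuple[bool, list[str]]]:
        diags.append(msg)
        return None if collect else (False, diags)

    for v in graph.vertices():
        if graph.is_isolated(v) and fix.reducible_vertex(v):
            if bad(f"reducible isolated vertex {v!r}"):
                return False, diags
    for p, c in graph.branches():
        if (not graph.is_labeled(c) and not graph.is_attached(c)
                and fix.reducible_vertex(c)):
            if bad(f"reducible branch with free-child {(p, c)}"):
                return False, diags
        if (not graph.is_labeled(p) and not graph.is_attached(p)
                and graph.parent(p) is None and len(graph.children(p)) == 1
                and fix.reducible_vertex(p)):
            if bad(f"reducible branch with free-parent {(p, c)}"):
                return False, diags
    for v in graph.vertices():
        if graph.is_labeled(v) and fix.reducible_label(v):
            cls = classify_label(graph, v, lift)
            if cls in NON_MINIMAL_LABEL:
                if bad(f"reducible non-minimal ({cls}) label on {v!r}"):
                    return False, diags
    for adj in graph.adjacencies():
        if fix.reducible_adjacency(adj):
            cls = classify_adjacency(graph, adj, lift)
            if cls in NON_MINIMAL_ADJ:
                if bad(f"reducible non-minimal ({cls}) adjacency {adj}"):
                    return False, diags
    if not diags:
        ub = unbridged_graph(graph, fix)
        for ping, pong in ping_pong_pairs(ub):
            if fix.reducible_adjacency(ping):
                if bad(f"reducible ping adjacency {ping} (pong {pong}) "
                       "in the unbridged graph"):
                    return False, diags
    return not diags, diags


# ----------------------------------------------------------------------
# composite minimisation
# ----------------------------------------------------------------------
def composite_minimisation(graph: HistoryGraph, fix: Fix,
                           vertex: str) -> HistoryGraph:
    """The three conditional clean-up steps after a detachment, in order:
    contract the parent branch, then (if now a bare root) the single
    child branch, then delete the vertex if isolated — each only when the
    vertex involved is unlabeled, unattached and G-reducible."""
    g = graph.copy()
    x = vertex
    if (not g.is_labeled(x) and not g.is_attached(x)
            and g.parent(x) is not None and fix.reducible_vertex(x)):
        p = g.parent(x)
        _contract_free_child(g, p, x)
        x = p
    if (not g.is_labeled(x) and not g.is_attached(x)
            and g.parent(x) is None and len(g.children(x)) == 1
            and fix.reducible_vertex(x)):
        c = g.children(x)[0]
        _contract_free_parent(g, x, c)
        x = c
    if x in g.labels and g.is_isolated(x) and not g.is_labeled(x) \
            and fix.reducible_vertex(x):
        g.delete_vertex(x)
    return g


# ----------------------------------------------------------------------
# extension operations (op records are JSON-able and replayable)
# ----------------------------------------------------------------------
def _interpolate_above(g: HistoryGraph, vid: str,
                       label: Optional[str] = None) -> str:
    """Interpolate a new vertex on the parent branch of ``vid`` (or as a
    new root above it if it has none).  Returns the new vertex id."""
    new = g.add_vertex(g.fresh_id("e"), label)
    p = g.parent(vid)
    if p is not None:
        g.delete_branch(p, vid)
        g.add_branch(p, new)
    g.add_branch(new, vid)
    return new


def apply_extension(graph: HistoryGraph, op: dict) -> HistoryGraph:
    """Apply one extension / G-bounded operation record.

    New vertex ids are drawn from the graph's deterministic counter, so
    replaying the same op sequence on the same graph reproduces ids
    exactly.
    """
    g = graph.copy()
    kind = op["kind"]
    if kind == "root_labeling":
        v = op["vertex"]
        if g.is_labeled(v):
            raise ValueError(f"vertex {v!r} already labeled")
        g.labels[v] = op["label"]
    elif kind == "bridge_label":
        _interpolate_above(g, op["below"], op["label"])
    elif kind == "attach_new":
        side = tuple(op["side"])
        v = g.add_vertex(g.fresh_id("e"))
        g.add_adjacency(side, (v, side[1]))
    elif kind == "attach_child":
        side = tuple(op["side"])
        q = op["partner_parent"]
        child = g.add_vertex(g.fresh_id("e"))
        g.add_branch(q, child)
        g.add_adjacency(side, (child, op["orientation"]))
    elif kind == "attach_interpose":
        side = tuple(op["side"])
        w = op["below"]
        new = _interpolate_above(g, w)
        g.add_adjacency(side, (new, op["orientation"]))
    elif kind == "bridge_adjacency":
        x, alpha = op["below"], op["orientation"]
        z, gamma = op["partner_parent"], op["partner_orientation"]
        xp = _interpolate_above(g, x)
        zc = g.add_vertex(g.fresh_id("e"))
        g.add_branch(z, zc)
        g.add_adjacency((xp, alpha), (zc, gamma))
    else:
        raise ValueError(f"unknown extension kind {kind!r}")
    return g


def apply_g_bounded_op(graph: HistoryGraph, fix: Fix, op: dict) -> HistoryGraph:
    """Apply a G-bounded move: an extension record or a detachment record
    (``label_detachment`` / ``adjacency_detachment`` /
    ``lateral_detachment``), including composite minimisation."""
    kind = op["kind"]
    if kind == "label_detachment":
        v = op["vertex"]
        g = apply_reduction(graph, {"kind": "delete_label", "vertex": v}, fix)
        return composite_minimisation(g, fix, v)
    if kind == "adjacency_detachment":
        a, b = (tuple(op["sides"][0]), tuple(op["sides"][1]))
        g = apply_reduction(
            graph, {"kind": "delete_adjacency", "sides": [a, b]}, fix)
        g = composite_minimisation(g, fix, a[0])
        if b[0] in g.labels:
            g = composite_minimisation(g, fix, b[0])
        return g
    if kind == "lateral_detachment":
        first = adjacency_key(tuple(op["first"][0]), tuple(op["first"][1]))
        second = adjacency_key(tuple(op["second"][0]), tuple(op["second"][1]))
        s, t = (tuple(op["attach"][0]), tuple(op["attach"][1]))
        g = graph.copy()
        for adj in (first, second):
            if fix is not None and not fix.reducible_adjacency(adj):
                raise ValueError(f"adjacency {adj} is in the fix")
            g.delete_adjacency(*adj)
        g.add_adjacency(s, t)
        for vid in sorted({side[0] for side in (*first, *second)}):
            if vid in g.labels:
                g = composite_minimisation(g, fix, vid)
        return g
    return apply_extension(graph, op)


# ----------------------------------------------------------------------
# candidate enumeration for the G-bounded poset
# ----------------------------------------------------------------------
def _most_ancestral_attached_descendants(graph: HistoryGraph,
                                         side: Side) -> list[Side]:
    """Attached descendant sides of ``side`` (same orientation) with no
    attached side strictly between them and ``side``."""
    v, o = side
    out: list[Side] = []
    stack = list(graph.children(v))
    while stack:
        u = stack.pop()
        if graph.is_side_attached((u, o)):
            out.append((u, o))
        else:
            stack.extend(graph.children(u))
    return sorted(out)


def candidate_attachments(graph: HistoryGraph,
                          lift: Optional[Lifting] = None) -> list[dict]:
    """Unchecked candidate extension moves, following the constructive
    cases that always lead a non-AVG towards an AVG: root labelings,
    bridge labels, junction-side attachments (plain, child-of-partner,
    and hanging-avoiding interposition) and bridge adjacencies."""
    lift = lift or Lifting(graph)
    g = graph
    ops: list[dict] = []

    # 1. root labelings of ambiguous free roots
    for owner, lls in sorted(lift._labels_by_owner.items()):
        if not is_free_root(owner) or len(lls) <= 1:
            continue
        root = owner.split(":", 1)[1]
        if g.is_labeled(root):
            continue
        counts: dict[str, int] = {}
        for ll in lls:
            counts[ll.label] = counts.get(ll.label, 0) + 1
        best = max(counts.values())
        for lab in sorted(l for l, c in counts.items() if c == best):
            ops.append({"kind": "root_labeling", "vertex": root, "label": lab})

    # 2. bridge labels under substitution-ambiguous labeled vertices
    for v in g.vertices():
        if not g.is_labeled(v):
            continue
        nontrivial = [ll for ll in lift.labels_at(v) if not ll.trivial]
        if len(nontrivial) < 2:
            continue
        for ll in nontrivial:
            ops.append({"kind": "bridge_label", "below": ll.source,
                        "label": g.label(v)})

    # 3. attachments of unattached junction sides
    hanging = _hanging_sides(g)
    for side in sorted(lift.junctions):
        if g.is_side_attached(side):
            continue
        anc = lift.lifting_ancestor_side(side)
        if is_free_root(anc[0]):
            ops.append({"kind": "attach_new", "side": list(side)})
        else:
            partner = g.partner(anc)
            ops.append({"kind": "attach_child", "side": list(side),
                        "partner_parent": partner[0],
                        "orientation": partner[1]})
        # hanging-avoiding interposition above a hanging partner
        for d in _most_ancestral_attached_descendants(g, side):
            w = g.partner(d)
            if w in hanging:
                ops.append({"kind": "attach_interpose", "side": list(side),
                            "below": w[0], "orientation": w[1]})

    # 4. bridge adjacencies at attached, rearrangement-ambiguous junctions
    for side in sorted(lift._edges_by_side):
        if is_free_root(side[0]) or not g.is_side_attached(side):
            continue
        nontrivial = [e for e in lift.edges_at(side) if not e.trivial]
        if len(nontrivial) < 2:
            continue
        partner = g.partner(side)
        for e in nontrivial:
            src = e.source
            for end, anc_end in zip(src, e.ends):
                if anc_end == side:
                    ops.append({
                        "kind": "bridge_adjacency", "below": end[0],
                        "orientation": end[1], "partner_parent": partner[0],
                        "partner_orientation": partner[1]})
    return ops


def candidate_detachments(graph: HistoryGraph, fix: Fix,
                          lift: Optional[Lifting] = None) -> list[dict]:
    """Unchecked candidate detachment moves on G-reducible elements."""
    lift = lift or Lifting(graph)
    ops: list[dict] = []
    for v in graph.vertices():
        if graph.is_labeled(v) and fix.reducible_label(v):
            ops.append({"kind": "label_detachment", "vertex": v})
    reducible = [adj for adj in graph.adjacencies()
                 if fix.reducible_adjacency(adj)]
    for adj in reducible:
        ops.append({"kind": "adjacency_detachment", "sides": list(adj)})
    # lateral detachments of (junction, lifted-partner junction) pairs
    for adj in reducible:
        if classify_adjacency(graph, adj, lift) != "junction":
            continue
        own = next(e for e in lift.lifted_edges if e.source == adj)
        second = adjacency_key(*own.ends)
        if second == adj or second not in set(graph.adjacencies()):
            continue
        if not fix.reducible_adjacency(second):
            continue
        if classify_adjacency(graph, second, lift) != "junction":
            continue
        (xa, yb) = adj
        (axa, ayb) = own.ends
        for attach in ([list(xa), list(ayb)], [list(yb), list(axa)],
                       [list(xa), list(yb)]):
            ops.append({"kind": "lateral_detachment", "first": list(adj),
                        "second": list(second), "attach": attach})
    return ops


def g_bounded_ops(graph: HistoryGraph, fix: Fix) -> list[dict]:
    """All applicable G-bounded moves: every returned op, when applied,
    yields a valid G-bounded history graph (verified by construction and
    by :func:`is_g_bounded`)."""
    lift = Lifting(graph)
    out = []
    for op in (candidate_detachments(graph, fix, lift)
               + candidate_attachments(graph, lift)):
        try:
            g2 = apply_g_bounded_op(graph, fix, op)
        except ValueError:
            continue
        if not g2.is_valid():
            continue
        ok, _ = is_g_bounded(g2, fix, collect=False)
        if ok:
            out.append(op)
    return out


def random_g_bounded_attachment(graph: HistoryGraph, fix: Fix,
                                rng: random.Random,
                                lift: Optional[Lifting] = None
                                ) -> Optional[tuple[dict, HistoryGraph]]:
    """One uniformly chosen applicable attachment move, or None on an AVG.

    Candidates are tried in random order and the first whose result is a
    valid G-bounded graph is returned; a non-AVG always has one.
    """
    lift = lift or Lifting(graph)
    cands = candidate_attachments(graph, lift)
    if not cands:
        return None
    rng.shuffle(cands)
    for op in cands:
        try:
            g2 = apply_g_bounded_op(graph, fix, op)
        except ValueError:
            continue
        if not g2.is_valid():
            continue
        ok, _ = is_g_bounded(g2, fix, collect=False)
        if ok:
            return op, g2
    return None
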