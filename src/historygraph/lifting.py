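"""The lifted graph L(G): projecting descendant state onto ancestors.

Labels and adjacencies of descendant vertices are *lifted* to their
nearest informative ancestor — the most recent labeled ancestor for a
vertex label, the most recent attached ancestor (same orientation) for an
attached side.  Where no such ancestor exists the lift lands on a virtual
*free root*, one per root vertex.  A lifted element is *trivial* when it
implies no evolutionary change; non-trivial lifts are exactly what the
cost bounds count.

Free roots are addressed as synthetic vertex ids ``"freeroot:<root id>"``;
they never appear inside a :class:`~historygraph.core.HistoryGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import (HEAD, ORIENTATIONS, TAIL, Adjacency, HistoryGraph, Side,
                   adjacency_key)

FREE_ROOT_PREFIX = "freeroot:"


def free_root_id(root: str) -> str:
    return FREE_ROOT_PREFIX + root


def is_free_root(owner: str) -> bool:
    return owner.startswith(FREE_ROOT_PREFIX)


@dataclass(frozen=True)
class LiftedLabel:
    """One lifted label: ``source``'s label projected onto ``owner``."""

    owner: str          # vertex id or free-root id
    source: str         # the labeled descendant it lifts from
    label: str
    trivial: bool


@dataclass(frozen=True)
class LiftedEdge:
    """The lifted adjacency of one real adjacency.

    ``ends`` are the lifting ancestors of the source endpoints, in source
    order.  If both ends coincide the edge contributes two incidences to
    that side.
    """

    source: Adjacency
    ends: tuple[Side, Side]
    trivial: bool


@dataclass
class Module:
    """A connected component of real + lifted adjacencies over sides."""

    sides: list[Side] = field(default_factory=list)
    real: list[Adjacency] = field(default_factory=list)
    lifted: list[LiftedEdge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sides)


class Lifting:
    """All lift-derived structure of a valid history graph, computed once."""

    def __init__(self, graph: HistoryGraph) -> None:
        self.graph = graph
        self._anc_vertex: dict[str, str] = {}
        self._anc_side: dict[Side, Side] = {}
        self._dirty_side: dict[Side, bool] = {}
        self.junctions: set[Side] = set()
        self.lifted_labels: list[LiftedLabel] = []
        self.lifted_edges: list[LiftedEdge] = []
        self._labels_by_owner: dict[str, list[LiftedLabel]] = {}
        self._edges_by_side: dict[Side, list[LiftedEdge]] = {}
        self._compute()

    # -- lifting ancestors --------------------------------------------
    def lifting_ancestor_vertex(self, vid: str) -> str:
        """Most recent labeled proper ancestor, else the tree's free root."""
        return self._anc_vertex[vid]

    def lifting_ancestor_side(self, side: Side) -> Side:
        """Most recent attached proper ancestor side, else a free-root side."""
        return self._anc_side[side]

    # -- multisets -----------------------------------------------------
    def labels_at(self, owner: str) -> list[LiftedLabel]:
        return self._labels_by_owner.get(owner, [])

    def edges_at(self, side: Side) -> list[LiftedEdge]:
        """Lifted edges incident with ``side`` (a self-lift appears twice)."""
        return self._edges_by_side.get(side, [])

    def nontrivial_incidences(self, side: Side) -> int:
        return sum(1 for e in self.edges_at(side) if not e.trivial)

    # -- modules -------------------------------------------------------
    def modules(self) -> list[Module]:
        parent: dict[Side, Side] = {}

        def find(s: Side) -> Side:
            while parent[s] != s:
                parent[s] = parent[parent[s]]
                s = parent[s]
            return s

        def union(a: Side, b: Side) -> None:
            for s in (a, b):
                parent.setdefault(s, s)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for a, b in self.graph.adjacencies():
            union(a, b)
        for e in self.lifted_edges:
            union(e.ends[0], e.ends[1])
        groups: dict[Side, Module] = {}
        for s in sorted(parent):
            groups.setdefault(find(s), Module()).sides.append(s)
        for adj in self.graph.adjacencies():
            groups[find(adj[0])].real.append(adj)
        for e in self.lifted_edges:
            groups[find(e.ends[0])].lifted.append(e)
        return [groups[k] for k in sorted(groups)]

    # -- computation ---------------------------------------------------
    def _compute(self) -> None:
        g = self.graph
        order = self._topological_vertices()
        # lifting ancestors, top-down
        for v in order:
            p = g.parent(v)
            if p is None:
                self._anc_vertex[v] = free_root_id(v)
            elif g.is_labeled(p):
                self._anc_vertex[v] = p
            else:
                self._anc_vertex[v] = self._anc_vertex[p]
            for o in ORIENTATIONS:
                if p is None:
                    self._anc_side[(v, o)] = (free_root_id(v), o)
                elif g.is_side_attached((p, o)):
                    self._anc_side[(v, o)] = (p, o)
                else:
                    self._anc_side[(v, o)] = self._anc_side[(p, o)]

        # junction sides: >=2 child subtrees containing an attached side
        has_attached: dict[Side, bool] = {}
        for v in reversed(order):
            for o in ORIENTATIONS:
                has_attached[(v, o)] = (
                    g.is_side_attached((v, o))
                    or any(has_attached[(c, o)] for c in g.children(v)))
        for v in order:
            for o in ORIENTATIONS:
                k = sum(1 for c in g.children(v) if has_attached[(c, o)])
                if k >= 2:
                    self.junctions.add((v, o))

        # clean paths: no unattached junction side strictly between a side
        # and its lifting ancestor
        def path_dirty(side: Side) -> bool:
            v, o = side
            anc = self._anc_side[side][0]
            p = g.parent(v)
            while p is not None and p != anc:
                if (p, o) in self.junctions and not g.is_side_attached((p, o)):
                    return True
                p = g.parent(p)
            return False

        # lifted labels
        for v in order:
            lab = g.label(v)
            if lab is None:
                continue
            owner = self._anc_vertex[v]
            if is_free_root(owner):
                trivial = True  # provisional; fixed below
            else:
                trivial = g.label(owner) == lab
            self.lifted_labels.append(LiftedLabel(owner, v, lab, trivial))
        by_owner: dict[str, list[LiftedLabel]] = {}
        for ll in self.lifted_labels:
            by_owner.setdefault(ll.owner, []).append(ll)
        for owner, lls in by_owner.items():
            if is_free_root(owner) and len(lls) > 1:
                by_owner[owner] = [
                    LiftedLabel(owner, ll.source, ll.label, False)
                    for ll in lls]
        self._labels_by_owner = by_owner
        self.lifted_labels = [ll for lls in by_owner.values() for ll in lls]

        # lifted adjacencies
        adj_set = set(g.adjacencies())
        for adj in g.adjacencies():
            a, b = adj
            ea, eb = self._anc_side[a], self._anc_side[b]
            dirty = path_dirty(a) or path_dirty(b)
            if dirty:
                trivial = False
            elif adjacency_key(ea, eb) in adj_set:
                trivial = True
            else:
                trivial = is_free_root(ea[0]) and is_free_root(eb[0])
            edge = LiftedEdge(adj, (ea, eb), trivial)
            self.lifted_edges.append(edge)
            self._edges_by_side.setdefault(ea, []).append(edge)
            if eb != ea:
                self._edges_by_side.setdefault(eb, []).append(edge)
            else:
                self._edges_by_side[ea].append(edge)  # self-lift counts twice

    def _topological_vertices(self) -> list[str]:
        g = self.graph
        out: list[str] = []
        for r in g.roots():
            out.append(r)
            out.extend(g.descendants(r))
        return out


# ----------------------------------------------------------------------
# spec-level convenience wrappers
# ----------------------------------------------------------------------
def lifting_ancestor_vertex(graph: HistoryGraph, vertex: str) -> str:
    return Lifting(graph).lifting_ancestor_vertex(vertex)


def lifting_ancestor_side(graph: HistoryGraph, side: Side) -> Side:
    return Lifting(graph).lifting_ancestor_side(side)


def lifted_labels(graph: HistoryGraph, owner: str) -> list[LiftedLabel]:
    return Lifting(graph).labels_at(owner)


def lifted_adjacencies(graph: HistoryGraph, owner_side: Side) -> list[LiftedEdge]:
    return Lifting(graph).edges_at(owner_side)


def junction_sides(graph: HistoryGraph) -> set[Side]:
    return Lifting(graph).junctions


def module_graph(graph: HistoryGraph) -> list[Module]:
    return Lifting(graph).modules()
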