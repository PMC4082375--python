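"""Bidirected sequence / thread / history graph data model.

A *history graph* couples two relationships between segments of DNA:

* covalent linkage, modelled by bidirected *adjacencies* between the
  oriented *sides* (head/tail) of vertices, and
* ancestry, modelled by directed *branches* between homologous vertices.

Vertices carry an optional DNA label (a multibase allele over {A,C,G,T});
an unlabeled vertex represents missing information.  Connected components
of the adjacency relation are *threads* (linear or circular chromosome
fragments); contracting all adjacencies yields the *event graph*, which
must be acyclic for the structure to be a coherent evolutionary history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import networkx as nx

HEAD = "head"
TAIL = "tail"
ORIENTATIONS = (HEAD, TAIL)

#: A side is a (vertex id, orientation) pair.
Side = tuple[str, str]
#: An adjacency is stored canonically as a sorted pair of sides.
Adjacency = tuple[Side, Side]
#: A branch is a (parent id, child id) pair.
Branch = tuple[str, str]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
DNA_ALPHABET = frozenset(_COMPLEMENT)


def opposite(orientation: str) -> str:
    """The other orientation: ``opposite(HEAD) == TAIL`` and vice versa."""
    if orientation == HEAD:
        return TAIL
    if orientation == TAIL:
        return HEAD
    raise ValueError(f"not an orientation: {orientation!r}")


def reverse_complement(label: str) -> str:
    """Reverse complement of a DNA label."""
    return "".join(_COMPLEMENT[b] for b in reversed(label))


def adjacency_key(a: Side, b: Side) -> Adjacency:
    """Canonical (sorted) form of an adjacency between two sides."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Violation:
    """One broken invariant, naming the offending elements."""

    code: str
    elements: tuple
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


class HistoryGraph:
    """A mutable history graph G = (V, E, B).

    Vertices are opaque string ids mapped to an optional label; adjacencies
    are unordered pairs of sides; branches are (parent, child) pairs.
    Mutators keep derived maps (side attachment, parent/children) in sync.
    All iteration orders are sorted so operations are deterministic.
    """

    def __init__(self) -> None:
        self.labels: dict[str, Optional[str]] = {}
        self._adjacencies: dict[Adjacency, None] = {}  # ordered set
        self._side_map: dict[Side, Side] = {}
        self._parent: dict[str, str] = {}
        self._children: dict[str, set[str]] = {}
        self._extra_attach: list[Side] = []  # sides attached more than once
        self._extra_parents: list[Branch] = []  # second+ incoming branches
        self._next_id = 0

    # ------------------------------------------------------------------
    # construction / copying
    # ------------------------------------------------------------------
    def copy(self) -> "HistoryGraph":
        g = HistoryGraph()
        g.labels = dict(self.labels)
        g._adjacencies = dict(self._adjacencies)
        g._side_map = dict(self._side_map)
        g._parent = dict(self._parent)
        g._children = {v: set(cs) for v, cs in self._children.items()}
        g._extra_attach = list(self._extra_attach)
        g._extra_parents = list(self._extra_parents)
        g._next_id = self._next_id
        return g

    def fresh_id(self, prefix: str = "v") -> str:
        """A new vertex id not present in the graph ('v0001', 'v0002', ...)."""
        while True:
            self._next_id += 1
            vid = f"{prefix}{self._next_id:04d}"
            if vid not in self.labels:
                return vid

    def add_vertex(self, vid: Optional[str] = None,
                   label: Optional[str] = None) -> str:
        if vid is None:
            vid = self.fresh_id()
        if vid in self.labels:
            raise ValueError(f"duplicate vertex id {vid!r}")
        self.labels[vid] = label
        return vid

    def delete_vertex(self, vid: str) -> None:
        """Remove an isolated vertex (no adjacencies, no branches)."""
        if self.is_attached(vid) or vid in self._parent or self._children.get(vid):
            raise ValueError(f"vertex {vid!r} is not isolated")
        del self.labels[vid]
        self._children.pop(vid, None)

    def add_adjacency(self, a: Side, b: Side, strict: bool = True) -> Adjacency:
        if a == b:
            raise ValueError(f"a side cannot pair with itself: {a}")
        key = adjacency_key(a, b)
        for s in (a, b):
            if s[0] not in self.labels:
                raise ValueError(f"unknown vertex in side {s}")
            if s[1] not in ORIENTATIONS:
                raise ValueError(f"bad orientation in side {s}")
        occupied = [s for s in (a, b) if s in self._side_map]
        if occupied and strict:
            raise ValueError(f"side(s) already attached: {occupied}")
        if key in self._adjacencies:
            if strict:
                raise ValueError(f"duplicate adjacency {key}")
            self._extra_attach.extend([a, b])
            return key
        self._adjacencies[key] = None
        if occupied:
            self._extra_attach.extend(occupied)
        for s, t in ((a, b), (b, a)):
            if s not in self._side_map:
                self._side_map[s] = t
        return key

    def delete_adjacency(self, a: Side, b: Side) -> None:
        key = adjacency_key(a, b)
        if key not in self._adjacencies:
            raise ValueError(f"no such adjacency {key}")
        del self._adjacencies[key]
        for s in key:
            if self._side_map.get(s) in key:
                del self._side_map[s]

    def add_branch(self, parent: str, child: str, strict: bool = True) -> Branch:
        for v in (parent, child):
            if v not in self.labels:
                raise ValueError(f"unknown vertex {v!r}")
        if strict and parent == child:
            raise ValueError(f"self-branch on {parent!r}")
        if strict and child in self._parent:
            raise ValueError(f"vertex {child!r} already has a parent")
        if child not in self._parent:
            self._parent[child] = parent
        elif self._parent[child] != parent:
            self._extra_parents.append((parent, child))
        self._children.setdefault(parent, set()).add(child)
        return (parent, child)

    def delete_branch(self, parent: str, child: str) -> None:
        if self._parent.get(child) != parent:
            raise ValueError(f"no branch {(parent, child)}")
        del self._parent[child]
        self._children[parent].discard(child)

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------
    def vertices(self) -> list[str]:
        return sorted(self.labels)

    def adjacencies(self) -> list[Adjacency]:
        return sorted(self._adjacencies)

    def branches(self) -> list[Branch]:
        return sorted((p, c) for c, p in self._parent.items())

    def label(self, vid: str) -> Optional[str]:
        return self.labels[vid]

    def is_labeled(self, vid: str) -> bool:
        return self.labels[vid] is not None

    def parent(self, vid: str) -> Optional[str]:
        return self._parent.get(vid)

    def children(self, vid: str) -> list[str]:
        return sorted(self._children.get(vid, ()))

    def roots(self) -> list[str]:
        return sorted(v for v in self.labels if v not in self._parent)

    def is_leaf(self, vid: str) -> bool:
        return not self._children.get(vid)

    def sides(self, vid: str) -> tuple[Side, Side]:
        return ((vid, HEAD), (vid, TAIL))

    def all_sides(self) -> Iterator[Side]:
        for v in self.vertices():
            yield (v, HEAD)
            yield (v, TAIL)

    def partner(self, side: Side) -> Optional[Side]:
        return self._side_map.get(side)

    def is_side_attached(self, side: Side) -> bool:
        return side in self._side_map

    def is_attached(self, vid: str) -> bool:
        return (vid, HEAD) in self._side_map or (vid, TAIL) in self._side_map

    def is_isolated(self, vid: str) -> bool:
        return (not self.is_attached(vid) and vid not in self._parent
                and not self._children.get(vid))

    def ancestors(self, vid: str) -> Iterator[str]:
        """Proper ancestors of ``vid``, nearest first."""
        seen = set()
        v = self._parent.get(vid)
        while v is not None:
            if v in seen:  # defensive: branch cycle
                return
            seen.add(v)
            yield v
            v = self._parent.get(v)

    def descendants(self, vid: str) -> Iterator[str]:
        """Proper descendants of ``vid`` (preorder, sorted siblings)."""
        stack = list(reversed(self.children(vid)))
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children(v)))

    def branch_tree_root(self, vid: str) -> str:
        v = vid
        seen = {v}
        while v in self._parent:
            v = self._parent[v]
            if v in seen:
                return v  # cycle; validate() reports it
            seen.add(v)
        return v

    # ------------------------------------------------------------------
    # threads & event graph
    # ------------------------------------------------------------------
    def threads(self) -> list["Thread"]:
        """Partition of vertices by adjacency connectivity (branches ignored).

        Each part is tagged ``linear`` (it has unattached sides) or
        ``circular`` (a simple cycle of adjacencies).
        """
        seen: set[str] = set()
        out = []
        for v in self.vertices():
            if v in seen:
                continue
            comp = {v}
            stack = [v]
            while stack:
                u = stack.pop()
                for side in self.sides(u):
                    p = self._side_map.get(side)
                    if p is not None and p[0] not in comp:
                        comp.add(p[0])
                        stack.append(p[0])
            seen |= comp
            unattached = sorted(
                s for u in comp for s in self.sides(u)
                if s not in self._side_map)
            out.append(Thread(tuple(sorted(comp)), tuple(unattached)))
        return out

    def thread_of(self, vid: str) -> "Thread":
        for t in self.threads():
            if vid in t.vertices:
                return t
        raise KeyError(vid)

    def event_graph(self) -> nx.DiGraph:
        """Contraction of adjacencies: one node per thread, arcs per branch.

        Nodes are thread indices into :meth:`threads`; multi-arcs collapse.
        """
        threads = self.threads()
        comp_of = {v: i for i, t in enumerate(threads) for v in t.vertices}
        d = nx.DiGraph()
        d.add_nodes_from(range(len(threads)))
        for p, c in self.branches():
            d.add_edge(comp_of[p], comp_of[c])
        return d

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> list[Violation]:
        """All broken history-graph invariants (empty list iff valid)."""
        out: list[Violation] = []
        for v, lab in sorted(self.labels.items()):
            if lab is not None:
                if lab == "":
                    out.append(Violation("empty-label", (v,),
                                         f"vertex {v!r} has an empty label"))
                elif not set(lab) <= DNA_ALPHABET:
                    out.append(Violation(
                        "bad-label", (v, lab),
                        f"vertex {v!r} label {lab!r} not over A/C/G/T"))
        for side in sorted(set(self._extra_attach)):
            out.append(Violation(
                "side-multiply-attached", (side,),
                f"side {side} appears in more than one adjacency"))
        for c, p in sorted(self._parent.items()):
            if p == c:
                out.append(Violation("self-branch", (p, c),
                                     f"vertex {c!r} is its own parent"))
        for p, c in sorted(self._extra_parents):
            out.append(Violation(
                "multiple-parents", (p, c),
                f"vertex {c!r} has more than one incoming branch"))
        # event-graph acyclicity (covers branch cycles too)
        if not self._extra_attach:
            d = self.event_graph()
            if not nx.is_directed_acyclic_graph(d):
                cyc = nx.find_cycle(d)
                out.append(Violation(
                    "event-graph-cycle", tuple(cyc),
                    "contracting adjacencies leaves a directed cycle "
                    f"through thread components {sorted({e[0] for e in cyc})}"))
        return out

    def is_valid(self) -> bool:
        return not self.validate()

    # ------------------------------------------------------------------
    # sequences
    # ------------------------------------------------------------------
    def thread_sequence(self, thread: "Thread",
                        start_side: Optional[Side] = None) -> str:
        """DNA sequence of a linear thread read from ``start_side``.

        Entering a vertex at its tail reads the label forward; entering at
        its head reads the reverse complement.  Reading from the other end
        yields the reverse complement of the whole sequence.
        """
        if start_side is None:
            if thread.is_circular:
                raise ValueError("circular thread has no canonical start; "
                                 "pass a start side")
            start_side = thread.unattached_sides[0]
        if thread.is_circular:
            if start_side[0] not in thread.vertices:
                raise ValueError(f"{start_side} not in thread")
        elif start_side not in thread.unattached_sides:
            raise ValueError(f"{start_side} is not an unattached side "
                             "of this thread")
        parts = []
        side = start_side
        n = len(thread.vertices)
        for _ in range(n):
            vid, orientation = side
            lab = self.labels[vid]
            if lab is None:
                raise ValueError(f"missing label on vertex {vid!r}")
            parts.append(lab if orientation == TAIL else reverse_complement(lab))
            exit_side = (vid, opposite(orientation))
            nxt = self._side_map.get(exit_side)
            if nxt is None:
                break
            side = nxt
        return "".join(parts)

    # ------------------------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"HistoryGraph(|V|={len(self.labels)}, "
                f"|E|={len(self._adjacencies)}, |B|={len(self._parent)})")

    def counts(self) -> tuple[int, int, int]:
        return (len(self.labels), len(self._adjacencies), len(self._parent))


@dataclass(frozen=True)
class Thread:
    """One adjacency-connected component: a chromosome or fragment."""

    vertices: tuple[str, ...]
    unattached_sides: tuple[Side, ...]

    @property
    def is_circular(self) -> bool:
        return not self.unattached_sides

    @property
    def is_linear(self) -> bool:
        return bool(self.unattached_sides)


def build_graph(vertices: Iterable[tuple[str, Optional[str]]] = (),
                adjacencies: Iterable[tuple[Side, Side]] = (),
                branches: Iterable[Branch] = (),
                strict: bool = True) -> HistoryGraph:
    """Convenience constructor from element lists.

    With ``strict=False`` structurally inconsistent input (multiply
    attached sides, repeated parents) is accepted and surfaced by
    :meth:`HistoryGraph.validate` instead of raising.
    """
    g = HistoryGraph()
    for vid, label in vertices:
        g.add_vertex(vid, label)
    for a, b in adjacencies:
        g.add_adjacency(tuple(a), tuple(b), strict=strict)
    for p, c in branches:
        g.add_branch(p, c, strict=strict)
    return g
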