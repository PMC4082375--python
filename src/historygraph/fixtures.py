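"""Worked-example graphs used throughout the documentation and tests.

Each fixture reconstructs a published illustration of the model from its
textual description and the quantities stated about it (thread
sequences, ambiguities, cost bounds, epoch counts).  The original
drawings were not available pixel-for-pixel, so element naming and
layout are this package's own; every fixture carries a ``note`` saying
what is pinned down and what is reconstruction.  Tests that depend on a
fixture's numbers surface the note on mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .core import HEAD, TAIL, HistoryGraph, reverse_complement


@dataclass(frozen=True)
class Fixture:
    name: str
    graph: HistoryGraph
    note: str


_REGISTRY: dict[str, Callable[[], Fixture]] = {}


def _register(name):
    def deco(fn):
        _REGISTRY[name] = lambda: Fixture(name, fn(), fn.__doc__ or "")
        return fn
    return deco


def fixture(name: str) -> Fixture:
    """Fetch a named fixture (a fresh graph each call)."""
    return _REGISTRY[name]()


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


# ----------------------------------------------------------------------
# thread graph with three linear threads
# ----------------------------------------------------------------------
TOP_THREAD_SEQUENCE = ("GAGGGTGGCCCGAGAA"
                       "TACTTTAAGGTTCTGAATA"
                       "AACCCCAGCACAAATTTT")
TOP_THREAD_RC_PREFIX = "AAAATTTGTGCTGGGGTT"


@_register("fig1")
def _fig1() -> HistoryGraph:
    """Three linear threads.  The top thread's three segments spell the
    published example sequence, with the middle segment attached in the
    opposite direction (read as its reverse complement left-to-right).
    The other two threads are reconstructions: only their count and
    linearity are pinned down by the source."""
    g = HistoryGraph()
    g.add_vertex("t1a", "GAGGGTGGCCCGAGAA")
    g.add_vertex("t1b", reverse_complement("TACTTTAAGGTTCTGAATA"))
    g.add_vertex("t1c", "AACCCCAGCACAAATTTT")
    g.add_adjacency(("t1a", HEAD), ("t1b", HEAD))
    g.add_adjacency(("t1b", TAIL), ("t1c", TAIL))
    for vid, lab in [("t2a", "CCTG"), ("t2b", "GGAT"), ("t2c", "AT")]:
        g.add_vertex(vid, lab)
    g.add_adjacency(("t2a", HEAD), ("t2b", TAIL))
    g.add_adjacency(("t2b", HEAD), ("t2c", TAIL))
    for vid, lab in [("t3a", "TTAC"), ("t3b", "CAG"), ("t3c", "GGC")]:
        g.add_vertex(vid, lab)
    g.add_adjacency(("t3a", HEAD), ("t3b", TAIL))
    g.add_adjacency(("t3b", HEAD), ("t3c", TAIL))
    return g


# ----------------------------------------------------------------------
# the ambiguous history graph (u_s 1, u_r 5, bounds 4/5 and 3/6)
# ----------------------------------------------------------------------
def _fig2b_graph() -> HistoryGraph:
    g = HistoryGraph()
    # ancestral thread r1 - r2 - r3 (all labeled roots)
    g.add_vertex("r1", "A")
    g.add_vertex("r2", "C")
    g.add_vertex("r3", "T")
    g.add_adjacency(("r1", HEAD), ("r2", TAIL))
    g.add_adjacency(("r2", HEAD), ("r3", TAIL))
    # internal vertex X under r2: relabeled, unattached; its two labeled
    # children share an identical changed label (one excess -> u_s = 1)
    g.add_vertex("X", "G")
    g.add_branch("r2", "X")
    for y, lab in [("y1", "A"), ("y2", "A"), ("y3", None)]:
        g.add_vertex(y, lab)
        g.add_branch("X", y)
    # leaves under r1 and r3, plus one unaligned segment z
    g.add_vertex("c1", "C")
    g.add_vertex("c1b", None)
    g.add_branch("r1", "c1")
    g.add_branch("r1", "c1b")
    g.add_vertex("c3", "G")
    g.add_vertex("c3x", None)
    g.add_branch("r3", "c3")
    g.add_branch("r3", "c3x")
    g.add_vertex("z", "T")  # parentless leaf segment
    # leaf threads (the six non-trivially lifting adjacencies)
    g.add_adjacency(("y1", TAIL), ("c1", HEAD))
    g.add_adjacency(("y2", TAIL), ("c3", HEAD))
    g.add_adjacency(("y3", TAIL), ("y1", HEAD))
    g.add_adjacency(("y2", HEAD), ("c3x", HEAD))
    g.add_adjacency(("y3", HEAD), ("c1b", TAIL))
    g.add_adjacency(("c3", TAIL), ("z", TAIL))
    return g


@_register("fig2b")
def _fig2b() -> HistoryGraph:
    """An ambiguous history graph extending the alignment graph: one
    vertex holds two non-trivial lifted labels (substitution ambiguity
    1); two sides carry three non-trivial lifted adjacency incidences
    and one side two (rearrangement ambiguity 5); LBSC/UBSC are 4/5 and
    LBRC/UBRC are 3/6.  The published drawing was unavailable, so the
    element layout is a reconstruction pinned to those stated values."""
    return _fig2b_graph()


@_register("fig2a")
def _fig2a() -> HistoryGraph:
    """The alignment-style history graph that the ambiguous example
    extends: leaf threads plus ancestral vertices carrying less state
    (a reduction of the extension; reconstruction)."""
    g = _fig2b_graph()
    g.labels["X"] = None  # the extension adds the inferred allele at X
    g.labels["z"] = None
    return g


# ----------------------------------------------------------------------
# the four-epoch simple history (s = 4, r = 3)
# ----------------------------------------------------------------------
@_register("fig2d")
def _fig2d() -> HistoryGraph:
    """A simple history with four epochs — replication, rearrangement,
    replication, rearrangement — containing four substitutions and
    rearrangement cycles of total size three.  Reconstruction pinned to
    the published epoch count and costs."""
    g = HistoryGraph()

    def thread(ids_labels):
        ids = []
        for vid, lab in ids_labels:
            ids.append(g.add_vertex(vid, lab))
        for i in range(len(ids) - 1):
            g.add_adjacency((ids[i], HEAD), (ids[i + 1], TAIL))
        return ids

    # epoch 0 layer: one chromosome of three segments
    thread([("a1", "A"), ("a2", "C"), ("a3", "T")])
    # epoch 1: whole-genome duplication; one substitution (b4: A -> C)
    thread([("b1", "A"), ("b2", "C"), ("b3", "T")])
    thread([("b4", "C"), ("b5", "C"), ("b6", "T")])
    for p, c in [("a1", "b1"), ("a2", "b2"), ("a3", "b3"),
                 ("a1", "b4"), ("a2", "b5"), ("a3", "b6")]:
        g.add_branch(p, c)
    # epoch 2: one reciprocal translocation (1 DCJ); one substitution
    # (c2: C -> G).  Pattern swaps the b1-b2 and b4-b5 bonds.
    for vid, lab, parent in [("c1", "A", "b1"), ("c2", "G", "b2"),
                             ("c3", "T", "b3"), ("c4", "C", "b4"),
                             ("c5", "C", "b5"), ("c6", "T", "b6")]:
        g.add_vertex(vid, lab)
        g.add_branch(parent, vid)
    g.add_adjacency(("c1", HEAD), ("c5", TAIL))
    g.add_adjacency(("c4", HEAD), ("c2", TAIL))
    g.add_adjacency(("c2", HEAD), ("c3", TAIL))
    g.add_adjacency(("c5", HEAD), ("c6", TAIL))
    # epoch 3: whole-genome duplication; one substitution (d7: A -> T)
    spec = [("c1", "A"), ("c2", "G"), ("c3", "T"),
            ("c4", "C"), ("c5", "C"), ("c6", "T")]
    for copy in (1, 2):
        for i, (parent, lab) in enumerate(spec, start=1):
            vid = f"d{i + (copy - 1) * 6}"
            g.add_vertex(vid, "T" if vid == "d7" else lab)
            g.add_branch(parent, vid)
    for copy_base in (0, 6):
        o = copy_base
        g.add_adjacency((f"d{1+o}", HEAD), (f"d{5+o}", TAIL))
        g.add_adjacency((f"d{4+o}", HEAD), (f"d{2+o}", TAIL))
        g.add_adjacency((f"d{2+o}", HEAD), (f"d{3+o}", TAIL))
        g.add_adjacency((f"d{5+o}", HEAD), (f"d{6+o}", TAIL))
    # epoch 4: two more DCJs (an inversion in each copy); one
    # substitution (e3: T -> G)
    for i in range(1, 13):
        lab = g.label(f"d{i}")
        vid = f"e{i}"
        g.add_vertex(vid, "G" if vid == "e3" else lab)
        g.add_branch(f"d{i}", vid)
    # copy 1: invert segment e5 (cuts both its bonds, rejoins flipped)
    g.add_adjacency(("e1", HEAD), ("e5", HEAD))
    g.add_adjacency(("e5", TAIL), ("e6", TAIL))
    g.add_adjacency(("e4", HEAD), ("e2", TAIL))
    g.add_adjacency(("e2", HEAD), ("e3", TAIL))
    # copy 2: invert segment e8 likewise
    g.add_adjacency(("e7", HEAD), ("e11", TAIL))
    g.add_adjacency(("e11", HEAD), ("e12", TAIL))
    g.add_adjacency(("e10", HEAD), ("e8", HEAD))
    g.add_adjacency(("e8", TAIL), ("e9", TAIL))
    return g


# ----------------------------------------------------------------------
# the AVG that is not a simple history (bounds coincide at 4 and 3)
# ----------------------------------------------------------------------
@_register("fig5")
def _fig5() -> HistoryGraph:
    """An unambiguous history graph (AVG) that is not a simple history:
    both substitution bounds equal 4 and both rearrangement bounds equal
    3 (three simple four-side modules, one DCJ each).  Reconstruction
    pinned to the published bound values."""
    g = HistoryGraph()
    subs = {("m1", "u1c"): ("A", "C"), ("m2", "u2c"): ("C", "T"),
            ("m3", "u3c"): ("G", "A"), ("m1", "y1c"): ("T", "G")}
    for mod in (1, 2, 3):
        # parents u,w,x,y form two bonds; the children's bonds are
        # swapped: two non-trivial lifted adjacencies closing a module
        for name in "uwxy":
            vid = f"{name}{mod}"
            g.add_vertex(vid, {"u": "A", "w": "C", "x": "G",
                               "y": "T"}[name])
        g.add_adjacency((f"u{mod}", HEAD), (f"w{mod}", TAIL))
        g.add_adjacency((f"x{mod}", HEAD), (f"y{mod}", TAIL))
        for name in "uwxy":
            vid = f"{name}{mod}c"
            g.add_vertex(vid, g.label(f"{name}{mod}"))
            g.add_branch(f"{name}{mod}", vid)
        g.add_adjacency((f"u{mod}c", HEAD), (f"y{mod}c", TAIL))
        g.add_adjacency((f"x{mod}c", HEAD), (f"w{mod}c", TAIL))
    # four substitutions, one non-trivial lifted label each
    g.labels["u1c"] = "C"
    g.labels["u2c"] = "T"
    g.labels["u3c"] = "G"
    g.labels["y1c"] = "G"
    # an unlabeled pass-through vertex keeps this from being a simple
    # history while changing no lift
    g.add_vertex("mid", None)
    p = g.parent("u1c")
    g.delete_branch(p, "u1c")
    g.add_branch(p, "mid")
    g.add_branch("mid", "u1c")
    return g


# ----------------------------------------------------------------------
# label / adjacency classification examples
# ----------------------------------------------------------------------
@_register("fig6a")
def _fig6a() -> HistoryGraph:
    """A junction label: a vertex holding two lifted labels."""
    g = HistoryGraph()
    g.add_vertex("x", "A")
    for vid, lab in [("c1", "C"), ("c2", "G")]:
        g.add_vertex(vid, lab)
        g.add_branch("x", vid)
    return g


@_register("fig6b")
def _fig6b() -> HistoryGraph:
    """A bridge label: a single non-trivial lifted label, an identically
    labeled lifting ancestor, and that ancestor itself ambiguous."""
    g = HistoryGraph()
    g.add_vertex("p", "A")
    g.add_vertex("x", "A")
    g.add_vertex("w", "G")
    g.add_vertex("y", "C")
    g.add_branch("p", "x")
    g.add_branch("p", "w")
    g.add_branch("x", "y")
    return g


@_register("fig6c")
def _fig6c() -> HistoryGraph:
    """A junction adjacency: an endpoint is the MRCA of two attached,
    indirectly related sides."""
    g = HistoryGraph()
    for vid in ("r", "s", "c1", "c2"):
        g.add_vertex(vid, "A")
    g.add_branch("r", "c1")
    g.add_branch("r", "c2")
    g.add_adjacency(("r", HEAD), ("s", HEAD))
    g.add_adjacency(("c1", HEAD), ("c2", HEAD))
    return g


@_register("fig6d")
def _fig6d() -> HistoryGraph:
    """A bridge adjacency: it lifts trivially onto a junction side that
    still carries a non-trivial lifted adjacency."""
    g = HistoryGraph()
    for vid in ("g", "h", "x", "y", "u", "w"):
        g.add_vertex(vid, "A")
    g.add_branch("g", "x")
    g.add_branch("g", "w")
    g.add_branch("h", "y")
    g.add_branch("x", "u")
    g.add_adjacency(("g", HEAD), ("h", HEAD))
    g.add_adjacency(("x", HEAD), ("y", HEAD))  # the bridge
    g.add_adjacency(("u", HEAD), ("w", HEAD))  # lifts non-trivially
    return g


@_register("fig6e")
def _fig6e() -> HistoryGraph:
    """A ping-pong pair: two adjacencies with hanging sides, linked
    through a most recent attached ancestor."""
    g = HistoryGraph()
    for vid in ("a", "b", "c", "d"):
        g.add_vertex(vid, "A")
    g.add_branch("a", "c")
    g.add_adjacency(("a", HEAD), ("b", HEAD))  # pong (b head hangs)
    g.add_adjacency(("c", HEAD), ("d", HEAD))  # ping (d head hangs)
    return g


@_register("fig15a")
def _fig15a() -> HistoryGraph:
    """Ping-pong through a deeper chain of unattached ancestors."""
    g = HistoryGraph()
    for vid in ("a", "b", "m", "c", "d"):
        g.add_vertex(vid, "A")
    g.add_branch("a", "m")
    g.add_branch("m", "c")
    g.add_adjacency(("a", HEAD), ("b", HEAD))
    g.add_adjacency(("c", HEAD), ("d", HEAD))
    return g


@_register("fig15b")
def _fig15b() -> HistoryGraph:
    """Two ping adjacencies sharing one pong."""
    g = HistoryGraph()
    for vid in ("a", "b", "c", "d", "e", "f"):
        g.add_vertex(vid, "A")
    g.add_branch("a", "c")
    g.add_branch("a", "e")
    g.add_adjacency(("a", HEAD), ("b", HEAD))
    g.add_adjacency(("c", HEAD), ("d", HEAD))
    g.add_adjacency(("e", HEAD), ("f", HEAD))
    return g


@_register("fig15c")
def _fig15c() -> HistoryGraph:
    """A chain where one adjacency is the pong of a deeper ping and the
    ping of a shallower pong at the same time."""
    g = HistoryGraph()
    for vid in ("a", "b", "c", "d", "e", "f"):
        g.add_vertex(vid, "A")
    g.add_branch("a", "c")
    g.add_branch("c", "e")
    g.add_adjacency(("a", HEAD), ("b", HEAD))
    g.add_adjacency(("c", HEAD), ("d", HEAD))
    g.add_adjacency(("e", HEAD), ("f", HEAD))
    return g


# ----------------------------------------------------------------------
# size-bound worked examples
# ----------------------------------------------------------------------
@_register("fig19a")
def _fig19a() -> HistoryGraph:
    """A seed graph with three adjacencies: the closed-form cap on
    G-reducible adjacencies, max(0, 10n-8), evaluates to 22 here."""
    g = HistoryGraph()
    ids = []
    for i, lab in enumerate("ACGT"):
        ids.append(g.add_vertex(f"s{i}", lab))
    for i in range(3):
        g.add_adjacency((ids[i], HEAD), (ids[i + 1], TAIL))
    return g


@_register("fig20a")
def _fig20a() -> HistoryGraph:
    """A seed graph with five labeled vertices: the closed-form cap on
    G-reducible labels, max(0, 2m-2), evaluates to 8 here."""
    g = HistoryGraph()
    g.add_vertex("root", "A")
    for i in range(4):
        g.add_vertex(f"leaf{i}", "ACGT"[i])
        g.add_branch("root", f"leaf{i}")
    return g


@_register("fig24a")
def _fig24a() -> HistoryGraph:
    """The seed whose minimal AVG extensions form an infinite family:
    four labeled leaves in two bonds, with unlabeled ancestors recording
    homology only.  Reconstruction with high layout uncertainty; only
    used as a validating fixture."""
    g = HistoryGraph()
    for vid in ("a", "b", "c", "d"):
        g.add_vertex(vid, "A")
    for vid in ("w", "x", "y", "z"):
        g.add_vertex(vid, None)
    g.add_adjacency(("a", HEAD), ("b", HEAD))
    g.add_adjacency(("c", HEAD), ("d", HEAD))
    g.add_branch("x", "w")
    g.add_branch("z", "y")
    g.add_branch("w", "a")
    g.add_branch("w", "c")
    g.add_branch("y", "b")
    g.add_branch("y", "d")
    return g
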