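"""Ambiguity measures, parsimony cost bounds and simple-history costs.

For a history graph G the minimum cost of any full evolutionary scenario
(realisation) is NP-hard to compute, but is sandwiched by four trivially
computable quantities derived from the lifted graph:

* ``lbsc``/``ubsc`` — lower/upper bounds on the number of substitutions,
* ``lbrc``/``ubrc`` — lower/upper bounds on the number of DCJ operations.

The bounds coincide exactly when G has zero *ambiguity* (excess
non-trivial lifted labels per vertex plus excess non-trivial lifted
adjacency incidences per side), i.e. when G is an ancestral variation
graph (AVG).
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .core import Adjacency, HistoryGraph, Side, adjacency_key
from .lifting import Lifting, is_free_root


# ----------------------------------------------------------------------
# cost functions
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CostFunction:
    """A monotone cost c(s, r) = ws*s + wr*r with positive weights."""

    ws: float = 1.0
    wr: float = 1.0

    def __post_init__(self) -> None:
        if self.ws <= 0 or self.wr <= 0:
            raise ValueError("substitution and rearrangement weights "
                             "must both be positive")

    def __call__(self, s: float, r: float) -> float:
        return self.ws * s + self.wr * r


DEFAULT_COST = CostFunction()


# ----------------------------------------------------------------------
# ambiguity and bounds
# ----------------------------------------------------------------------
def substitution_ambiguity(graph: HistoryGraph,
                           lifting: Optional[Lifting] = None) -> int:
    """u_s: non-trivial lifted labels in excess of one per vertex."""
    lift = lifting or Lifting(graph)
    total = 0
    for owner in lift._labels_by_owner:
        k = sum(1 for ll in lift.labels_at(owner) if not ll.trivial)
        total += max(0, k - 1)
    return total


def rearrangement_ambiguity(graph: HistoryGraph,
                            lifting: Optional[Lifting] = None) -> int:
    """u_r: non-trivial lifted adjacency incidences in excess of one per side."""
    lift = lifting or Lifting(graph)
    total = 0
    for side in lift._edges_by_side:
        total += max(0, lift.nontrivial_incidences(side) - 1)
    return total


def ambiguity(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> int:
    lift = lifting or Lifting(graph)
    return (substitution_ambiguity(graph, lift)
            + rearrangement_ambiguity(graph, lift))


def is_avg(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> bool:
    """True iff the graph is an ancestral variation graph (zero ambiguity)."""
    return ambiguity(graph, lifting) == 0


def lbsc(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> int:
    """Lower bound substitution cost: distinct non-trivial lifted labels,
    minus one per unlabeled vertex (free root) that has any."""
    lift = lifting or Lifting(graph)
    total = 0
    for owner in lift._labels_by_owner:
        distinct = {ll.label for ll in lift.labels_at(owner) if not ll.trivial}
        total += len(distinct)
        if distinct and is_free_root(owner):
            total -= 1
    return total


def ubsc(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> int:
    """Upper bound substitution cost: all non-trivial lifted labels, minus
    the deepest identical class at each free root that has any."""
    lift = lifting or Lifting(graph)
    total = 0
    for owner in lift._labels_by_owner:
        nontrivial = [ll.label for ll in lift.labels_at(owner)
                      if not ll.trivial]
        total += len(nontrivial)
        if nontrivial and is_free_root(owner):
            total -= max(Counter(nontrivial).values())
    return total


def lbrc(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> int:
    """Lower bound rearrangement cost: sum over modules of ceil(|V_M|/2)-1."""
    lift = lifting or Lifting(graph)
    return sum(math.ceil(len(m) / 2) - 1 for m in lift.modules())


def ubrc(graph: HistoryGraph, lifting: Optional[Lifting] = None) -> int:
    """Upper bound rearrangement cost: non-trivial lifted adjacency edges,
    minus the number of modules whose every side has exactly one
    non-trivial incidence."""
    lift = lifting or Lifting(graph)
    nontrivial_edges = sum(1 for e in lift.lifted_edges if not e.trivial)
    saturated = 0
    for m in lift.modules():
        if all(lift.nontrivial_incidences(s) == 1 for s in m.sides):
            saturated += 1
    return nontrivial_edges - saturated


@dataclass(frozen=True)
class BoundsReport:
    """Ambiguities and cost bounds of one history graph."""

    u_s: int
    u_r: int
    s_l: int
    s_u: int
    r_l: int
    r_u: int

    @property
    def is_avg(self) -> bool:
        return self.u_s + self.u_r == 0

    def as_dict(self) -> dict:
        return {"u_s": self.u_s, "u_r": self.u_r, "s_l": self.s_l,
                "s_u": self.s_u, "r_l": self.r_l, "r_u": self.r_u,
                "is_avg": self.is_avg}


def bounds_report(graph: HistoryGraph) -> BoundsReport:
    lift = Lifting(graph)
    return BoundsReport(
        u_s=substitution_ambiguity(graph, lift),
        u_r=rearrangement_ambiguity(graph, lift),
        s_l=lbsc(graph, lift),
        s_u=ubsc(graph, lift),
        r_l=lbrc(graph, lift),
        r_u=ubrc(graph, lift),
    )


# ----------------------------------------------------------------------
# simple-history costs
# ----------------------------------------------------------------------
def substitution_count(graph: HistoryGraph) -> int:
    """Branches whose endpoint labels differ (both endpoints labeled)."""
    n = 0
    for p, c in graph.branches():
        if graph.label(p) != graph.label(c):
            n += 1
    return n


def epoch_rearrangement_cost(graph: HistoryGraph,
                             root_vertices: Iterable[str],
                             leaf_vertices: Optional[Iterable[str]] = None
                             ) -> int:
    """Total rearrangement-cycle size of one rearrangement epoch.

    Each root has at most one child.  Leaf-layer adjacencies are mapped
    back onto root sides through the branches; components of the union of
    root-layer and (mapped) leaf-layer adjacencies are alternating cycles
    or (degenerate) paths.  A cycle with k adjacencies per layer costs
    k - 1.  A path costs the size of the smallest rearrangement cycle
    completing it: max(a, b) - 1 when the layer counts a and b differ
    (only missing branches need closing), but a when a == b (the path
    has one loose end in each layer, and closing it requires a whole
    extra pattern repetition) -- together floor((a + b) / 2).
    """
    roots = sorted(root_vertices)
    child_of = {}
    leaves = set() if leaf_vertices is None else set(leaf_vertices)
    for v in roots:
        cs = graph.children(v)
        if len(cs) > 1:
            raise ValueError(f"rearrangement epoch root {v!r} must have "
                             f"at most one child, has {len(cs)}")
        if cs:
            child_of[v] = cs[0]
            leaves.add(cs[0])
    root_set = set(roots)
    leaf_to_root = {c: v for v, c in child_of.items()}

    def leaf_node(side: Side) -> Side:
        # identify a leaf side with its parent's side; material with no
        # parent in the epoch keeps a private node
        v, o = side
        if v in leaf_to_root:
            return (leaf_to_root[v], o)
        return ("+" + v, o)

    r_edges: dict[Side, Side] = {}
    l_edges: dict[Side, Side] = {}
    for a, b in graph.adjacencies():
        if a[0] in root_set and b[0] in root_set:
            r_edges[a] = b
            r_edges[b] = a
        elif ((a[0] in leaves or a[0] in leaf_to_root)
              and (b[0] in leaves or b[0] in leaf_to_root)):
            ra, rb = leaf_node(a), leaf_node(b)
            l_edges[ra] = rb
            l_edges[rb] = ra

    nodes = set(r_edges) | set(l_edges)
    seen: set[Side] = set()
    total = 0
    for start in sorted(nodes):
        if start in seen:
            continue
        comp, stack = {start}, [start]
        while stack:
            s = stack.pop()
            for m in (r_edges.get(s), l_edges.get(s)):
                if m is not None and m not in comp:
                    comp.add(m)
                    stack.append(m)
        seen |= comp
        a = len({adjacency_key(s, r_edges[s]) for s in comp if s in r_edges})
        b = len({adjacency_key(s, l_edges[s]) for s in comp if s in l_edges})
        is_cycle = all(s in r_edges and s in l_edges for s in comp)
        if is_cycle:
            total += a - 1
        else:
            total += (a + b) // 2
    return total


def simple_history_costs(history: HistoryGraph) -> tuple[int, int]:
    """(substitution cost, rearrangement cost) of a simple history.

    Raises ``ValueError`` (naming the failed epoch condition) if the input
    is not a simple history.
    """
    from .transform import validate_simple_history  # local: avoids cycle

    ok, epochs, reason = validate_simple_history(history)
    if not ok:
        raise ValueError(f"not a simple history: {reason}")
    s = substitution_count(history)
    r = 0
    for epoch in epochs:
        if epoch.kind == "rearrangement":
            r += epoch_rearrangement_cost(history, epoch.root_vertices,
                                          epoch.leaf_vertices)
    return s, r


# ----------------------------------------------------------------------
# DCJ oracle
# ----------------------------------------------------------------------
def _dcj_neighbours(state: frozenset, universe: tuple[Side, ...]):
    adjs = sorted(state)
    attached = {s for adj in state for s in adj}
    free = [s for s in universe if s not in attached]
    # rematch two adjacencies
    for i in range(len(adjs)):
        a, b = adjs[i]
        for j in range(i + 1, len(adjs)):
            c, d = adjs[j]
            base = state - {adjs[i], adjs[j]}
            yield base | {adjacency_key(a, c), adjacency_key(b, d)}
            yield base | {adjacency_key(a, d), adjacency_key(b, c)}
        # cut one adjacency
        yield state - {adjs[i]}
        # rematch one adjacency with a telomere
        for c in free:
            yield (state - {adjs[i]}) | {adjacency_key(a, c)}
            yield (state - {adjs[i]}) | {adjacency_key(b, c)}
    # join two telomeres
    for i in range(len(free)):
        for j in range(i + 1, len(free)):
            yield state | {adjacency_key(free[i], free[j])}


def dcj_distance_oracle(root_adjacencies: Iterable[Adjacency],
                        leaf_adjacencies: Iterable[Adjacency],
                        max_adjacencies: int = 6) -> int:
    """Exact minimum number of DCJ operations, by breadth-first search.

    Each operation cuts up to two adjacencies (or uses unattached sides)
    and rejoins the loose ends differently.  A testing oracle only: the
    state space is guarded to ``max_adjacencies`` adjacencies.
    """
    start = frozenset(adjacency_key(*adj) for adj in root_adjacencies)
    goal = frozenset(adjacency_key(*adj) for adj in leaf_adjacencies)
    if len(start) > max_adjacencies or len(goal) > max_adjacencies:
        raise ValueError("state space guard exceeded: "
                         f"more than {max_adjacencies} adjacencies")
    universe = tuple(sorted({s for adj in (start | goal) for s in adj}))
    if start == goal:
        return 0
    dist = {start: 0}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        d = dist[state]
        for nxt in _dcj_neighbours(state, universe):
            nxt = frozenset(nxt)
            if nxt in dist:
                continue
            if nxt == goal:
                return d + 1
            dist[nxt] = d + 1
            queue.append(nxt)
    raise RuntimeError("DCJ search exhausted without reaching the target")
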