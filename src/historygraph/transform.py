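"""Constructive transforms between history graphs, AVGs and realisations.

Two algorithms close the loop of the cost-bound theory:

* :func:`extend_to_avg` — extend any history graph to an ancestral
  variation graph without raising either upper bound, by iterating four
  ambiguity-reducing extension moves (root labeling, bridge-label
  interpolation, junction-side attachment, bridge-adjacency creation).
* :func:`realise_avg` — extend any AVG to a *simple history* (a fully
  explicit layered scenario of replication and rearrangement epochs)
  whose substitution and rearrangement costs equal the AVG's lower
  bounds.

Together they witness the sandwich: every history graph has realisations
with costs between its lower and upper bounds.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .core import ORIENTATIONS, HistoryGraph, Side, adjacency_key
from .costs import ambiguity, is_avg, lbrc, lbsc, ubrc, ubsc
from .edits import (_interpolate_above, _most_ancestral_attached_descendants,
                    apply_extension)
from .lifting import Lifting, is_free_root

CASE8_LABEL = "A"  # free label choice for all-unlabeled branch trees


# ----------------------------------------------------------------------
# simple-history validation
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Epoch:
    """One layer transition of a simple history.

    ``root_vertices`` are all vertices in the epoch's root layer; those
    without children in the epoch are material lost before the next
    layer (their dangling adjacencies form degenerate rearrangement
    cycles, at zero cost each).
    """

    index: int
    kind: str  # "replication" | "rearrangement"
    arity: int
    root_vertices: tuple[str, ...]
    leaf_vertices: tuple[str, ...]


def _thread_layers(graph: HistoryGraph):
    """Assign each thread a layer so every branch spans consecutive
    layers, independently per weakly connected component of the event
    graph.  Returns (vertex -> layer, list of per-component layer maps)
    or a failure reason string."""
    threads = graph.threads()
    comp_of = {v: i for i, t in enumerate(threads) for v in t.vertices}
    # thread-level branch multigraph
    nbrs: dict[int, list[tuple[int, int]]] = {i: [] for i in
                                              range(len(threads))}
    for p, c in graph.branches():
        tp, tc = comp_of[p], comp_of[c]
        nbrs[tp].append((tc, +1))
        nbrs[tc].append((tp, -1))
    layer: dict[int, int] = {}
    components: list[list[int]] = []
    for start in range(len(threads)):
        if start in layer:
            continue
        layer[start] = 0
        comp = [start]
        queue = [start]
        while queue:
            t = queue.pop()
            for u, step in nbrs[t]:
                want = layer[t] + step
                if u not in layer:
                    layer[u] = want
                    comp.append(u)
                    queue.append(u)
                elif layer[u] != want:
                    return None, (f"threads {t} and {u} cannot be layered "
                                  "consistently (a branch path closes with "
                                  "unequal layer offsets)")
        base = min(layer[t] for t in comp)
        for t in comp:
            layer[t] -= base
        components.append(sorted(comp, key=lambda t: layer[t]))
    vertex_layer = {v: layer[comp_of[v]] for v in graph.vertices()}
    return (vertex_layer, components, comp_of), None


def validate_simple_history(graph: HistoryGraph):
    """Check the layered epoch structure of a simple history.

    Returns ``(ok, epochs, reason)``: when ``ok`` the epoch partition is
    returned (independently layered per event-graph component, epochs
    concatenated), otherwise ``reason`` names the first violated
    condition.
    """
    def fail(reason):
        return False, [], reason

    if not graph.is_valid():
        return fail("not a valid history graph")
    unlabeled = [v for v in graph.vertices() if not graph.is_labeled(v)]
    if unlabeled:
        return fail(f"unlabeled vertices (e.g. {unlabeled[0]!r})")

    layered, reason = _thread_layers(graph)
    if layered is None:
        return fail(reason)
    vertex_layer, components, comp_of = layered

    epochs = []
    for comp in components:
        comp_threads = set(comp)
        verts = [v for v, t in comp_of.items() if t in comp_threads]
        if not verts:
            continue
        n_layers = max(vertex_layer[v] for v in verts)
        for i in range(n_layers):
            roots = tuple(sorted(v for v in verts if vertex_layer[v] == i))
            leaves = tuple(sorted(v for v in verts
                                  if vertex_layer[v] == i + 1))
            arities = {len(graph.children(v)) for v in roots
                       if graph.children(v)}
            if len(arities) > 1:
                return fail(f"epoch at layer {i}: mixed branch-tree "
                            f"arities {sorted(arities)}")
            n = arities.pop() if arities else 1
            kind = "rearrangement" if n == 1 else "replication"
            # homologous sides all attached or all unattached
            for v in roots:
                if not graph.children(v):
                    continue
                for o in ORIENTATIONS:
                    statuses = {graph.is_side_attached((v, o))} | {
                        graph.is_side_attached((c, o))
                        for c in graph.children(v)}
                    if len(statuses) > 1:
                        return fail(f"epoch at layer {i}: homologous sides "
                                    f"of ({v!r},{o}) not uniformly attached")
            if kind == "replication":
                root_set = set(roots)
                for a, b in graph.adjacencies():
                    if a[0] not in root_set or b[0] not in root_set:
                        continue
                    for x, y in ((a, b), (b, a)):
                        partners = {graph.partner((c, x[1]))
                                    for c in graph.children(x[0])}
                        expected = {(c, y[1]) for c in graph.children(y[0])}
                        if not partners <= expected:
                            return fail(
                                f"epoch at layer {i}: children of adjacency "
                                f"{(a, b)} are not attached to one another")
                for v in roots:
                    diff = [c for c in graph.children(v)
                            if graph.label(c) != graph.label(v)]
                    if len(diff) > 1:
                        return fail(f"epoch at layer {i}: replication root "
                                    f"{v!r} has {len(diff)} children with "
                                    "changed labels")
            epochs.append(Epoch(len(epochs) + 1, kind, n, roots, leaves))
    return True, epochs, None


# ----------------------------------------------------------------------
# extension to an AVG (upper-bound preserving)
# ----------------------------------------------------------------------
def _phase_ops(g: HistoryGraph, lift: Lifting) -> list[dict]:
    """Moves of the highest-priority applicable ambiguity-reducing phase."""
    # phase 1: ambiguous free roots -> root labelings
    ops = []
    for owner, lls in sorted(lift._labels_by_owner.items()):
        if is_free_root(owner) and len(lls) > 1:
            root = owner.split(":", 1)[1]
            counts: dict[str, int] = {}
            for ll in lls:
                counts[ll.label] = counts.get(ll.label, 0) + 1
            best = max(counts.values())
            for lab in sorted(l for l, c in counts.items() if c == best):
                ops.append({"kind": "root_labeling", "vertex": root,
                            "label": lab})
    if ops:
        return ops
    # phase 2: substitution ambiguity -> bridge labels
    for v in g.vertices():
        if not g.is_labeled(v):
            continue
        nontrivial = [ll for ll in lift.labels_at(v) if not ll.trivial]
        if len(nontrivial) >= 2:
            for ll in nontrivial:
                ops.append({"kind": "bridge_label", "below": ll.source,
                            "label": g.label(v)})
    if ops:
        return ops
    # phase 3: unattached junction sides -> junction side attachments
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
    if ops:
        return ops
    # phase 4: rearrangement ambiguity -> bridge adjacencies
    for side in sorted(lift._edges_by_side):
        if is_free_root(side[0]) or not g.is_side_attached(side):
            continue
        nontrivial = [e for e in lift.edges_at(side) if not e.trivial]
        if len(nontrivial) < 2:
            continue
        partner = g.partner(side)
        for e in nontrivial:
            for end, anc_end in zip(e.source, e.ends):
                if anc_end == side:
                    ops.append({
                        "kind": "bridge_adjacency", "below": end[0],
                        "orientation": end[1], "partner_parent": partner[0],
                        "partner_orientation": partner[1]})
    return ops


def extend_to_avg(graph: HistoryGraph,
                  rng: Optional[random.Random] = None) -> HistoryGraph:
    """An AVG extension H of ``graph`` with s_u(H) <= s_u(G) and
    r_u(H) <= r_u(G).  Deterministic without an ``rng`` (first move in
    sorted order); otherwise the move is drawn from the current phase."""
    g = graph.copy()
    guard = 0
    monitor = None
    while True:
        lift = Lifting(g)
        u = ambiguity(g, lift)
        if u == 0:
            return g
        unattached_junctions = sum(
            1 for s in lift.junctions if not g.is_side_attached(s))
        key = (u, unattached_junctions)
        if monitor is not None and key >= monitor:
            raise AssertionError(
                f"extension loop failed to make progress: {key} !< {monitor}")
        monitor = key
        ops = _phase_ops(g, lift)
        if not ops:
            raise AssertionError("ambiguous graph with no applicable "
                                 "ambiguity-reducing move")
        op = rng.choice(ops) if rng is not None else ops[0]
        g = apply_extension(g, op)
        guard += 1
        if guard > 10000:
            raise AssertionError("extension loop exceeded move budget")


# ----------------------------------------------------------------------
# realisation of an AVG as a simple history
# ----------------------------------------------------------------------
def _thread_relation(g: HistoryGraph):
    """Maps vertex -> thread index, plus the ancestor relation between
    threads (via the event graph)."""
    threads = g.threads()
    comp_of = {v: i for i, t in enumerate(threads) for v in t.vertices}
    d = g.event_graph()
    reach = {n: nx.descendants(d, n) for n in d.nodes}

    def related(i: int, j: int) -> str:
        if i == j:
            return "equal"
        if j in reach[i]:
            return "ancestral"   # i ancestral to j
        if i in reach[j]:
            return "descendant"  # i descendant of j
        return "unrelated"

    return comp_of, related


def _module_of_side(modules, side: Side):
    for m in modules:
        if side in m.sides:
            return m
    return None


def _odd_path(module, a: Side, b: Side) -> bool:
    """Is b reachable from a within the module by a path with an odd
    number of (real or lifted) adjacency edges?"""
    edges = []
    for adj in module.real:
        edges.append((adj[0], adj[1]))
    for e in module.lifted:
        edges.append((e.ends[0], e.ends[1]))
    nbrs: dict[Side, set[Side]] = {}
    for u, v in edges:
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    seen = {(a, 0)}
    stack = [(a, 0)]
    while stack:
        s, par = stack.pop()
        for t in nbrs.get(s, ()):
            state = (t, 1 - par)
            if state not in seen:
                seen.add(state)
                stack.append(state)
    return (b, 1) in seen


def realise_avg(avg: HistoryGraph, attempts: int = 60,
                rng: Optional[random.Random] = None) -> HistoryGraph:
    """A simple history extending the AVG with s = lbsc and r = lbrc.

    The constructive completion below involves genuinely free choices
    (which module ends to pair, how surplus copies are matched, how
    displaced sides re-pair).  A first pass uses deterministic sorted
    tie-breaks; if its rearrangement cost exceeds the AVG's lower bound,
    further passes redraw the tie-breaks at random and the best
    realisation found is returned.  Substitution cost is exact by
    construction in every pass.
    """
    if not is_avg(avg):
        raise ValueError("input is not an AVG (it has non-zero ambiguity)")
    target = lbrc(avg)
    best = None
    best_r = None
    for i in range(max(1, attempts)):
        draw = None if i == 0 else random.Random(
            i if rng is None else rng.randrange(2 ** 30))
        real = _realise_once(avg, draw)
        from .costs import simple_history_costs
        _, r = simple_history_costs(real)
        if best is None or r < best_r:
            best, best_r = real, r
        if best_r <= target:
            break
    return best


def _realise_once(avg: HistoryGraph,
                  rng: Optional[random.Random] = None) -> HistoryGraph:
    """One realisation pass; ``rng`` redraws the free tie-breaks."""
    g = avg.copy()

    def maybe_shuffle(seq):
        seq = list(seq)
        if rng is not None:
            rng.shuffle(seq)
        return seq

    # give every attached root a fresh unattached parent, so the ends of
    # every module path are unattached root sides that the module
    # pairing below can close
    for v in list(g.vertices()):
        if g.parent(v) is None and g.is_attached(v):
            _interpolate_above(g, v)

    # roots whose trees carry attachments but which are themselves
    # unattached must be attached first; their free-root sides sit in
    # modules, and pairing the two ends of a module (preferring pairs
    # already joined by a lifted edge) leaves every lift's status intact.
    while True:  # even out odd modules with fresh root partners
        lift = Lifting(g)
        modules = [m for m in lift.modules() if len(m) % 2 == 1]
        if not modules:
            break
        m = modules[0]
        frees = [s for s in m.sides if is_free_root(s[0])
                 and not g.is_side_attached((s[0].split(":", 1)[1], s[1]))]
        if not frees:
            raise AssertionError("odd module without an unattached root")
        # avoid splitting a pair of free-root sides already joined by a
        # lifted edge: their roots should be attached to each other later
        lift_joined = {end for e in m.lifted for end in e.ends
                       if is_free_root(end[0])}
        fr_side = next((s for s in frees if s not in lift_joined), frees[0])
        root = fr_side[0].split(":", 1)[1]
        # the fresh partner is deliberately childless: it retires with
        # its thread at no cost once the paired lineage moves on
        y = g.add_vertex(g.fresh_id("e"))
        g.add_adjacency((root, fr_side[1]), (y, fr_side[1]))
    while True:  # pair unattached root sides within modules
        lift = Lifting(g)
        comp_of, related = _thread_relation(g)
        progress = False
        for m in lift.modules():
            face_roots = []
            for s in m.sides:
                if is_free_root(s[0]):
                    rs = (s[0].split(":", 1)[1], s[1])
                    if not g.is_side_attached(rs):
                        face_roots.append((s, rs))
            fr_map = dict(face_roots)
            used: set = set()
            for e in m.lifted:
                ea, eb = e.ends
                if ea in fr_map and eb in fr_map and ea != eb \
                        and ea not in used and eb not in used:
                    g.add_adjacency(fr_map[ea], fr_map[eb])
                    used.update((ea, eb))
                    progress = True
            rest = maybe_shuffle(
                rs for s, rs in face_roots if s not in used)
            while len(rest) >= 2:
                a = rest.pop(0)
                partner = next(
                    (b for b in rest
                     if related(comp_of[a[0]], comp_of[b[0]])
                     in ("equal", "unrelated")), None)
                if partner is None:
                    continue
                rest.remove(partner)
                g.add_adjacency(a, partner)
                progress = True
        if not progress:
            break

    # label propagation (unlabeled trees get a constant label; labels
    # are copied up then down so no branch adds a spurious substitution)
    for r in g.roots():
        tree = [r] + list(g.descendants(r))
        if not any(g.is_labeled(v) for v in tree):
            g.labels[r] = CASE8_LABEL
    changed = True
    while changed:
        changed = False
        for p, c in g.branches():
            if g.is_labeled(c) and not g.is_labeled(p):
                g.labels[p] = g.label(c)
                changed = True
    changed = True
    while changed:
        changed = False
        for p, c in g.branches():
            if g.is_labeled(p) and not g.is_labeled(c):
                g.labels[c] = g.label(p)
                changed = True

    return _build_epochs(g, rng)


def _thread_layer_longest_path(g: HistoryGraph) -> dict[str, int]:
    """Layer per vertex: longest-path layering of the event graph, so
    every branch spans >= 1 layer and adjacent vertices share a layer."""
    threads = g.threads()
    comp_of = {v: i for i, t in enumerate(threads) for v in t.vertices}
    d = g.event_graph()
    layer = {n: 0 for n in d.nodes}
    for n in nx.topological_sort(d):
        for m in d.successors(n):
            layer[m] = max(layer[m], layer[n] + 1)
    return {v: layer[comp_of[v]] for v in g.vertices()}


def _sole_attached_descendant(base: HistoryGraph, side: Side):
    """The unique most-ancestral attached descendant side (same
    orientation), or the side itself if attached, or None.  Uniqueness
    holds in an AVG: two would make an unattached junction side."""
    if base.is_side_attached(side):
        return side
    found = _most_ancestral_attached_descendants(base, side)
    if not found:
        return None
    assert len(found) == 1, f"unattached junction side {side}: {found}"
    return found[0]


def _build_epochs(base: HistoryGraph,
                  rng: Optional[random.Random] = None) -> HistoryGraph:
    """Stretch a root-completed, fully labeled AVG into a simple history."""
    g = base.copy()

    def maybe_shuffle(seq):
        seq = list(seq)
        if rng is not None:
            rng.shuffle(seq)
        return seq

    L = _thread_layer_longest_path(base)
    n_layers = max(L.values(), default=0)
    real_at: dict[int, list[str]] = {}
    for v in base.vertices():
        real_at.setdefault(L[v], []).append(v)

    def covering_side(tstar: Side, t_next: int, next_line_vertex):
        """The vertex standing in for side ``tstar``'s lineage at layer
        ``t_next``: the real vertex itself at its own layer, else the
        chain vertex of the base branch spanning the layer."""
        w, o = tstar
        prev = None
        while L[w] > t_next:
            prev = w
            w = base.parent(w)
            if w is None:
                return None
        if L[w] == t_next and prev is None:
            return (w, o)  # the real vertex itself (an arrival)
        if L[w] == t_next:
            return (w, o)
        line = (w, prev)
        cv = next_line_vertex.get(line)
        if cv is not None and cv != prev:
            return (cv, o)
        if cv == prev:
            return (prev, o)
        return None

    line_target: dict[str, tuple[str, str]] = {}
    cur_all: list[str] = sorted(real_at.get(0, []))

    for t in range(n_layers):
        cur_lines: dict[str, list[tuple[str, str]]] = {}
        for u in cur_all:
            if u in line_target:
                cur_lines[u] = [line_target.pop(u)]
        for p in real_at.get(t, []):
            for c in base.children(p):
                cur_lines.setdefault(p, []).append((p, c))
                if g.parent(c) == p:
                    g.delete_branch(p, c)
        n = max((len(ls) for ls in cur_lines.values()), default=1)

        mid_all = cur_all
        mid_line: dict[str, Optional[tuple[str, str]]] = {}
        if n > 1:
            # replication epoch: n children for every vertex that is
            # attached or carries lines; surplus copies are clones that
            # die immediately.  Copy sides pair across each parental
            # adjacency, aligning lineages whose terminal sides are
            # adjacent so they stay together all the way down.
            copies: dict[str, list[str]] = {}
            mid_all = []
            for u in cur_all:
                if u in cur_lines or g.is_attached(u):
                    kids = []
                    for i in range(n):
                        kid = g.add_vertex(g.fresh_id("m"), g.label(u))
                        g.add_branch(u, kid)
                        kids.append(kid)
                        mid_all.append(kid)
                    copies[u] = kids
                    for i, line in enumerate(cur_lines.get(u, [])):
                        mid_line[kids[i]] = line
            def _desire(side):
                # the side this copy's lineage is ultimately bound for
                line = mid_line.get(side[0])
                if line is None:
                    return "clone", None
                end = (line[1], side[1])
                sstar = _sole_attached_descendant(base, end)
                if sstar is None:
                    return "blind", None
                return "bound", base.partner(sstar)

            def _carries(side, desired):
                # does this copy's lineage pass through ``desired``?
                line = mid_line.get(side[0])
                if line is None or desired is None:
                    return False
                if side[1] != desired[1]:
                    return False
                d = line[1]
                return desired[0] == d or d in set(base.ancestors(desired[0]))

            for a, b in list(g.adjacencies()):
                if a[0] not in copies or b[0] not in copies:
                    continue
                asides = maybe_shuffle(
                    (copies[a[0]][i], a[1]) for i in range(n))
                bsides = maybe_shuffle(
                    (copies[b[0]][i], b[1]) for i in range(n))
                pairs = []
                # 1. a lineage bound for a terminal partner stays with
                #    the copy whose lineage carries that partner
                for sa in list(asides):
                    ka, want = _desire(sa)
                    if want is None:
                        continue
                    sb = next((s for s in bsides if _carries(s, want)), None)
                    if sb is not None:
                        pairs.append((sa, sb))
                        asides.remove(sa)
                        bsides.remove(sb)
                # 2. blind lineages pair together (they mirror each
                #    other for free); lineages that must re-pair later
                #    take a disposable clone that dies at the switch
                for prefer_a, prefer_b in (("blind", "blind"),
                                           ("bound", "clone"),
                                           ("clone", "bound"),
                                           ("blind", "clone"),
                                           ("clone", "blind")):
                    for sa in list(asides):
                        if _desire(sa)[0] != prefer_a:
                            continue
                        sb = next((s for s in bsides
                                   if _desire(s)[0] == prefer_b), None)
                        if sb is None:
                            break
                        pairs.append((sa, sb))
                        asides.remove(sa)
                        bsides.remove(sb)
                pairs.extend(zip(asides, bsides))
                for sa, sb in pairs:
                    g.add_adjacency(sa, sb)
        else:
            for u in cur_all:
                if u in cur_lines:
                    mid_line[u] = cur_lines[u][0]

        # rearrangement hop into layer t+1
        child_of: dict[str, str] = {}
        next_line_vertex: dict[tuple[str, str], str] = {}
        for u in mid_all:
            line = mid_line.get(u)
            if line is None:
                continue
            p, c = line
            if L[c] == t + 1:
                child = c
            else:
                child = g.add_vertex(g.fresh_id("m"), g.label(p))
                line_target[child] = line
            g.add_branch(u, child)
            child_of[u] = child
            next_line_vertex[line] = child

        # target proposals of line children: where each lineage's
        # terminal side is bound, if the opposing lineage is live now
        def line_pool_sides(u):
            child = child_of[u]
            line = mid_line.get(u)
            out = []
            for o in ORIENTATIONS:
                if not g.is_side_attached((u, o)):
                    continue
                side = (child, o)
                if g.is_side_attached(side):
                    continue  # real arrival with its own base adjacency
                out.append((side, (line[1], o) if line is not None else None))
            return out

        targets: dict[Side, Side] = {}
        for u in sorted(child_of):
            for side, end in line_pool_sides(u):
                if end is None:
                    continue
                sstar = _sole_attached_descendant(base, end)
                if sstar is None:
                    continue
                tstar = base.partner(sstar)
                cover = covering_side(tstar, t + 1, next_line_vertex)
                if cover is not None:
                    targets[side] = cover

        # ghost continuation: a vertex with no lineage of its own keeps
        # a child while an attached partner lineage continues with a
        # side that has no destination of its own (so attached partners
        # die together and no side is orphaned)
        continuing = set(child_of)
        changed = True
        while changed:
            changed = False
            for u in mid_all:
                if u in continuing:
                    continue
                for o in ORIENTATIONS:
                    if not g.is_side_attached((u, o)):
                        continue
                    w, ow = g.partner((u, o))
                    if w not in continuing:
                        continue
                    cw = child_of.get(w)
                    if cw is not None:
                        if g.is_side_attached((cw, ow)):
                            continue  # partner's side is spoken for
                        tgt = targets.get((cw, ow))
                        if tgt is not None and targets.get(tgt) == (cw, ow):
                            continue  # partner is mutually bound elsewhere
                    continuing.add(u)
                    changed = True
                    break
        for u in sorted(continuing):
            if u not in child_of:
                child = g.add_vertex(g.fresh_id("m"), g.label(u))
                g.add_branch(u, child)
                child_of[u] = child

        # the pairing pool: chain and ghost sides, plus real arrivals
        # whose side must attach (their lineage is attached) but has no
        # adjacency of its own in the base graph
        pool: list[tuple[Side, str, Optional[Side]]] = []
        for u in sorted(child_of):
            for side, end in line_pool_sides(u):
                pool.append((side, u, end))
        in_pool = {entry[0] for entry in pool}
        proposals: dict[Side, Side] = {}
        wanted: dict[Side, Side] = {}
        for side, u, end in pool:
            # a destination only counts when it is mutual: the covering
            # lineage must itself be bound for us, otherwise it has its
            # own arrival to honour and we keep the parental pattern
            cand = targets.get(side)
            if cand is not None and (cand not in in_pool
                                     or targets.get(cand) != side):
                cand = None
            mside = None
            mpartner = g.partner((u, side[1]))
            if mpartner is not None and mpartner[0] in child_of:
                mside = (child_of[mpartner[0]], mpartner[1])
            if cand is None and mside is not None and mside in in_pool:
                cand = mside
            if cand is not None:
                proposals[side] = cand
            # what this side would have joined, pool or not: used to
            # complete DCJs whose other half is a fixed arrival pair
            want = targets.get(side)
            if want is None:
                want = mside
            if want is not None:
                wanted[side] = want
        paired: set[Side] = set()
        formed: list[tuple[Side, Side]] = []
        for side, _, _ in pool:
            if side in paired:
                continue
            cand = proposals.get(side)
            if cand is not None and cand not in paired \
                    and proposals.get(cand) == side:
                g.add_adjacency(side, cand)
                paired.update((side, cand))
                formed.append((side, cand))
        # displaced sides complete the double-cut-and-join: two sides
        # whose desired partners were the two ends of a pair formed
        # above — or of a fixed arrival adjacency at this layer — are
        # the loose ends of that same rearrangement
        arrivals = {child_of[u] for u in child_of}
        for a, b in g.adjacencies():
            if a[0] in arrivals and b[0] in arrivals \
                    and a[0] in base.labels and b[0] in base.labels:
                formed.append((a, b))
        leftovers = [s for s, _, _ in pool if s not in paired]
        progress = True
        while progress:
            progress = False
            for x, y in formed:
                lx = [s for s in leftovers if wanted.get(s) == x]
                ly = [s for s in leftovers if wanted.get(s) == y]
                for a, b in zip(lx, ly):
                    g.add_adjacency(a, b)
                    formed.append((a, b))
                    leftovers.remove(a)
                    leftovers.remove(b)
                    progress = True
        leftovers = maybe_shuffle(leftovers)
        # a lonely displaced side revives the lineage its counterpart
        # abandoned: the retired vertex (and, by mirroring, any retired
        # partners it drags along) gets a ghost child to hold the bond
        def _revive(zv: str) -> str:
            child = g.add_vertex(g.fresh_id("m"), g.label(zv))
            g.add_branch(zv, child)
            child_of[zv] = child
            revived.append(zv)
            return child

        revived: list[str] = []
        for lone in list(leftovers):
            want = wanted.get(lone)
            if want is None:
                continue
            taker = g.partner(want)
            if taker is None:
                continue
            mid_parent = g.parent(taker[0])
            if mid_parent is None or mid_parent not in mid_all:
                continue
            z = g.partner((mid_parent, taker[1]))
            if z is None or z[0] in child_of:
                continue
            child = _revive(z[0])
            g.add_adjacency(lone, (child, z[1]))
            leftovers.remove(lone)
        qi = 0
        while qi < len(revived):
            zv = revived[qi]
            qi += 1
            child = child_of[zv]
            for o2 in ORIENTATIONS:
                if not g.is_side_attached((zv, o2)) or \
                        g.is_side_attached((child, o2)):
                    continue
                w2 = g.partner((zv, o2))
                wc = child_of.get(w2[0])
                if wc is None and w2[0] in mid_all:
                    wc = _revive(w2[0])
                if wc is not None and not g.is_side_attached((wc, w2[1])):
                    g.add_adjacency((child, o2), (wc, w2[1]))
                else:
                    leftovers.append((child, o2))

        fresh_material = []
        while len(leftovers) >= 2:
            a = leftovers.pop(0)
            b = leftovers.pop(0)
            g.add_adjacency(a, b)
        if leftovers:
            a = leftovers.pop()
            fresh = g.add_vertex(g.fresh_id("m"), CASE8_LABEL)
            g.add_adjacency(a, (fresh, a[1]))
            fresh_material.append(fresh)

        nxt = [child_of[u] for u in sorted(child_of)] + fresh_material
        arrived = set(nxt)
        nxt.extend(v for v in real_at.get(t + 1, []) if v not in arrived)
        cur_all = nxt
    return g
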