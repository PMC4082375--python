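"""Forward simulation of simple histories and their degraded reductions.

The protocol: a single linear chromosome of a few single-base segments
evolves through a fixed number of epochs, each either a whole-genome
(2-way) replication or a burst of DCJ rearrangements, with substitutions
applied at a constant per-branch rate.  Histories are retained only if
they contain substitutions, rearrangements and at least two replication
epochs.  A test pair (H, G) is produced by reducing H to its leaf
threads plus bare homology trees and then randomly degrading a fraction
of the leaf adjacencies, labels and vertices — emulating an incomplete
genome assembly.

Every reduction step is logged as an op record replayable through
:func:`historygraph.edits.apply_reduction`, so ``G`` is a reduction of
``H`` by construction.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .core import HEAD, ORIENTATIONS, TAIL, HistoryGraph, adjacency_key
from .edits import apply_reduction

BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Forward-simulation parameters.

    ``start_vertices`` segments in one linear thread, ``epochs`` epochs
    of uniformly chosen type, per-branch substitution probability
    ``substitution_rate``, 2-way replication, and ``1 + Poisson(rearrangement_mean)``
    DCJ operations per rearrangement epoch.  ``degradation_fraction`` is
    the expected share of leaf elements removed by :func:`degrade`.
    """

    start_vertices: int = 5
    epochs: int = 4
    substitution_rate: float = 0.05
    degradation_fraction: float = 0.10
    min_replications: int = 2
    rearrangement_mean: float = 0.5
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.start_vertices < 0 or self.epochs < 0:
            raise ValueError("counts must be non-negative")
        for r in (self.substitution_rate, self.degradation_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _poisson(rng: random.Random, lam: float) -> int:
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _substituted(rng: random.Random, base: str) -> str:
    return rng.choice([b for b in BASES if b != base])


def _simulate_once(params: SimParams, rng: random.Random) -> HistoryGraph:
    g = HistoryGraph()
    layer = []
    for i in range(params.start_vertices):
        layer.append(g.add_vertex(f"L00v{i:03d}", rng.choice(BASES)))
    for i in range(len(layer) - 1):
        g.add_adjacency((layer[i], HEAD), (layer[i + 1], TAIL))

    for e in range(1, params.epochs + 1):
        replicate = rng.random() < 0.5
        if replicate:
            children: dict[str, list[str]] = {}
            new_layer = []
            for v in layer:
                kids = []
                mutant = rng.randrange(2)  # at most one child may differ
                for k in range(2):
                    lab = g.label(v)
                    if k == mutant and rng.random() < params.substitution_rate:
                        lab = _substituted(rng, lab)
                    kid = g.add_vertex(f"L{e:02d}v{len(new_layer):03d}", lab)
                    g.add_branch(v, kid)
                    kids.append(kid)
                    new_layer.append(kid)
                children[v] = kids
            for a, b in list(g.adjacencies()):
                if a[0] in children and b[0] in children:
                    for k in range(2):
                        g.add_adjacency((children[a[0]][k], a[1]),
                                        (children[b[0]][k], b[1]))
            layer = new_layer
        else:
            child_of = {}
            new_layer = []
            for v in layer:
                lab = g.label(v)
                if rng.random() < params.substitution_rate:
                    lab = _substituted(rng, lab)
                kid = g.add_vertex(f"L{e:02d}v{len(new_layer):03d}", lab)
                g.add_branch(v, kid)
                child_of[v] = kid
                new_layer.append(kid)
            child_adjs = []
            for a, b in g.adjacencies():
                if a[0] in child_of and b[0] in child_of:
                    child_adjs.append(((child_of[a[0]], a[1]),
                                      (child_of[b[0]], b[1])))
            n_ops = 1 + _poisson(rng, params.rearrangement_mean)
            for _ in range(n_ops):
                if len(child_adjs) < 2:
                    break
                i, j = rng.sample(range(len(child_adjs)), 2)
                (a, b), (c, d) = child_adjs[i], child_adjs[j]
                if rng.random() < 0.5:
                    pair = ((a, c), (b, d))
                else:
                    pair = ((a, d), (b, c))
                # reject a rematch that would pair a side with itself
                if any(s == t for s, t in pair):
                    continue
                for k in sorted((i, j), reverse=True):
                    del child_adjs[k]
                child_adjs.extend(pair)
            for a, b in child_adjs:
                g.add_adjacency(a, b)
            layer = new_layer
    return g


def simulate_history(params: SimParams = SimParams(),
                     rng: Optional[random.Random] = None,
                     seed: Optional[int] = None) -> HistoryGraph:
    """A simple history satisfying the selection predicate (substitutions
    present, rearrangements present, >= ``min_replications`` replication
    epochs), found by a retry loop."""
    from .costs import simple_history_costs
    from .transform import validate_simple_history

    if rng is None:
        rng = random.Random(seed)
    for _ in range(params.max_attempts):
        g = _simulate_once(params, rng)
        ok, epochs, _ = validate_simple_history(g)
        assert ok, "simulator emitted a non-simple history"
        if params.epochs == 0:
            return g
        n_rep = sum(1 for ep in epochs if ep.kind == "replication")
        if n_rep < params.min_replications:
            continue
        s, r = simple_history_costs(g)
        if s > 0 and r > 0:
            return g
    raise RuntimeError("retry budget exhausted: no history satisfied the "
                       "selection predicate")


# ----------------------------------------------------------------------
# reduction protocol
# ----------------------------------------------------------------------
@dataclass
class ReductionResult:
    graph: HistoryGraph
    log: list[dict] = field(default_factory=list)


def reduce_to_leaves(history: HistoryGraph) -> ReductionResult:
    """Strip all ancestral detail from a simple history.

    Labels of non-leaf vertices and adjacencies incident on non-leaf
    vertices are deleted, then the parent branches of all internal
    vertices are contracted, leaving the leaf threads plus bare homology
    trees.  The op log replays through ``apply_reduction``.
    """
    g = history.copy()
    log: list[dict] = []

    def run(op):
        nonlocal g
        g = apply_reduction(g, op)
        log.append(op)

    internal_or_root = [v for v in g.vertices() if not g.is_leaf(v)]
    for v in internal_or_root:
        if g.is_labeled(v):
            run({"kind": "delete_label", "vertex": v})
    for adj in g.adjacencies():
        if not g.is_leaf(adj[0][0]) or not g.is_leaf(adj[1][0]):
            run({"kind": "delete_adjacency", "sides": list(adj)})
    # contract parent branches of internal vertices (now all free)
    while True:
        target = next(
            (v for v in g.vertices()
             if g.parent(v) is not None and not g.is_leaf(v)
             and not g.is_labeled(v) and not g.is_attached(v)), None)
        if target is None:
            break
        run({"kind": "contract_branch", "parent": g.parent(target),
             "child": target})
    return ReductionResult(g, log)


def degrade(graph: HistoryGraph, fraction: float,
            rng: random.Random) -> ReductionResult:
    """Randomly remove ~``fraction`` of leaf adjacencies, labels and
    vertices, using only legal reduction operations (a removed vertex
    first loses its label and adjacencies, then its parent branch is
    contracted or the isolated vertex deleted)."""
    g = graph.copy()
    log: list[dict] = []

    def run(op):
        nonlocal g
        g = apply_reduction(g, op)
        log.append(op)

    doomed_vertices = [v for v in graph.vertices() if graph.is_leaf(v)
                       and rng.random() < fraction]
    doomed_adjs = [adj for adj in graph.adjacencies()
                   if rng.random() < fraction]
    doomed_labels = [v for v in graph.vertices()
                     if graph.is_labeled(v) and rng.random() < fraction]

    for v in doomed_vertices:
        if g.is_labeled(v):
            run({"kind": "delete_label", "vertex": v})
        for side in g.sides(v):
            partner = g.partner(side)
            if partner is not None:
                run({"kind": "delete_adjacency",
                     "sides": [list(side), list(partner)]})
        if g.parent(v) is not None:
            run({"kind": "contract_branch", "parent": g.parent(v),
                 "child": v})
        elif g.is_isolated(v):
            run({"kind": "delete_vertex", "vertex": v})
    for adj in doomed_adjs:
        if adj in set(g.adjacencies()):
            run({"kind": "delete_adjacency", "sides": list(adj)})
    for v in doomed_labels:
        if v in g.labels and g.is_labeled(v):
            run({"kind": "delete_label", "vertex": v})
    return ReductionResult(g, log)


def simulate_pair(params: SimParams = SimParams(),
                  seed: Optional[int] = None,
                  rng: Optional[random.Random] = None):
    """A (simple history H, degraded seed graph G) test pair."""
    if rng is None:
        rng = random.Random(seed)
    h = simulate_history(params, rng=rng)
    reduced = reduce_to_leaves(h)
    degraded = degrade(reduced.graph, params.degradation_fraction, rng)
    return h, degraded.graph, reduced.log + degraded.log
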