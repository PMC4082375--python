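"""Random-walk sampling of G-bounded AVG extensions.

From a seed history graph G (with its identity fix), walks repeatedly
apply uniformly chosen applicable G-bounded extension operations until an
AVG is reached.  A walk is pruned (restarted) as soon as the sum of its
lower-bound costs exceeds the incumbent: initially the seed's upper-bound
sum s_u(G) + r_u(G), then the cost of the best AVG found so far.  Because
every G-bounded graph respects the closed-form size limits (at most
max(0, 10n-8) reducible adjacencies and max(0, 2m-2, 20n-16, 20n+2m-18)
additional vertices for a seed with n adjacencies and m labeled
vertices), every walk terminates within a computable move budget.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .core import HistoryGraph
from .costs import (CostFunction, DEFAULT_COST, bounds_report, lbrc, lbsc)
from .edits import Fix, apply_g_bounded_op, is_g_bounded, \
    random_g_bounded_attachment
from .lifting import Lifting


def reducible_adjacency_bound(n: int) -> int:
    """Closed-form cap on G-reducible adjacencies for a seed with n
    adjacencies: max(0, 10n - 8)."""
    return max(0, 10 * n - 8)


def additional_vertex_bound(n: int, m: int) -> int:
    """Closed-form cap on additional vertices for a seed with n
    adjacencies and m labeled vertices:
    max(0, 2m - 2, 20n - 16, 20n + 2m - 18)."""
    return max(0, 2 * m - 2, 20 * n - 16, 20 * n + 2 * m - 18)


@dataclass
class WalkResult:
    """One retained AVG endpoint of a walk."""

    s: int
    r: int
    cost: float
    moves: int
    log: list[dict]


@dataclass
class SampleReport:
    """Outcome of a sampling run over one seed graph."""

    seed_bounds: dict
    n_starts: int = 0
    n_retained: int = 0
    n_pruned: int = 0
    best: Optional[WalkResult] = None
    s_min: Optional[int] = None
    s_max: Optional[int] = None
    r_min: Optional[int] = None
    r_max: Optional[int] = None
    best_graph: Optional[HistoryGraph] = None
    walks: list[WalkResult] = field(default_factory=list)

    def table_row(self) -> dict:
        """Summary columns: ambiguities, bounds and retained extremes."""
        b = self.seed_bounds
        return {"u_s": b["u_s"], "s_l": b["s_l"], "s_u": b["s_u"],
                "s_min": self.s_min, "s_max": self.s_max,
                "u_r": b["u_r"], "r_l": b["r_l"], "r_u": b["r_u"],
                "r_min": self.r_min, "r_max": self.r_max,
                "starts": self.n_starts, "retained": self.n_retained,
                "pruned": self.n_pruned}


def sample_avgs(seed_graph: HistoryGraph, n_starts: int,
                rng: Optional[random.Random] = None,
                cost_fn: CostFunction = DEFAULT_COST,
                keep_logs: bool = False,
                check_size_bounds: bool = True) -> SampleReport:
    """Sample G-bounded AVG extensions of ``seed_graph``.

    Every retained endpoint is a G-bounded AVG; the report records the
    spread of substitution and rearrangement costs over retained AVGs
    and the best endpoint under ``cost_fn``.
    """
    if rng is None:
        rng = random.Random(0)
    fix = Fix.identity(seed_graph)
    sb = bounds_report(seed_graph)
    report = SampleReport(seed_bounds=sb.as_dict())
    incumbent = cost_fn(sb.s_u, sb.r_u)
    n = len(seed_graph.adjacencies())
    m = sum(1 for v in seed_graph.vertices() if seed_graph.is_labeled(v))
    adj_cap = reducible_adjacency_bound(n)
    vert_cap = additional_vertex_bound(n, m)
    move_budget = 2 * (adj_cap + vert_cap + m) + 20
    n_seed_vertices = len(seed_graph.vertices())

    for _ in range(n_starts):
        report.n_starts += 1
        g = seed_graph.copy()
        log: list[dict] = []
        pruned = False
        for _move in range(move_budget):
            lift = Lifting(g)
            if check_size_bounds:
                n_red = sum(1 for adj in g.adjacencies()
                            if fix.reducible_adjacency(adj))
                extra = len(g.vertices()) - n_seed_vertices
                if n_red > adj_cap or extra > vert_cap:
                    raise AssertionError(
                        f"size bound violated: {n_red} reducible "
                        f"adjacencies (cap {adj_cap}), {extra} extra "
                        f"vertices (cap {vert_cap})")
            if cost_fn(lbsc(g, lift), lbrc(g, lift)) > incumbent:
                pruned = True
                break
            step = random_g_bounded_attachment(g, fix, rng, lift)
            if step is None:
                break  # an AVG
            op, g = step
            log.append(op)
        else:
            raise AssertionError("walk exceeded its move budget, "
                                 "contradicting the size bounds")
        if pruned:
            report.n_pruned += 1
            continue
        b = bounds_report(g)
        if not b.is_avg:
            raise AssertionError("walk ended on a non-AVG with no "
                                 "applicable extension operation")
        ok, diags = is_g_bounded(g, fix, collect=False)
        if not ok:
            raise AssertionError(f"endpoint is not G-bounded: {diags}")
        s, r = b.s_l, b.r_l
        cost = cost_fn(s, r)
        res = WalkResult(s, r, cost, len(log), log if keep_logs else [])
        report.n_retained += 1
        if keep_logs:
            report.walks.append(res)
        if report.best is None or cost < report.best.cost:
            report.best = res
            report.best_graph = g
        incumbent = min(incumbent, cost)
        report.s_min = s if report.s_min is None else min(report.s_min, s)
        report.s_max = s if report.s_max is None else max(report.s_max, s)
        report.r_min = r if report.r_min is None else min(report.r_min, r)
        report.r_max = r if report.r_max is None else max(report.r_max, r)
    return report


def replay(seed_graph: HistoryGraph, walk_log: list[dict]) -> HistoryGraph:
    """Reconstruct a walk endpoint from its op log, bit-identically.

    Raises if an op does not apply (log/graph mismatch).
    """
    g = seed_graph.copy()
    fix = Fix.identity(seed_graph)
    for op in walk_log:
        g = apply_g_bounded_op(g, fix, op)
    return g
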