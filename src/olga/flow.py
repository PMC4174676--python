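"""Maximum-likelihood read copy counts via convex min-cost bidirected flow.

Each edge's copy count f (how many times its string occurs in the genome) is
scored by the negative log Poisson likelihood of its observed read count x
under arrival rate λ·f, λ = (n/L)·(effective edge length):

    cost_e(f) = λ_e·f − x_e·ln f        (f >= 1; additive constant dropped)

which is separable convex, minimized near f* = x_e/λ_e.  The R(e,m) log-odds
statistics fix per-edge capacity bounds; every vertex must be traversed at
least once (its read is part of the genome).  Each convex cost gets a
three-piece linear approximation and the bidirected instance is reduced to a
directed min-cost circulation on a strand-doubled network (each vertex splits
into a forward-state and a reverse-state node, each edge into a mirror pair
of arc bundles), solved exactly with the network simplex.  Walks may start
and end anywhere at a per-endpoint penalty, which models linear genomes and
coverage gaps; the mirror symmetry of the doubled network guarantees a
symmetric optimum, recovered by averaging the two mirror flows (an exact
integer re-solve handles the rare half-integral case).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .graph import FWD, REV, OverlapGraph, flip
from .stats import edge_logodds, effective_length

logger = logging.getLogger(__name__)

_COST_SCALE = 10**6  # slopes are scaled to integers for the exact solver


@dataclass
class CapacityBounds:
    l: int
    u: Optional[int]  # None = unbounded

    def __post_init__(self):
        if self.l < 0 or (self.u is not None and self.u < self.l):
            raise ValueError("require 0 <= l <= u")


@dataclass
class FlowConfig:
    """Thresholds of the copy-count stage.

    ``T`` is the log-odds confidence threshold for fixing bounds; edges of at
    least ``unique_len`` bases are long enough for the statistics to be
    informative; shorter composite edges with at least ``short_edge_reads``
    reads still get a lower bound of 1.  ``zero_flow_penalty`` is the cost of
    leaving an l=0 edge out of the assembly (None: λ_e + x_e·ln(x_e+1), the
    cost of explaining its reads as noise).  ``walk_end_penalty`` is charged
    per walk endpoint; ``max_multiplicity`` caps the search for the smallest
    confident m."""

    T: float = 3.0
    unique_len: int = 1000
    short_edge_reads: int = 30
    zero_flow_penalty: Optional[float] = None
    walk_end_penalty: float = 10.0
    max_multiplicity: int = 1000

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T > 0 required")


def assign_capacity_bounds(
    g: OverlapGraph, n: int, L: float, config: FlowConfig | None = None
) -> Dict[int, CapacityBounds]:
    """Per-edge flow bounds from the R(e,m) statistics.

    In priority order: (1) long edge confidently unique (R(e,1) >= T) →
    l=u=1; (2) long edge with a confident multiplicity m (smallest m with
    R(e,m−1) <= −T and R(e,m) >= T) → l=m, u=∞; (3) other long edges → l=1,
    u=∞; (4) short composite edges with >= ``short_edge_reads`` reads → l=1,
    u=∞; (5) the rest → l=0, u=∞.  Every vertex additionally carries an
    implicit lower bound of 1, enforced by the solver's vertex splitting.
    """
    config = config or FlowConfig()
    out: Dict[int, CapacityBounds] = {}
    for eid in g.edges:
        d = g.edge_len(eid)
        k = g.k(eid)
        if d >= config.unique_len:
            r1 = edge_logodds(g, eid, 1, n, L)
            if r1 >= config.T:
                b = CapacityBounds(1, 1)
            else:
                m_found = None
                for m in range(2, config.max_multiplicity + 1):
                    if edge_logodds(g, eid, m, n, L) >= config.T:
                        if edge_logodds(g, eid, m - 1, n, L) <= -config.T:
                            m_found = m
                        break
                b = CapacityBounds(m_found, None) if m_found else CapacityBounds(1, None)
        elif k >= config.short_edge_reads:
            b = CapacityBounds(1, None)
        else:
            b = CapacityBounds(0, None)
        out[eid] = b
        g.edges[eid].lb, g.edges[eid].ub = b.l, b.u
    return out


@dataclass
class EdgeCost:
    """Convex copy-count cost of one edge: λ·f − x·ln f for f >= 1, a flat
    penalty at f = 0 (only reachable when the lower bound is 0)."""

    lam: float
    x: int
    zero_penalty: float

    def __call__(self, f: float) -> float:
        if f < 0:
            raise ValueError("flow must be nonnegative")
        if f == 0:
            return self.zero_penalty
        return self.lam * f - self.x * math.log(f)

    def integer_minimizer(self, lo: int = 1, hi: int = 10**9) -> int:
        """argmin over integers in [lo, hi]; the continuous optimum is x/λ."""
        fc = self.x / self.lam if self.lam > 0 else hi
        cands = {lo, hi, int(math.floor(fc)), int(math.ceil(fc))}
        cands = {c for c in cands if lo <= c <= hi}
        return min(cands, key=lambda f: (self(f), f))


def edge_cost_function(
    g: OverlapGraph, eid: int, n: int, L: float, config: FlowConfig | None = None
) -> EdgeCost:
    config = config or FlowConfig()
    d_eff = effective_length(g.edge_len(eid), g.read_len)
    lam = (n / L) * d_eff
    x = g.k(eid)
    zp = config.zero_flow_penalty
    if zp is None:
        zp = lam + x * math.log(x + 1)
    return EdgeCost(lam=lam, x=x, zero_penalty=zp)


def flow_horizon(cost: EdgeCost, bounds: CapacityBounds) -> int:
    """Finite search range for an unbounded edge: at least twice the
    continuous optimum, never below 4 or the lower bound."""
    if bounds.u is not None:
        return bounds.u
    h = max(4, int(math.ceil(2 * cost.x / cost.lam)) if cost.lam > 0 else 4)
    return max(h, bounds.l, 1)


def linearize_three_piece(
    cost: EdgeCost, bounds: CapacityBounds, horizon: Optional[int] = None
) -> List[Tuple[int, int, float]]:
    """Piecewise-linear convex approximation with at most three segments.

    Breakpoints are the lower bound, the integer minimizer f* and the horizon
    (plus f=1 when flow 0 is allowed); the approximation interpolates the
    exact cost at every breakpoint and its slopes are non-decreasing.
    Returns segments ``(f_lo, f_hi, slope)``.
    """
    h = horizon if horizon is not None else flow_horizon(cost, bounds)
    lo = bounds.l
    knots = {lo, h}
    if lo == 0 and h >= 1:
        knots.add(1)
    if h >= 1:
        knots.add(cost.integer_minimizer(max(1, lo), h))
    ks = sorted(knots)
    segs = []
    for a, b in zip(ks, ks[1:]):
        segs.append((a, b, (cost(b) - cost(a)) / (b - a)))
    for (_, _, s1), (_, _, s2) in zip(segs, segs[1:]):
        assert s2 >= s1 - 1e-9, "linearization lost convexity"
    return segs


@dataclass
class CopyCountSolution:
    """Integer copy counts per edge (flow) and per read, with the exact
    objective value of the linearized instance."""

    edge_flow: Dict[int, int]
    read_copy: Dict[str, int]
    objective: float
    walk_endpoints: int
    method: str = "network-simplex"


def _directed_network(g, bounds, costs, horizons, segs, penalty_scaled):
    """Strand-doubled directed circulation network with demand-transformed
    lower bounds.  Mirror arc pairs: u→v in strand state (su→sv) and
    v→u in (1-sv → 1-su)."""
    D = nx.DiGraph()
    demand: Dict = {}
    BIG = sum(horizons.values()) + 2 * g.n_vertices + 10

    def bump(node, delta):
        demand[node] = demand.get(node, 0) + delta

    def add_arc(a, b, cap, w):
        if cap <= 0:
            return
        D.add_edge(a, b, capacity=cap, weight=w)

    active = [v for v in range(g.n_vertices) if g.degree(v) > 0]
    for v in active:
        for s in (FWD, REV):
            # vertex splitting with an internal lower bound of 1
            bump(("i", v, s), -1)
            bump(("o", v, s), +1)
            add_arc(("i", v, s), ("o", v, s), BIG, 0)
            add_arc("G", ("i", v, s), BIG, penalty_scaled)
            add_arc(("o", v, s), "G", BIG, penalty_scaled)
    D.add_node("G")

    for eid, e in g.edges.items():
        l = bounds[eid].l
        dirs = [
            (("o", e.u, e.su), ("i", e.v, e.sv)),
            (("o", e.v, flip(e.sv)), ("i", e.u, flip(e.su))),
        ]
        for di, (a, b) in enumerate(dirs):
            if l > 0:  # fixed part of the flow, removed by the demand transform
                bump(a, +l)
                bump(b, -l)
            for j, (f_lo, f_hi, slope) in enumerate(segs[eid]):
                mid = ("s", eid, di, j)
                w = int(round(slope * _COST_SCALE))
                add_arc(a, mid, f_hi - f_lo, w)
                add_arc(mid, b, f_hi - f_lo, 0)
    for node, d in demand.items():
        if not D.has_node(node):
            D.add_node(node)
        D.nodes[node]["demand"] = d
    for node in D.nodes:
        D.nodes[node].setdefault("demand", 0)
    return D


def _milp_exact(g, bounds, costs, horizons, segs, penalty):
    """Exact integer re-solve of the bidirected instance (scipy MILP),
    used when mirror averaging yields a half-integral flow."""
    from scipy.optimize import LinearConstraint, milp

    eids = sorted(g.edges)
    seg_vars = []  # (eid, f_lo, f_hi, slope)
    for eid in eids:
        for f_lo, f_hi, slope in segs[eid]:
            seg_vars.append((eid, f_lo, f_hi, slope))
    active = [v for v in range(g.n_vertices) if g.degree(v) > 0]
    nv = len(active)
    n_seg = len(seg_vars)
    # variables: segment fills, then per-vertex (gin, gout)
    nvar = n_seg + 2 * nv
    c = np.zeros(nvar)
    ub = np.zeros(nvar)
    for i, (_, f_lo, f_hi, slope) in enumerate(seg_vars):
        c[i] = slope
        ub[i] = f_hi - f_lo
    for j in range(2 * nv):
        c[n_seg + j] = penalty
        ub[n_seg + j] = sum(bounds[e].l for e in eids) + sum(horizons.values()) + 2 * nv + 10

    A_bal, b_bal = [], []
    A_thr, lb_thr = [], []
    for vi, v in enumerate(active):
        fwd_side, rev_side = g.sides(v)
        row_bal = np.zeros(nvar)
        row_thr = np.zeros(nvar)
        const_f = const_r = 0.0
        for (eid, _endi) in fwd_side:
            for i, (se, _, _, _) in enumerate(seg_vars):
                if se == eid:
                    row_bal[i] += 1
                    row_thr[i] += 1
            const_f += bounds[eid].l
        for (eid, _endi) in rev_side:
            for i, (se, _, _, _) in enumerate(seg_vars):
                if se == eid:
                    row_bal[i] -= 1
            const_r += bounds[eid].l
        row_bal[n_seg + 2 * vi] = -1  # gin
        row_bal[n_seg + 2 * vi + 1] = 1  # gout
        A_bal.append(row_bal)
        b_bal.append(const_r - const_f)
        row_thr[n_seg + 2 * vi + 1] = 1  # S_f + gout >= 1
        A_thr.append(row_thr)
        lb_thr.append(1 - const_f)
    constraints = [
        LinearConstraint(np.array(A_bal), np.array(b_bal), np.array(b_bal)),
        LinearConstraint(np.array(A_thr), np.array(lb_thr), np.inf),
    ]
    from scipy.optimize import Bounds as SpBounds

    res = milp(
        c,
        constraints=constraints,
        bounds=SpBounds(np.zeros(nvar), ub),
        integrality=np.ones(nvar),
    )
    if not res.success:
        raise RuntimeError(f"exact integer flow solve failed: {res.message}")
    flows = {}
    for eid in eids:
        f = bounds[eid].l
        for i, (se, f_lo, f_hi, _) in enumerate(seg_vars):
            if se == eid:
                f += int(round(res.x[i]))
        flows[eid] = f
    endpoints = int(round(sum(res.x[n_seg:])))
    return flows, endpoints


def solve_copy_counts(
    g: OverlapGraph,
    n: int,
    L: float,
    config: FlowConfig | None = None,
    bounds: Optional[Dict[int, CapacityBounds]] = None,
    costs: Optional[Dict[int, EdgeCost]] = None,
) -> CopyCountSolution:
    """Solve for maximum-likelihood integer copy counts.

    Flow conservation holds at every node of the directed reduction and every
    edge flow respects its bounds (both asserted post-solve); edge flows are
    written back onto the graph and per-read copy counts are looked up from
    the read placements.
    """
    config = config or FlowConfig()
    if bounds is None:
        bounds = assign_capacity_bounds(g, n, L, config)
    if costs is None:
        costs = {eid: edge_cost_function(g, eid, n, L, config) for eid in g.edges}
    horizons = {eid: flow_horizon(costs[eid], bounds[eid]) for eid in g.edges}
    segs = {eid: linearize_three_piece(costs[eid], bounds[eid], horizons[eid]) for eid in g.edges}
    penalty_scaled = int(round(config.walk_end_penalty * _COST_SCALE))

    D = _directed_network(g, bounds, costs, horizons, segs, penalty_scaled)
    method = "network-simplex"
    try:
        flow_dict = nx.min_cost_flow(D)
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - ground arcs keep it feasible
        raise RuntimeError(f"copy-count flow instance infeasible: {exc}") from exc

    # conservation check on the directed reduction
    for node in D.nodes:
        inflow = sum(flow_dict[p].get(node, 0) for p in D.predecessors(node))
        outflow = sum(flow_dict[node].values())
        assert inflow - outflow == D.nodes[node]["demand"], "conservation violated"

    def dir_total(eid, di):
        e = g.edges[eid]
        tails = [("o", e.u, e.su), ("o", e.v, flip(e.sv))]
        total = bounds[eid].l
        for j in range(len(segs[eid])):
            mid = ("s", eid, di, j)
            if D.has_node(mid):
                total += flow_dict[tails[di]].get(mid, 0)
        return total

    flows: Dict[int, int] = {}
    half = False
    for eid in g.edges:
        f1 = dir_total(eid, 0)
        f2 = dir_total(eid, 1)
        if (f1 + f2) % 2:
            half = True
            break
        flows[eid] = (f1 + f2) // 2
    ground_out = sum(flow_dict.get("G", {}).values())
    ground_in = sum(flow_dict[p].get("G", 0) for p in D.predecessors("G")) if D.has_node("G") else 0
    endpoints = (ground_out + ground_in) // 2

    if half:
        logger.info("mirror-averaged flow is half-integral; exact integer re-solve")
        flows, endpoints = _milp_exact(
            g, bounds, costs, horizons, segs, config.walk_end_penalty
        )
        method = "milp"

    for eid, f in flows.items():
        b = bounds[eid]
        assert b.l <= f and (b.u is None or f <= b.u), "flow bound violated"
        g.edges[eid].flow = f

    objective = sum(_pwl_value(segs[eid], costs[eid], bounds[eid].l, flows[eid]) for eid in g.edges)
    objective += config.walk_end_penalty * endpoints

    read_copy: Dict[str, int] = {}
    for eid in g.edges:
        f = flows[eid]
        for rid, _off, _s in g.edge_reads(eid):
            read_copy[rid] = max(read_copy.get(rid, 0), f)

    return CopyCountSolution(
        edge_flow=flows,
        read_copy=read_copy,
        objective=objective,
        walk_endpoints=endpoints,
        method=method,
    )


def _pwl_value(segments, cost: EdgeCost, l: int, f: int) -> float:
    """Value of the piecewise-linear approximation at integer flow f."""
    val = cost(l)
    for f_lo, f_hi, slope in segments:
        take = min(max(f - f_lo, 0), f_hi - f_lo)
        val += slope * take
    return val


def dump_edge_table(g: OverlapGraph, n: int, L: float, path) -> None:
    """TSV of per-edge (d, k, R(e,1), l, u, flow) for inspection."""
    with open(path, "w") as fh:
        fh.write("edge\td\tk\tR1\tl\tu\tflow\n")
        for eid in sorted(g.edges):
            e = g.edges[eid]
            r1 = edge_logodds(g, eid, 1, n, L)
            u = "inf" if e.ub is None else e.ub
            fh.write(
                f"E{eid}\t{g.edge_len(eid)}\t{g.k(eid)}\t{r1:.3f}\t{e.lb}\t{u}\t{e.flow}\n"
            )
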