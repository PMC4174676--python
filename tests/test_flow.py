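"""Capacity bounds, convex costs, linearization, min-cost-flow copy counts."""

import itertools
import math

import pytest

from olga.flow import (
    CapacityBounds,
    EdgeCost,
    FlowConfig,
    assign_capacity_bounds,
    edge_cost_function,
    flow_horizon,
    linearize_three_piece,
    solve_copy_counts,
)
from olga.graph import FWD, build_graph
from olga.simplify import clean
from olga.stats import edge_logodds
from tests.conftest import add_toy_edge, make_toy_graph, simulate_dataset

N, L = 1000, 100_000  # toy-scale global read count and genome length


class TestCapacityBounds:
    def _single(self, d, k, ell=100):
        g = make_toy_graph(2, ell=ell)
        e = add_toy_edge(g, 0, 1, d=d, k=k)
        return g, e

    def test_confident_unique_edge_pinned(self):
        g, e = self._single(2000, 10)
        assert edge_logodds(g, e.eid, 1, N, L) >= 3
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (1, 1)

    def test_confident_multiplicity_two(self):
        g, e = self._single(2000, 38)
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (2, None)

    def test_confident_multiplicity_three(self):
        g, e = self._single(2199, 60)
        r = [edge_logodds(g, e.eid, m, N, L) for m in (1, 2, 3)]
        assert r[0] <= -3 and r[1] <= -3 and r[2] >= 3
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (3, None)

    def test_inconclusive_long_edge_falls_back(self):
        g, e = self._single(2000, 24)
        r1 = edge_logodds(g, e.eid, 1, N, L)
        assert -3 < r1 < 3
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (1, None)

    def test_short_well_covered_edge(self):
        g, e = self._single(500, 35, ell=50)
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (1, None)

    def test_trivial_bounds(self):
        g, e = self._single(500, 12, ell=50)
        b = assign_capacity_bounds(g, N, L)[e.eid]
        assert (b.l, b.u) == (0, None)


class TestEdgeCost:
    def test_minimizer_at_expected_copy_number(self):
        c1 = EdgeCost(lam=20.0, x=20, zero_penalty=1e9)
        assert c1.integer_minimizer() == 1
        c2 = EdgeCost(lam=20.0, x=40, zero_penalty=1e9)
        assert c2.integer_minimizer() == 2

    def test_discrete_convexity(self):
        import random

        rng = random.Random(1)
        for _ in range(50):
            c = EdgeCost(lam=rng.uniform(1, 50), x=rng.randint(0, 200), zero_penalty=0)
            for f in range(2, 20):
                assert c(f - 1) + c(f + 1) >= 2 * c(f) - 1e-9


class TestLinearization:
    def test_linear_cost_is_fixpoint(self):
        c = EdgeCost(lam=5.0, x=0, zero_penalty=0.0)
        segs = linearize_three_piece(c, CapacityBounds(0, None), horizon=6)
        for f in range(0, 7):
            val = c(0) + sum(s * (min(f, b) - min(f, a)) for a, b, s in segs)
            assert val == pytest.approx(c(f) if f else c(0))

    def test_three_segments_with_interior_minimum(self):
        c = EdgeCost(lam=10.0, x=20, zero_penalty=10 + 20 * math.log(21))
        segs = linearize_three_piece(c, CapacityBounds(0, None), horizon=6)
        assert len(segs) == 3
        slopes = [s for _, _, s in segs]
        assert slopes == sorted(slopes)
        # interpolates the exact cost at every breakpoint
        knots = [segs[0][0]] + [b for _, b, _ in segs]
        for kn in knots:
            val = c(segs[0][0]) + sum(
                s * (min(kn, b) - min(kn, a)) for a, b, s in segs
            )
            assert val == pytest.approx(c(kn))

    def test_approximation_error_bounded_between_knots(self):
        import random

        rng = random.Random(2)
        for _ in range(30):
            lam = rng.uniform(5, 30)
            x = rng.randint(1, 150)
            c = EdgeCost(lam=lam, x=x, zero_penalty=lam + x * math.log(x + 1))
            b = CapacityBounds(0, None)
            h = flow_horizon(c, b)
            segs = linearize_three_piece(c, b, h)
            for f in range(0, h + 1):
                val = c(0) + sum(s * (min(f, hi) - min(f, lo)) for lo, hi, s in segs)
                assert val >= c(f) - 1e-6  # PWL over-approximates a convex function


# ---------------------------------------------------------------------------
# solver vs exhaustive enumeration
# ---------------------------------------------------------------------------


def enumeration_optimum(g, n, L, config):
    """Independent oracle: enumerate all integer edge flows within bounds and
    horizon; walk endpoints at each vertex cost P per unit of side imbalance
    (2P for an untraversed vertex, which must still appear in the assembly)."""
    bounds = {eid: CapacityBounds(g.edges[eid].lb, g.edges[eid].ub) for eid in g.edges}
    costs = {eid: edge_cost_function(g, eid, n, L, config) for eid in g.edges}
    horizons = {eid: flow_horizon(costs[eid], bounds[eid]) for eid in g.edges}
    segs = {eid: linearize_three_piece(costs[eid], bounds[eid], horizons[eid]) for eid in g.edges}
    eids = sorted(g.edges)

    def pwl(eid, f):
        return costs[eid](bounds[eid].l) + sum(
            s * (min(f, hi) - min(f, lo)) for lo, hi, s in segs[eid] if f > lo
        )

    sides = {}
    for v in range(g.n_vertices):
        if g.degree(v):
            sides[v] = g.sides(v)
    best = None
    for combo in itertools.product(*(range(bounds[e].l, horizons[e] + 1) for e in eids)):
        flows = dict(zip(eids, combo))
        total = sum(pwl(e, f) for e, f in flows.items())
        for v, (fs, rs) in sides.items():
            s_f = sum(flows[eid] for eid, _ in fs)
            s_r = sum(flows[eid] for eid, _ in rs)
            if s_f == 0 and s_r == 0:
                total += 2 * config.walk_end_penalty
            else:
                total += config.walk_end_penalty * abs(s_f - s_r)
        if best is None or total < best[0] - 1e-12:
            best = (total, flows)
    return best


class TestSolver:
    def test_single_edge_forced_flow_one(self):
        g = make_toy_graph(2, ell=100)
        e = add_toy_edge(g, 0, 1, d=2000, k=20)
        sol = solve_copy_counts(g, n=N, L=L)
        assert sol.edge_flow[e.eid] == 1
        assert all(c == 1 for c in sol.read_copy.values())

    @pytest.mark.parametrize("fixture", ["path", "branch", "parallel", "self_loop"])
    def test_matches_enumeration_on_small_graphs(self, fixture):
        config = FlowConfig()
        if fixture == "path":
            g = make_toy_graph(3, ell=10)
            add_toy_edge(g, 0, 1, d=300, k=31)
            add_toy_edge(g, 1, 2, d=300, k=28)
            n, Lg = 60, 600
        elif fixture == "branch":
            g = make_toy_graph(4, ell=10)
            add_toy_edge(g, 0, 1, d=300, k=30)
            add_toy_edge(g, 1, 2, d=300, k=12)
            add_toy_edge(g, 1, 3, d=300, k=18)
            n, Lg = 100, 1000
        elif fixture == "parallel":
            g = make_toy_graph(2, ell=10)
            add_toy_edge(g, 0, 1, d=300, k=25, seed=1)
            add_toy_edge(g, 0, 1, d=300, k=25, seed=2)
            n, Lg = 100, 600
        else:
            g = make_toy_graph(3, ell=10)
            add_toy_edge(g, 0, 1, d=300, k=30)
            add_toy_edge(g, 1, 1, su=FWD, sv=FWD, d=300, k=55)
            add_toy_edge(g, 1, 2, d=300, k=30)
            n, Lg = 100, 900
        sol = solve_copy_counts(g, n=n, L=Lg, config=config)
        best_obj, best_flows = enumeration_optimum(g, n, Lg, config)
        assert sol.objective == pytest.approx(best_obj, rel=1e-6, abs=1e-6)

    def test_two_copy_repeat_recovered(self):
        ref, ann, rs, truth = simulate_dataset(
            genome_length=6000,
            repeat_spec=[(2, 800, 1.0)],
            coverage=25,
            read_length=100,
            seed=13,
        )
        g = build_graph(rs, 50)
        clean(g)
        assert len(g.edges) <= 8
        n = g.total_reads
        sol = solve_copy_counts(g, n=n, L=6000)
        config = FlowConfig()
        best_obj, best_flows = enumeration_optimum(g, n, 6000, config)
        assert sol.objective == pytest.approx(best_obj, rel=1e-6, abs=1e-6)
        flows = sorted(sol.edge_flow.values())
        assert flows.count(2) == 1  # the repeat edge
        correct = sum(1 for rid, c in sol.read_copy.items() if truth[rid].copy_count == c)
        assert correct / len(truth) >= 0.8

    def test_monotone_in_observed_reads(self):
        def run(k_mid):
            g = make_toy_graph(4, ell=10)
            add_toy_edge(g, 0, 1, d=300, k=30)
            e = add_toy_edge(g, 1, 2, d=300, k=k_mid)
            add_toy_edge(g, 2, 3, d=300, k=30)
            sol = solve_copy_counts(g, n=100, L=900)
            return sol.edge_flow[e.eid]

        assert run(70) >= run(35) >= run(12)
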