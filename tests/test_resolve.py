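"""Flow-guided collapses, self-loop unrolling, mate support, scaffolding."""

from olga.graph import FWD, REV
from olga.resolve import (
    collapse_degree_one_side,
    compute_mate_support,
    merge_disconnected_mates,
    merge_supported_edges,
    remove_simple_self_loop,
)
from olga.stats import InsertSizeModel
from tests.conftest import add_toy_edge, make_toy_graph


class TestCollapse:
    def test_single_in_splits_onto_outs(self):
        g = make_toy_graph(4, ell=10)
        a = add_toy_edge(g, 0, 1, d=300, k=10, flow=3)
        b = add_toy_edge(g, 1, 2, d=300, k=10, flow=2)
        c = add_toy_edge(g, 1, 3, d=300, k=10, flow=1)
        sa, sb, sc = a.seq, b.seq, c.seq
        collapse_degree_one_side(g)
        assert g.degree(1) == 0
        edges = sorted(g.edges.values(), key=lambda e: -e.flow)
        assert [(e.u, e.v, e.flow) for e in edges] == [(0, 2, 2), (0, 3, 1)]
        # strings spliced through the removed vertex read (length 10)
        assert edges[0].seq == sa + sb[10:]
        assert edges[1].seq == sa + sc[10:]

    def test_ambiguous_vertex_untouched(self):
        g = make_toy_graph(5, ell=10)
        add_toy_edge(g, 0, 2, d=300, k=10)
        add_toy_edge(g, 1, 2, d=300, k=10)
        add_toy_edge(g, 2, 3, d=300, k=10)
        add_toy_edge(g, 2, 4, d=300, k=10)
        before = set(g.edges)
        collapse_degree_one_side(g)
        assert set(g.edges) == before

    def test_terminates_on_fixpoint(self):
        g = make_toy_graph(6, ell=10)
        add_toy_edge(g, 0, 1, d=300, k=10, flow=2)
        add_toy_edge(g, 1, 2, d=300, k=10, flow=1)
        add_toy_edge(g, 1, 3, d=300, k=10, flow=1)
        add_toy_edge(g, 2, 4, d=300, k=10, flow=1)
        add_toy_edge(g, 3, 5, d=300, k=10, flow=1)
        collapse_degree_one_side(g)
        collapse_degree_one_side(g)  # idempotent second pass
        assert sorted(tuple(sorted((e.u, e.v))) for e in g.edges.values()) == [
            (0, 4),
            (0, 5),
        ]


class TestSelfLoop:
    def test_tandem_loop_unrolled(self):
        g = make_toy_graph(3, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=10, flow=1)
        loop = add_toy_edge(g, 1, 1, su=FWD, sv=FWD, d=300, k=10, flow=1)
        e2 = add_toy_edge(g, 1, 2, d=300, k=10, flow=1)
        s1, sl, s2 = e1.seq, loop.seq, e2.seq
        remove_simple_self_loop(g)
        (eid,) = g.edges
        e = g.edges[eid]
        assert (e.u, e.v, e.flow) == (0, 2, 1)
        assert e.seq == s1 + sl[10:] + s2[10:]

    def test_loop_inserted_flow_many_times(self):
        g = make_toy_graph(3, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=10, flow=3)
        loop = add_toy_edge(g, 1, 1, su=FWD, sv=FWD, d=300, k=10, flow=2)
        e2 = add_toy_edge(g, 1, 2, d=300, k=10, flow=3)
        s1, sl, s2 = e1.seq, loop.seq, e2.seq
        remove_simple_self_loop(g)
        (eid,) = g.edges
        assert g.edges[eid].seq == s1 + sl[10:] * 2 + s2[10:]

    def test_busy_vertex_untouched(self):
        g = make_toy_graph(4, ell=10)
        add_toy_edge(g, 0, 1, d=300, k=10)
        add_toy_edge(g, 1, 1, su=FWD, sv=FWD, d=300, k=10)
        add_toy_edge(g, 1, 2, d=300, k=10)
        add_toy_edge(g, 1, 3, d=300, k=10)
        before = set(g.edges)
        remove_simple_self_loop(g)
        assert set(g.edges) == before


def ambiguous_cross(g=None):
    """Ambiguous vertex 2 with in-edges from 0,1 and out-edges to 3,4."""
    g = g or make_toy_graph(5, ell=10)
    a = add_toy_edge(g, 0, 2, d=300, k=5, flow=1)
    b = add_toy_edge(g, 1, 2, d=300, k=5, flow=1)
    c = add_toy_edge(g, 2, 3, d=300, k=5, flow=1)
    dd = add_toy_edge(g, 2, 4, d=300, k=5, flow=1)
    return g, a, b, c, dd


def place_pair(g, e1, o1, e2, o2, name):
    e1.reads = sorted(e1.reads + [(f"{name}/1", o1, FWD)], key=lambda t: (t[1], t[0]))
    e2.reads = sorted(e2.reads + [(f"{name}/2", o2, REV)], key=lambda t: (t[1], t[0]))
    g.read_lengths[f"{name}/1"] = g.read_len
    g.read_lengths[f"{name}/2"] = g.read_len
    return (f"{name}/1", f"{name}/2")


class TestMateSupport:
    def test_unique_path_supports_traversal(self):
        g, a, b, c, dd = ambiguous_cross()
        # pair spanning from edge a into edge c: outer distance 200
        pairs = [place_pair(g, a, 250, c, 150, f"m{i}") for i in range(5)]
        model = InsertSizeModel(mu=200, sigma=20)
        supports, votes = compute_mate_support(g, pairs, model)
        key = (2, (a.eid, 1), (c.eid, 0))
        assert supports.get(key) == 5
        assert all(k == key for k in supports)
        assert votes == {}

    def test_two_alternative_paths_give_no_support(self):
        g = make_toy_graph(7, ell=10)
        a = add_toy_edge(g, 0, 2, d=300, k=5)
        b = add_toy_edge(g, 1, 2, d=300, k=5)
        c = add_toy_edge(g, 2, 3, d=300, k=5)
        dd = add_toy_edge(g, 2, 4, d=300, k=5)
        g1 = add_toy_edge(g, 3, 5, d=300, k=5)
        g2 = add_toy_edge(g, 4, 5, d=300, k=5)
        h = add_toy_edge(g, 5, 6, d=300, k=5)
        pairs = [place_pair(g, a, 250, h, 70, f"m{i}") for i in range(5)]
        model = InsertSizeModel(mu=700, sigma=30)
        supports, _votes = compute_mate_support(g, pairs, model)
        assert supports == {}

    def test_disconnected_pair_votes_with_gap_arithmetic(self):
        g = make_toy_graph(4, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=5, flow=1)
        e2 = add_toy_edge(g, 2, 3, d=300, k=5, flow=1)
        # flank distances 120 + 130 with mu=300 imply a 50 N gap
        pairs = [place_pair(g, e1, 180, e2, 120, f"m{i}") for i in range(5)]
        model = InsertSizeModel(mu=300, sigma=30)
        supports, votes = compute_mate_support(g, pairs, model)
        assert supports == {}
        ((key, gaps),) = votes.items()
        assert key == ((e1.eid, 1), (e2.eid, 0))
        assert gaps == [50.0] * 5


class TestMergeSupported:
    def test_flow_splitting_rule(self):
        g, a, b, c, dd = ambiguous_cross()
        a.flow, c.flow = 3, 2
        key = (2, (a.eid, 1), (c.eid, 0))
        merge_supported_edges(g, {key: 7}, min_support=5)
        assert c.eid not in g.edges
        assert g.edges[a.eid].flow == 1
        merged = [e for e in g.edges.values() if (e.u, e.v) == (0, 3)]
        assert len(merged) == 1 and merged[0].flow == 2

    def test_equal_flows_delete_both(self):
        g, a, b, c, dd = ambiguous_cross()
        a.flow, c.flow = 2, 2
        merge_supported_edges(g, {(2, (a.eid, 1), (c.eid, 0)): 9}, min_support=5)
        assert a.eid not in g.edges and c.eid not in g.edges
        merged = [e for e in g.edges.values() if (e.u, e.v) == (0, 3)]
        assert merged[0].flow == 2

    def test_below_threshold_no_merge(self):
        g, a, b, c, dd = ambiguous_cross()
        before = set(g.edges)
        merge_supported_edges(g, {(2, (a.eid, 1), (c.eid, 0)): 4}, min_support=5)
        assert set(g.edges) == before

    def test_tied_conflicting_merges_skipped(self):
        g, a, b, c, dd = ambiguous_cross()
        sup = {
            (2, (a.eid, 1), (c.eid, 0)): 6,
            (2, (a.eid, 1), (dd.eid, 0)): 6,
        }
        before = set(g.edges)
        merge_supported_edges(g, sup, min_support=5)
        assert set(g.edges) == before


class TestScaffolding:
    def test_positive_gap_filled_with_ns(self):
        g = make_toy_graph(4, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=5, flow=1)
        e2 = add_toy_edge(g, 2, 3, d=300, k=5, flow=1)
        votes = {((e1.eid, 1), (e2.eid, 0)): [50.0] * 5}
        s1, s2 = e1.seq, e2.seq
        merge_disconnected_mates(g, votes, min_support=5)
        (eid,) = g.edges
        e = g.edges[eid]
        assert e.seq == s1 + "N" * 50 + s2
        assert e.gaps == [(300, 50)]
        assert (e.u, e.v) == (0, 3)

    def test_confirmed_overlap_joins_without_ns(self):
        g = make_toy_graph(4, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=5, flow=1)
        e2 = add_toy_edge(g, 2, 3, d=300, k=5, flow=1)
        e2.seq = e1.seq[-20:] + e2.seq[20:]  # real 20-base overlap
        votes = {((e1.eid, 1), (e2.eid, 0)): [-20.0] * 5}
        merge_disconnected_mates(g, votes, min_support=5)
        (eid,) = g.edges
        e = g.edges[eid]
        assert "N" not in e.seq
        assert len(e.seq) == 300 + 300 - 20

    def test_zero_flow_short_edge_ineligible(self):
        g = make_toy_graph(4, ell=10)
        e1 = add_toy_edge(g, 0, 1, d=300, k=5, flow=1)
        e2 = add_toy_edge(g, 2, 3, d=80, k=5, flow=0)
        votes = {((e1.eid, 1), (e2.eid, 0)): [50.0] * 5}
        before = set(g.edges)
        merge_disconnected_mates(g, votes, min_support=5)
        assert set(g.edges) == before
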