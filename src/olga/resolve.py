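"""Flow-guided graph resolution, mate-pair support and scaffolding.

Once copy counts are known, vertices with a single edge on one side are
collapsed, simple self-loops (tandem repeats) are unrolled flow-many times,
and remaining ambiguous vertices — more than one edge on both sides — are
resolved with mate pairs: a pair supports the traversal (in-edge, vertex,
out-edge) when every graph path between the mates whose implied outer
distance lies within μ±3σ passes through it.  Sufficiently supported edge
pairs are merged with the flow-splitting rule; mate pairs with no connecting
path at all can still join two edges end-to-end, estimating the gap from μ
and padding it with N's.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .graph import FWD, REV, BidirectedEdge, OverlapGraph, flip
from .simplify import compress_unary_paths, splice_path
from .stats import InsertSizeModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# local flow-guided simplifications
# ---------------------------------------------------------------------------


def _toward(endi: int) -> bool:
    """Traversal direction (forward?) that arrives at the end's vertex."""
    return endi == 1


def _away(endi: int) -> bool:
    """Traversal direction (forward?) that departs from the end's vertex."""
    return endi == 0


def collapse_degree_one_side(g: OverlapGraph) -> OverlapGraph:
    """Collapse every vertex with exactly one edge on one side.

    The single in-edge (s,r) is spliced onto each out-edge (r,r_i); the new
    edge (s,r_i) inherits the out-edge's flow.  Vertices with several edges
    on both sides (ambiguous) or with a self-loop are left untouched.
    Iterates to a fixpoint.
    """
    changed = True
    while changed:
        changed = False
        for v in sorted(list(g.adj)):
            if g.degree(v) == 0:
                continue
            if any(g.edges[eid].u == g.edges[eid].v for eid in g.adj[v]):
                continue
            fwd_side, rev_side = g.sides(v)
            if len(fwd_side) == 0 or len(rev_side) == 0:
                continue
            if len(fwd_side) == 1:
                single, others = fwd_side[0], rev_side
            elif len(rev_side) == 1:
                single, others = rev_side[0], fwd_side
            else:
                continue
            ein, endi_in = single
            new_edges = []
            for eout, endi_out in others:
                merged = splice_path(
                    g, [(ein, _toward(endi_in)), (eout, _away(endi_out))]
                )
                merged.flow = g.edges[eout].flow
                new_edges.append(merged)
            for eid in {ein} | {eo for eo, _ in others}:
                g.remove_edge(eid)
            for e in new_edges:
                g.add_edge(e)
            changed = True
            break
    return g


def remove_simple_self_loop(g: OverlapGraph) -> OverlapGraph:
    """Resolve vertices carrying a self-loop plus exactly two other edges.

    The loop string is inserted loop-flow-many times between the two flank
    edges; the replacement (s,t) edge carries the flank flow (minimum of the
    two, with a warning when they disagree).  Loops whose orientation does
    not allow repeated traversal are left alone.
    """
    for v in sorted(list(g.adj)):
        eids = sorted(set(g.adj.get(v, ())))
        loops = [eid for eid in eids if g.edges[eid].u == g.edges[eid].v]
        others = [eid for eid in eids if g.edges[eid].u != g.edges[eid].v]
        if len(loops) != 1 or len(others) != 2:
            continue
        loop = g.edges[loops[0]]
        if loop.u != v:
            continue
        e1id, e2id = others
        # orient e1 toward v
        e1_end = 1 if g.edges[e1id].v == v else 0
        _, _, _, arr = g.edge_endpoints(e1id, _toward(e1_end))
        # loop must depart v with `arr` and return with `arr` to be repeatable
        if loop.su == arr and loop.sv == arr:
            loop_dir = True
        elif flip(loop.sv) == arr and flip(loop.su) == arr:
            loop_dir = False
        else:
            logger.info("self-loop at vertex %d not consistently traversable; skipped", v)
            continue
        e2_end = 0 if g.edges[e2id].u == v else 1
        tail2, _, dep2, _ = g.edge_endpoints(e2id, _away(e2_end))
        if dep2 != arr:
            logger.info("flank orientations at self-loop vertex %d mismatch; skipped", v)
            continue
        phi = loop.flow
        f1, f2 = g.edges[e1id].flow, g.edges[e2id].flow
        if f1 != f2:
            logger.warning(
                "self-loop flanks at vertex %d carry unequal flow (%d vs %d); using min",
                v,
                f1,
                f2,
            )
        chain = [(e1id, _toward(e1_end))] + [(loops[0], loop_dir)] * phi + [
            (e2id, _away(e2_end))
        ]
        merged = splice_path(g, chain)
        merged.flow = min(f1, f2)
        for eid in [e1id, e2id, loops[0]]:
            g.remove_edge(eid)
        g.add_edge(merged)
    return g


# ---------------------------------------------------------------------------
# mate-pair support
# ---------------------------------------------------------------------------


@dataclass
class MateSupport:
    """Support count for routing vertex r from one in-edge end to one
    out-edge end, accumulated over mate pairs."""

    vertex: int
    in_end: Tuple[int, int]  # (eid, end index at r)
    out_end: Tuple[int, int]
    support: int = 0


def placement_index(g: OverlapGraph) -> Dict[str, List[Tuple[int, int, int]]]:
    idx: Dict[str, List[Tuple[int, int, int]]] = defaultdict(list)
    for eid in g.edges:
        for rid, off, s in g.edge_reads(eid):
            idx[rid].append((eid, off, s))
    return dict(idx)


def _orient_placement(g, eid, off, s, forward, rlen):
    if forward:
        return off, s
    d = g.edge_len(eid)
    return d - off - rlen, flip(s)


def _is_ambiguous(g, v) -> bool:
    f, r = g.sides(v)
    return len(f) > 1 and len(r) > 1


@dataclass
class PairPathResult:
    paths: List[frozenset]  # sets of traversal triples per in-range path
    disconnected: Optional[Tuple] = None  # scaffolding candidate record
    capped: bool = False


def _enumerate_pair_paths(g, p1, p2, rlen1, rlen2, lo, hi, path_cap, expand_cap=20000):
    """All walks from mate 1 to mate 2 whose implied outer distance is within
    [lo, hi].  Returns the per-path sets of (vertex, in-end, out-end) triples,
    or the flank-distance record when no such walk exists."""
    e1, o1, s1 = p1
    dir1 = s1 == FWD  # orient the start edge so mate 1 reads forward
    o1p, _ = _orient_placement(g, e1, o1, s1, dir1, rlen1)
    pos0 = o1p
    paths: List[frozenset] = []
    expansions = 0
    capped = False

    stack = [(e1, dir1, 0, frozenset())]
    while stack:
        eid, fwd, base, triples = stack.pop()
        expansions += 1
        if expansions > expand_cap or len(paths) > path_cap:
            capped = True
            break
        d = g.edge_len(eid)
        # mate 2 on this edge, reverse strand in walk coordinates?
        for (e2, o2, s2) in ([p2] if p2[0] == eid else []):
            o2p, s2p = _orient_placement(g, eid, o2, s2, fwd, rlen2)
            if s2p == REV:
                dist = base + o2p + rlen2 - pos0
                if lo <= dist <= hi:
                    paths.append(triples)
        # extend
        tail, head, dep, arr = g.edge_endpoints(eid, fwd)
        new_base = base + d - g.vlen(head)
        if new_base + g.vlen(head) - pos0 > hi:
            continue
        fwd_side, rev_side = g.sides(head)
        in_end = (eid, 1 if fwd else 0)
        for eid2, endi2 in fwd_side if arr == FWD else rev_side:
            if (eid2, endi2) == in_end:
                continue
            t = (head, in_end, (eid2, endi2))
            stack.append((eid2, _away(endi2), new_base, triples | {t}))

    if capped:
        return PairPathResult([], None, True)
    if paths:
        return PairPathResult(paths)
    # no connecting path: record flank distances for scaffolding
    d1 = g.edge_len(e1)
    a1 = d1 - pos0
    exit1 = (e1, 1 if dir1 else 0)
    e2, o2, s2 = p2
    dir2 = s2 == REV  # orient the far edge so mate 2 reads reverse
    o2p, _ = _orient_placement(g, e2, o2, s2, dir2, rlen2)
    a2 = o2p + rlen2
    entry2 = (e2, 0 if dir2 else 1)
    return PairPathResult([], (exit1, entry2, a1, a2))


def compute_mate_support(
    g: OverlapGraph,
    mate_pairs: Iterable[Tuple[str, str]],
    insert_model: InsertSizeModel,
    path_cap: int = 500,
):
    """Mate-pair support for ambiguous-vertex traversals.

    Returns ``(supports, scaffold_votes)``: ``supports`` maps
    (vertex, in-end, out-end) to the number of pairs all of whose in-range
    paths use that traversal; ``scaffold_votes`` maps ordered edge-end pairs
    to the gap estimates contributed by pairs with no connecting path.
    """
    mu, sigma = insert_model.mu, insert_model.sigma
    lo, hi = mu - 3 * sigma, mu + 3 * sigma
    idx = placement_index(g)
    supports: Dict[Tuple, int] = defaultdict(int)
    scaffold_votes: Dict[Tuple, List[float]] = defaultdict(list)
    skipped = 0
    for r1, r2 in mate_pairs:
        pl1, pl2 = idx.get(r1), idx.get(r2)
        if not pl1 or not pl2 or len(pl1) > 1 or len(pl2) > 1:
            skipped += 1
            continue
        rlen1 = g.read_lengths.get(r1, g.read_len)
        rlen2 = g.read_lengths.get(r2, g.read_len)
        res = _enumerate_pair_paths(g, pl1[0], pl2[0], rlen1, rlen2, lo, hi, path_cap)
        if res.capped:
            skipped += 1
            continue
        if res.paths:
            common = frozenset.intersection(*res.paths)
            for (v, in_end, out_end) in common:
                if _is_ambiguous(g, v):
                    supports[(v, in_end, out_end)] += 1
        elif res.disconnected is not None:
            exit1, entry2, a1, a2 = res.disconnected
            if exit1[0] != entry2[0] and a1 + a2 < hi:
                scaffold_votes[(exit1, entry2)].append(mu - (a1 + a2))
    if skipped:
        logger.info("mate support: %d pairs unusable (unplaced/ambiguous/capped)", skipped)
    return dict(supports), dict(scaffold_votes)


def merge_supported_edges(
    g: OverlapGraph, supports: Dict[Tuple, int], min_support: int = 5
) -> OverlapGraph:
    """Merge edge pairs around ambiguous vertices with support >= min_support.

    The merged (s,t) edge takes the minimum flow of the two; the lower-flow
    constituent is deleted and the other's flow decreased by the minimum
    (both deleted on a tie).  Merges are applied in descending support order;
    equal-support merges competing for the same edge end are all skipped.
    """
    entries = [(sup, key) for key, sup in supports.items() if sup >= min_support]
    entries.sort(key=lambda t: (-t[0], t[1]))
    # equal-support conflicts: skip every contender for a contested end
    contested = set()
    by_sup: Dict[int, List] = defaultdict(list)
    for sup, key in entries:
        by_sup[sup].append(key)
    for sup, keys in by_sup.items():
        usage = defaultdict(int)
        for (_v, in_end, out_end) in keys:
            usage[in_end] += 1
            usage[out_end] += 1
        for key in keys:
            if usage[key[1]] > 1 or usage[key[2]] > 1:
                contested.add((sup, key))

    for sup, key in entries:
        if (sup, key) in contested:
            logger.info("skipping tied conflicting merge at vertex %d", key[0])
            continue
        v, (ea, enda), (eb, endb) = key
        if ea not in g.edges or eb not in g.edges:
            continue
        fa, fb = g.edges[ea].flow, g.edges[eb].flow
        fmin = min(fa, fb)
        if fmin < 1:
            continue
        merged = splice_path(g, [(ea, _toward(enda)), (eb, _away(endb))])
        merged.flow = fmin
        if fa == fb:
            g.remove_edge(ea)
            g.remove_edge(eb)
        elif fa < fb:
            g.remove_edge(ea)
            g.edges[eb].flow = fb - fmin
        else:
            g.remove_edge(eb)
            g.edges[ea].flow = fa - fmin
        g.add_edge(merged)
    return g


def merge_disconnected_mates(
    g: OverlapGraph,
    scaffold_votes: Dict[Tuple, List[float]],
    min_support: int = 5,
    min_eligible_len: int = 100,
) -> OverlapGraph:
    """Join edge pairs supported by mates with no connecting path.

    Only edges with non-zero flow or at least ``min_eligible_len`` bases are
    eligible.  The gap is the mean of μ − (flank distances); positive gaps are
    filled with N's, non-positive gaps are checked for a real sequence overlap
    of the flanks and otherwise joined seamlessly.
    """
    entries = sorted(scaffold_votes.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    used_ends = set()
    for (exit1, entry2), gaps in entries:
        if len(gaps) < min_support:
            continue
        (e1, end1), (e2, end2) = exit1, entry2
        if e1 not in g.edges or e2 not in g.edges or e1 == e2:
            continue
        if (e1, end1) in used_ends or (e2, end2) in used_ends:
            continue

        def eligible(eid):
            return g.edges[eid].flow > 0 or g.edge_len(eid) >= min_eligible_len

        if not (eligible(e1) and eligible(e2)):
            continue
        gap = int(round(sum(gaps) / len(gaps)))
        fwd1 = end1 == 1  # orient e1 so the supported end is its head
        fwd2 = end2 == 0  # orient e2 so the supported end is its tail
        s1 = g.edge_seq(e1, fwd1)
        s2 = g.edge_seq(e2, fwd2)
        tail, _, dep1, _ = g.edge_endpoints(e1, fwd1)
        _, head, _, arr2 = g.edge_endpoints(e2, fwd2)
        gap_spans = list(g.edge_gaps(e1, fwd1))
        # a real sequence overlap of the flanks (shorter than M, else the
        # edges would already be connected) takes precedence over the
        # insert-based gap estimate
        max_ov = min(len(s1) - 1, len(s2) - 1, max(g.M - 1, -gap + 50))
        ov_found = 0
        for ov in range(max_ov, 9, -1):
            if s1[-ov:] == s2[:ov]:
                ov_found = ov
                break
        if ov_found:
            seq = s1 + s2[ov_found:]
            shift = len(s1) - ov_found
        elif gap > 0:
            seq = s1 + "N" * gap + s2
            shift = len(s1) + gap
            gap_spans.append((len(s1), gap))
        else:
            logger.info(
                "estimated overlap of %d bases not confirmed; joining without gap", -gap
            )
            seq = s1 + s2
            shift = len(s1)
        reads = list(g.edge_reads(e1, fwd1))
        for rid, off, s in g.edge_reads(e2, fwd2):
            reads.append((rid, off + shift, s))
        for st, ln in g.edge_gaps(e2, fwd2):
            gap_spans.append((st + shift, ln))
        f1, f2 = g.edges[e1].flow, g.edges[e2].flow
        merged = BidirectedEdge(
            -1,
            tail,
            head,
            dep1,
            arr2,
            seq=seq,
            reads=sorted(set(reads), key=lambda t: (t[1], t[0], t[2])),
            composite=True,
            gaps=sorted(gap_spans),
        )
        merged.flow = max(1, min(f1 if f1 else 1, f2 if f2 else 1))
        g.remove_edge(e1)
        g.remove_edge(e2)
        g.add_edge(merged)
        used_ends.add(exit1)
        used_ends.add(entry2)
    return g


def resolve_graph(
    g: OverlapGraph,
    mate_pairs,
    insert_model: Optional[InsertSizeModel],
    min_support: int = 5,
    path_cap: int = 500,
) -> OverlapGraph:
    """Full resolution pass: local collapses, self-loop unrolling, then
    mate-supported merging (when mate pairs and an insert model exist)."""
    collapse_degree_one_side(g)
    remove_simple_self_loop(g)
    compress_unary_paths(g)
    if insert_model is not None and mate_pairs:
        supports, _votes = compute_mate_support(g, mate_pairs, insert_model, path_cap)
        merge_supported_edges(g, supports, min_support)
        compress_unary_paths(g)
    return g
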