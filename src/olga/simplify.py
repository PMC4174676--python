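"""Graph cleaning: unary-path compression, dead-end removal, bubble popping.

Composite-edge compression replaces every maximal path of indegree-1/
outdegree-1 vertices with a single edge whose merged string and read
placements are stored explicitly.  Dead ends (tips) are short, poorly
covered edges hanging off the graph, the typical footprint of residual
sequencing errors; bubbles are pairs of parallel edges with highly similar
strings where the weakly covered branch is an error artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import edlib

from .graph import FWD, BidirectedEdge, OverlapGraph, flip

logger = logging.getLogger(__name__)


@dataclass
class CleaningParams:
    """Thresholds for tip and bubble removal.

    The read-count threshold below which a dead-end edge is discarded and the
    similarity/coverage-ratio cutoffs for bubbles are experimentally chosen
    defaults (the underlying model gives no canonical value); the tip length
    cap, in units of the read length, keeps long genuine dead ends safe.
    """

    tip_min_reads: int = 5
    tip_len_factor: float = 3.0
    bubble_identity_min: float = 0.95
    bubble_coverage_ratio_min: float = 3.0
    max_rounds: int = 10

    def __post_init__(self):
        if self.tip_min_reads < 1:
            raise ValueError("tip_min_reads >= 1 required")
        if not (0 < self.bubble_identity_min <= 1):
            raise ValueError("bubble_identity_min in (0, 1] required")
        if self.bubble_coverage_ratio_min < 1:
            raise ValueError("bubble_coverage_ratio_min >= 1 required")


def is_unary(g: OverlapGraph, x: int) -> bool:
    """True when x has exactly one edge end on each side and is not a bare
    self-loop vertex, i.e. a walk through x is forced."""
    fwd_side, rev_side = g.sides(x)
    if len(fwd_side) != 1 or len(rev_side) != 1:
        return False
    if fwd_side[0][0] == rev_side[0][0]:
        e = g.edges[fwd_side[0][0]]
        if e.u == e.v:
            return False
    return True


def splice_path(g: OverlapGraph, chain: List[Tuple[int, bool]]) -> BidirectedEdge:
    """Merge a consistent chain of edges into one edge record (not inserted).

    The merged string dedups the shared vertex read at every junction; read
    placements are re-based onto the merged string and deduplicated; N-gap
    spans are carried over.
    """
    eid0, fwd0 = chain[0]
    tail, head, dep0, arr = g.edge_endpoints(eid0, fwd0)
    seq = g.edge_seq(eid0, fwd0)
    reads = list(g.edge_reads(eid0, fwd0))
    gaps = list(g.edge_gaps(eid0, fwd0))
    cur_head, cur_arr = head, arr
    for eid, fwdi in chain[1:]:
        t2, h2, d2, a2 = g.edge_endpoints(eid, fwdi)
        if t2 != cur_head or d2 != cur_arr:
            raise ValueError("inconsistent chain: orientation mismatch at internal vertex")
        base = len(seq) - g.vlen(cur_head)
        seq = seq + g.edge_seq(eid, fwdi)[g.vlen(cur_head) :]
        for rid, off, s in g.edge_reads(eid, fwdi):
            reads.append((rid, off + base, s))
        for st, ln in g.edge_gaps(eid, fwdi):
            gaps.append((st + base, ln))
        cur_head, cur_arr = h2, a2
    reads = sorted(set(reads), key=lambda t: (t[1], t[0], t[2]))
    return BidirectedEdge(
        -1,
        tail,
        cur_head,
        dep0,
        cur_arr,
        seq=seq,
        reads=reads,
        composite=len(chain) > 1,
        gaps=sorted(set(gaps)),
    )


def _walk_chain(g: OverlapGraph, eid: int, forward: bool, stop_vertex=None):
    """Extend a chain through unary vertices starting from one edge traversal."""
    chain = [(eid, forward)]
    used = {eid}
    tail, head, dep, arr = g.edge_endpoints(eid, forward)
    start = tail if stop_vertex is None else stop_vertex
    while head != start and is_unary(g, head):
        fwd_side, rev_side = g.sides(head)
        (eid2, endi2) = (fwd_side if arr == FWD else rev_side)[0]
        if eid2 in used and g.edges[eid2].u == g.edges[eid2].v:
            break
        forward2 = endi2 == 0
        chain.append((eid2, forward2))
        used.add(eid2)
        _, head, _, arr = g.edge_endpoints(eid2, forward2)
    return chain


def compress_unary_paths(g: OverlapGraph) -> OverlapGraph:
    """Compress every maximal unary path to a single composite edge.

    Idempotent: a second application leaves the graph unchanged.  Pure cycles
    of unary vertices collapse to a composite self-loop on their smallest
    vertex.
    """
    visited = set()
    new_edges: List[BidirectedEdge] = []
    removed: List[int] = []

    anchors = [x for x in sorted(g.adj) if g.degree(x) > 0 and not is_unary(g, x)]
    for a in anchors:
        fwd_side, rev_side = g.sides(a)
        for eid, endi in fwd_side + rev_side:
            if eid in visited:
                continue
            chain = _walk_chain(g, eid, endi == 0, stop_vertex=a)
            for ceid, _ in chain:
                visited.add(ceid)
            if len(chain) > 1:
                new_edges.append(splice_path(g, chain))
                removed.extend(ceid for ceid, _ in chain)

    # pure unary cycles: every remaining unvisited edge has unary endpoints
    for eid in sorted(set(g.edges) - visited):
        if eid in visited:
            continue
        e = g.edges[eid]
        if not (is_unary(g, e.u) and is_unary(g, e.v)):
            continue
        chain = _walk_chain(g, eid, True, stop_vertex=e.u)
        cycle_edges = {ceid for ceid, _ in chain}
        if any(c in visited for c in cycle_edges):
            continue
        visited |= cycle_edges
        if len(chain) > 1:
            new_edges.append(splice_path(g, chain))
            removed.extend(cycle_edges)

    for eid in removed:
        g.remove_edge(eid)
    for e in new_edges:
        g.add_edge(e)
    if removed:
        logger.info("compressed %d edges into %d composite edges", len(removed), len(new_edges))
    return g


def remove_dead_ends(g: OverlapGraph, params: CleaningParams) -> OverlapGraph:
    """Iteratively delete tips: edges with a degree-1 endpoint, fewer than
    ``tip_min_reads`` reads and length at most ``tip_len_factor``·ℓ, then
    re-compress, until a fixpoint."""
    cap = params.tip_len_factor * g.read_len
    for _ in range(params.max_rounds):
        tips = []
        for eid, e in g.edges.items():
            if g.degree(e.u) == 1 or g.degree(e.v) == 1:
                if g.k(eid) < params.tip_min_reads and g.edge_len(eid) <= cap:
                    tips.append(eid)
        if not tips:
            break
        lost = sum(g.k(eid) for eid in tips)
        for eid in tips:
            g.remove_edge(eid)
        logger.info("removed %d dead-end edges (%d read placements)", len(tips), lost)
        compress_unary_paths(g)
    return g


def _bubble_identity(s1: str, s2: str) -> float:
    res = edlib.align(s1, s2, task="distance", mode="NW")
    dist = res["editDistance"]
    return 1.0 - dist / max(len(s1), len(s2))


def _parallel_signature(g: OverlapGraph, eid: int):
    e = g.edges[eid]
    if e.u <= e.v:
        return (e.u, e.v, e.su, e.sv)
    return (e.v, e.u, flip(e.sv), flip(e.su))


def pop_bubbles(g: OverlapGraph, params: CleaningParams) -> OverlapGraph:
    """Remove the weak branch of two-edge bubbles.

    A bubble is a pair of parallel edges between the same vertex pair with the
    same strand signature whose strings align at identity >=
    ``bubble_identity_min`` while the read counts differ by a factor >=
    ``bubble_coverage_ratio_min``; the lower-coverage branch is deleted and
    the graph re-compressed.
    """
    groups = {}
    for eid, e in g.edges.items():
        if e.u == e.v:
            continue
        groups.setdefault(_parallel_signature(g, eid), []).append(eid)
    doomed = []
    for sig, eids in sorted(groups.items()):
        if len(eids) != 2:
            continue
        e1, e2 = eids
        k1, k2 = g.k(e1), g.k(e2)
        lo, hi = (e1, e2) if k1 <= k2 else (e2, e1)
        klo, khi = min(k1, k2), max(k1, k2)
        if klo == 0 or khi / klo < params.bubble_coverage_ratio_min:
            continue
        s1 = g.edge_seq(e1, g.edges[e1].u == sig[0])
        s2 = g.edge_seq(e2, g.edges[e2].u == sig[0])
        if _bubble_identity(s1, s2) >= params.bubble_identity_min:
            doomed.append(lo)
    for eid in doomed:
        logger.info("popped bubble edge %d (k=%d)", eid, g.k(eid))
        g.remove_edge(eid)
    if doomed:
        compress_unary_paths(g)
    return g


def clean(g: OverlapGraph, params: CleaningParams | None = None) -> OverlapGraph:
    """Full cleaning schedule: compress, then alternate tip removal and bubble
    popping (each followed by re-compression) to a fixpoint with a round cap."""
    params = params or CleaningParams()
    compress_unary_paths(g)
    for _ in range(params.max_rounds):
        before = set(g.edges)
        remove_dead_ends(g, params)
        pop_bubbles(g, params)
        if set(g.edges) == before:
            break
    return g
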