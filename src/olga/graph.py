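"""Bidirected string-overlap graph construction and transitive reduction.

Vertices are (deduplicated) reads; a read and its reverse complement share one
vertex.  An edge records a suffix–prefix overlap of length >= M between two
reads, in either strand combination, and carries an orientation at each end.

Internal strand convention
--------------------------
Strands are 0 (forward) and 1 (reverse complement).  An edge stores the strand
pair ``(su, sv)`` of its canonical u→v traversal: the overlap is

    suffix of strand(u, su)  ==  prefix of strand(v, sv),

and the edge string for that traversal is ``strand(u,su) + strand(v,sv)[olen:]``.
Traversing v→u uses strands ``(1-sv, 1-su)`` and spells the reverse complement.
A walk is consistent when it leaves each internal vertex on the same strand it
arrived with.  The per-end orientations of the bidirected-graph literature map
onto this as: orientation at u is "out" iff su is forward, orientation at v is
"out" iff sv is reverse — same-strand overlaps give (out,in)/(in,out) and the
two opposite-strand types give (out,out) and (in,in).
"""

from __future__ import annotations

import heapq
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .seqio import KEY_CAPACITY, ReadSet, encode_2bit, reverse_complement, roll_2bit

logger = logging.getLogger(__name__)

FWD, REV = 0, 1

#: end orientations of the bidirected-graph formalism
OUT, IN = "out", "in"


def flip(s: int) -> int:
    return 1 - s


# ---------------------------------------------------------------------------
# overlap detection
# ---------------------------------------------------------------------------


def build_affix_hash(seqs: Sequence[str], M: int) -> Dict[int, List[Tuple[int, str, int]]]:
    """Hash every length-min{32,M} prefix and suffix of every sequence and its
    reverse complement.

    Returns a table mapping the 2-bit packed key to entries
    ``(index, kind, strand)`` with ``kind`` in {"prefix", "suffix"}.  When a
    sequence's prefix equals its suffix (window == whole read) the duplicate
    entry is skipped, so each (read, strand) contributes at most two entries.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    shortest = min((len(s) for s in seqs), default=0)
    if seqs and M > shortest:
        raise ValueError("minimum overlap exceeds read length")
    w = min(KEY_CAPACITY, M)
    table: Dict[int, List[Tuple[int, str, int]]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for strand, t in ((FWD, s), (REV, reverse_complement(s))):
            pk = encode_2bit(t[:w])
            table[pk].append((i, "prefix", strand))
            if t[-w:] != t[:w]:
                table[encode_2bit(t[-w:])].append((i, "suffix", strand))
    return dict(table)


def _canonical_overlap(a: int, sa: int, b: int, sb: int, o: int):
    """Canonical key for the overlap event suffix(strand(a,sa)) == prefix(strand(b,sb))."""
    if a <= b:
        return (a, b, sa, sb), o
    return (b, a, flip(sb), flip(sa)), o


def find_overlaps(seqs: Sequence[str], M: int):
    """All maximal suffix–prefix overlaps of length >= M between distinct
    sequences, over both strands.

    Returns ``(overlaps, containments)`` where ``overlaps`` maps the canonical
    key ``(u, v, su, sv)`` (u < v) to the maximal overlap length, and
    ``containments`` is a set of ``(inner, host, offset, strand)`` records for
    sequences that occur as a substring of another (offset within the host's
    forward string; strand of the inner sequence relative to it).

    Every hash hit is verified by full character comparison before emission.
    """
    w = min(KEY_CAPACITY, M)
    table = build_affix_hash(seqs, M)
    rcs = [reverse_complement(s) for s in seqs]

    def strand_seq(j: int, s: int) -> str:
        return seqs[j] if s == FWD else rcs[j]

    overlaps: Dict[Tuple[int, int, int, int], int] = {}
    contain: Set[Tuple[int, int, int, int]] = set()

    def emit(a, sa, b, sb, o):
        if a == b:
            return
        key, o = _canonical_overlap(a, sa, b, sb, o)
        if overlaps.get(key, 0) < o:
            overlaps[key] = o

    def emit_containment(inner, host, off, strand):
        # record relative to the host's *forward* string
        if inner == host:
            return
        contain.add((inner, host, off, strand))

    for i, x in enumerate(seqs):
        lx = len(x)
        key = encode_2bit(x[:w])
        for p in range(lx - w + 1):
            if p > 0:
                key = roll_2bit(key, x[p + w - 1], w)
            for j, kind, strand in table.get(key, ()):
                t = strand_seq(j, strand)
                lt = len(t)
                if kind == "prefix":
                    if p + lt <= lx:
                        # t possibly contained in x at offset p
                        if x[p : p + lt] == t:
                            emit_containment(j, i, p, strand)
                        continue
                    o = lx - p
                    if o >= M and x[p:] == t[:o]:
                        emit(i, FWD, j, strand, o)
                else:  # suffix of t ends at window end
                    o = p + w
                    if o >= lt:
                        start = o - lt
                        if x[start:o] == t:
                            emit_containment(j, i, start, strand)
                        continue
                    if o >= M and o < lx and x[:o] == t[lt - o :]:
                        emit(j, strand, i, FWD, o)
                    elif o == lx and lt > lx and x == t[lt - o :]:
                        # x itself contained at the end of t; express in t's fwd coords
                        if strand == FWD:
                            emit_containment(i, j, lt - o, FWD)
                        else:
                            emit_containment(i, j, 0, REV)
    return overlaps, contain


def find_overlaps_bruteforce(seqs: Sequence[str], M: int):
    """O(n²·ℓ) all-pairs oracle: maximal suffix–prefix overlap per ordered
    pair and strand combination, canonicalized like :func:`find_overlaps`.
    Containments are excluded (reported separately by the fast path)."""
    rcs = [reverse_complement(s) for s in seqs]

    def strand_seq(j, s):
        return seqs[j] if s == FWD else rcs[j]

    overlaps: Dict[Tuple[int, int, int, int], int] = {}
    n = len(seqs)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            for sa in (FWD, REV):
                for sb in (FWD, REV):
                    sA, sB = strand_seq(a, sa), strand_seq(b, sb)
                    hi = min(len(sA), len(sB)) - 1
                    for o in range(hi, M - 1, -1):
                        if sA[-o:] == sB[:o]:
                            key, oo = _canonical_overlap(a, sa, b, sb, o)
                            if overlaps.get(key, 0) < oo:
                                overlaps[key] = oo
                            break
    return overlaps


# ---------------------------------------------------------------------------
# transitive reduction (record level)
# ---------------------------------------------------------------------------
#
# An overlap record is (u, v, su, sv, olen) keyed by (u, v, su, sv).  An edge e
# is transitive iff some consistent two-edge path through a third vertex spells
# exactly the same string.  With exact overlaps this is equivalent to a purely
# combinatorial condition on strands and overlap lengths:
#     o_e == o_1 + o_2 - len(w)
# for a consistent path u -(o1)-> w -(o2)-> x matching e's strands; the string
# identity then follows from the two constituent overlap identities.


def _ends_of(key, o):
    """The two directed ends of an overlap record: (from, dep, to, arr, o)."""
    u, v, su, sv = key
    return (
        (u, su, v, sv, o),
        (v, flip(sv), u, flip(su), o),
    )


class _EndIndex:
    """Per-vertex directed-end lists for a record set."""

    def __init__(self, records: Dict[Tuple, int]):
        self.ends: Dict[int, List[Tuple]] = defaultdict(list)
        for key, o in records.items():
            for frm, dep, to, arr, oo in _ends_of(key, o):
                self.ends[frm].append((to, dep, arr, oo, key))

    def add(self, key, o):
        for frm, dep, to, arr, oo in _ends_of(key, o):
            self.ends[frm].append((to, dep, arr, oo, key))

    def remove(self, key, o):
        for frm, dep, to, arr, oo in _ends_of(key, o):
            self.ends[frm].remove((to, dep, arr, oo, key))


def _mark_transitive_at(v, end_index: _EndIndex, lengths, marked: set, fuzz: int = 0):
    """Mark every edge incident to v certified transitive by a two-edge path."""
    mine = end_index.ends.get(v, ())
    index = {}
    for (x, dep, arr, o, key) in mine:
        index[(x, dep, arr, o)] = key
    for (w, s, a, o1, k1) in mine:
        lw = lengths[w]
        for (x, dep2, b, o2, k2) in end_index.ends.get(w, ()):
            if dep2 != a or k2 == k1:
                continue
            o_req = o1 + o2 - lw
            if o_req < 1:
                continue
            for delta in range(-fuzz, fuzz + 1):
                k3 = index.get((x, s, b, o_req + delta))
                if k3 is not None and k3 not in (k1, k2):
                    marked.add(k3)
    return marked


def reduce_records_full(records: Dict[Tuple, int], lengths, fuzz: int = 0):
    """Full-graph transitive reduction oracle: build everything, then mark and
    delete.  Returns the surviving record dict and the marked key set."""
    idx = _EndIndex(records)
    marked: set = set()
    for v in list(idx.ends):
        _mark_transitive_at(v, idx, lengths, marked, fuzz)
    kept = {k: o for k, o in records.items() if k not in marked}
    return kept, marked


class IncrementalReducer:
    """Space-efficient construction: insert edges one at a time (grouped by
    their smaller endpoint, ascending) and reduce as the graph is built.

    A vertex v is reduced once every edge incident to v or to a neighbour of v
    has been inserted.  Edges marked transitive are physically deleted once all
    vertices whose reduction they could influence — the endpoints and every
    neighbour of either endpoint — have been reduced.  ``peak_live`` records
    the maximum number of simultaneously retained edges, which never exceeds
    the full (unreduced) graph size.
    """

    def __init__(self, lengths: Sequence[int], neighbors: Dict[int, Set[int]], fuzz: int = 0):
        self.lengths = lengths
        self.neighbors = neighbors
        self.fuzz = fuzz
        self.idx = _EndIndex({})
        self.live: Dict[Tuple, int] = {}
        self.marked: set = set()
        self.deleted: set = set()
        self.peak_live = 0
        self._batch = -1
        # h(v): insertion batch by which every edge of v has arrived
        self._h = {v: max(neighbors.get(v, {v}) | {v}) for v in range(len(lengths))}
        self._pending = []  # (readiness batch, vertex)
        for v in range(len(lengths)):
            heapq.heappush(self._pending, (self._h[v], v))
        self._processed: Set[int] = set()
        self._delete_bucket: Dict[int, List[Tuple]] = defaultdict(list)
        self._proc_frontier = -1

    def insert_edge(self, key, o) -> None:
        b = min(key[0], key[1])
        if b < self._batch:
            raise ValueError("edges must arrive grouped by smaller endpoint, ascending")
        if b > self._batch:
            self._advance(b - 1)
            self._batch = b
        self.live[key] = o
        self.idx.add(key, o)
        self.peak_live = max(self.peak_live, len(self.live))
        u, z = key[0], key[1]
        g = max(self._h[u], self._h[z])
        self._delete_bucket[g].append(key)

    def _advance(self, arrival_frontier: int) -> None:
        while self._pending and self._pending[0][0] <= arrival_frontier:
            _, v = heapq.heappop(self._pending)
            _mark_transitive_at(v, self.idx, self.lengths, self.marked, self.fuzz)
            self._processed.add(v)
            # advance the contiguous processed frontier and flush deletions
            while (self._proc_frontier + 1) in self._processed:
                self._proc_frontier += 1
                for key in self._delete_bucket.pop(self._proc_frontier, ()):
                    if key in self.marked and key in self.live:
                        self.idx.remove(key, self.live[key])
                        del self.live[key]
                        self.deleted.add(key)

    def finalize(self) -> Dict[Tuple, int]:
        self._advance(len(self.lengths))
        for key in list(self.live):
            if key in self.marked:
                del self.live[key]
        return dict(self.live)


def reduce_records_incremental(records: Dict[Tuple, int], lengths, fuzz: int = 0):
    neighbors: Dict[int, Set[int]] = defaultdict(set)
    for (u, v, su, sv) in records:
        neighbors[u].add(v)
        neighbors[v].add(u)
    red = IncrementalReducer(lengths, neighbors, fuzz)
    for key in sorted(records, key=lambda k: (min(k[0], k[1]), k)):
        red.insert_edge(key, records[key])
    kept = red.finalize()
    return kept, red


# ---------------------------------------------------------------------------
# graph data structure
# ---------------------------------------------------------------------------


@dataclass
class BidirectedEdge:
    """An overlap-derived edge of the bidirected graph.

    ``olen`` and implicit strings apply to simple edges; composite edges
    (products of path compression) carry ``seq`` and explicit read placements
    ``(read_id, offset, strand)`` sorted by offset on the u→v string.  ``flow``
    is the copy count assigned by the min-cost-flow stage; ``lb``/``ub`` its
    capacity bounds (``ub=None`` means unbounded).  ``gaps`` lists (start,
    length) spans of N's introduced by scaffolding.
    """

    eid: int
    u: int
    v: int
    su: int
    sv: int
    olen: int = 0
    seq: Optional[str] = None
    reads: Optional[List[Tuple[str, int, int]]] = None
    composite: bool = False
    flow: int = 0
    lb: int = 0
    ub: Optional[int] = None
    gaps: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def orient_u(self) -> str:
        return OUT if self.su == FWD else IN

    @property
    def orient_v(self) -> str:
        return OUT if self.sv == REV else IN

    def ends(self):
        """[(vertex, departure strand), ...] for the two edge ends."""
        return [(self.u, self.su), (self.v, flip(self.sv))]


class OverlapGraph:
    """Mutable bidirected multigraph over reads, through all assembly stages."""

    def __init__(self, M: int, read_len: int):
        self.M = M
        self.read_len = read_len
        self.vseq: List[str] = []
        self.members: List[List[Tuple[str, int]]] = []  # (read_id, flip)
        self.host_contents: List[List[Tuple[int, int, int]]] = []  # (vertex, off, flip)
        self.contained_in: List[Optional[int]] = []
        self.edges: Dict[int, BidirectedEdge] = {}
        self.adj: Dict[int, List[int]] = defaultdict(list)
        self.read_lengths: Dict[str, int] = {}
        self.construction_peak_edges = 0
        self.full_overlap_count = 0
        self._next_eid = 0

    # -- vertices -----------------------------------------------------------

    def add_vertex(self, seq: str) -> int:
        self.vseq.append(seq)
        self.members.append([])
        self.host_contents.append([])
        self.contained_in.append(None)
        return len(self.vseq) - 1

    def vlen(self, x: int) -> int:
        return len(self.vseq[x])

    def vstrand(self, x: int, s: int) -> str:
        return self.vseq[x] if s == FWD else reverse_complement(self.vseq[x])

    @property
    def n_vertices(self) -> int:
        return len(self.vseq)

    @property
    def total_reads(self) -> int:
        return sum(len(m) for m in self.members)

    def unit_placements(self, x: int, strand: int, base: int):
        """Placements of every read unit of vertex x (members plus contained
        reads) when the vertex read is laid at ``base`` with ``strand``."""
        lx = self.vlen(x)
        out = []
        for rid, f in self.members[x]:
            out.append((rid, base, strand ^ f))
        for cv, off, cf in self.host_contents[x]:
            lc = self.vlen(cv)
            if strand == FWD:
                o2, s2 = off, cf
            else:
                o2, s2 = lx - (off + lc), flip(cf)
            for rid, f in self.members[cv]:
                out.append((rid, base + o2, s2 ^ f))
        return out

    # -- edges --------------------------------------------------------------

    def add_edge(self, edge: BidirectedEdge) -> int:
        edge.eid = self._next_eid
        self._next_eid += 1
        self.edges[edge.eid] = edge
        self.adj[edge.u].append(edge.eid)
        self.adj[edge.v].append(edge.eid)
        return edge.eid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self.adj[e.u].remove(eid)
        self.adj[e.v].remove(eid)

    def degree(self, x: int) -> int:
        return len(self.adj.get(x, ()))

    def sides(self, x: int):
        """Edge ends at x split by departure strand: (fwd side, rev side),
        each a list of (eid, end_index).  A self-loop contributes both ends."""
        fwd_side, rev_side = [], []
        for eid in sorted(set(self.adj.get(x, ()))):
            e = self.edges[eid]
            for endi, (vtx, dep) in enumerate(e.ends()):
                if vtx != x:
                    continue
                (fwd_side if dep == FWD else rev_side).append((eid, endi))
        return fwd_side, rev_side

    def edge_len(self, eid: int) -> int:
        e = self.edges[eid]
        if e.seq is not None:
            return len(e.seq)
        return self.vlen(e.u) + self.vlen(e.v) - e.olen

    def edge_seq(self, eid: int, forward: bool = True) -> str:
        e = self.edges[eid]
        if e.seq is not None:
            s = e.seq
        else:
            s = self.vstrand(e.u, e.su) + self.vstrand(e.v, e.sv)[e.olen :]
        return s if forward else reverse_complement(s)

    def edge_reads(self, eid: int, forward: bool = True):
        e = self.edges[eid]
        if e.reads is not None:
            pl = e.reads
        else:
            d = self.edge_len(eid)
            pl = self.unit_placements(e.u, e.su, 0) + self.unit_placements(
                e.v, e.sv, d - self.vlen(e.v)
            )
            pl = sorted(set(pl), key=lambda t: (t[1], t[0], t[2]))
        if not forward:
            d = self.edge_len(eid)
            out = []
            for rid, off, s in pl:
                lr = self.read_lengths.get(rid, self.read_len)
                out.append((rid, d - off - lr, flip(s)))
            pl = sorted(out, key=lambda t: (t[1], t[0], t[2]))
        return pl

    def edge_gaps(self, eid: int, forward: bool = True):
        e = self.edges[eid]
        if forward:
            return list(e.gaps)
        d = self.edge_len(eid)
        return sorted((d - st - ln, ln) for st, ln in e.gaps)

    def k(self, eid: int) -> int:
        e = self.edges[eid]
        if e.reads is not None:
            return len(e.reads)
        return len(self.edge_reads(eid))

    # -- traversal ----------------------------------------------------------

    def edge_endpoints(self, eid: int, forward: bool = True):
        """(tail, head, dep strand at tail, arr strand at head) for the chosen
        traversal direction."""
        e = self.edges[eid]
        if forward:
            return e.u, e.v, e.su, e.sv
        return e.v, e.u, flip(e.sv), flip(e.su)

    def path_string(self, path: Sequence[Tuple[int, bool]]) -> str:
        """String spelled by a consistent path [(eid, forward), ...].

        At every internal vertex the arrival strand of the incoming edge must
        equal the departure strand of the outgoing edge; reversing the path
        spells the reverse complement.
        """
        if not path:
            return ""
        s = self.edge_seq(*_pf(path[0]))
        prev = path[0]
        for step in path[1:]:
            _, head, _, arr = self.edge_endpoints(*_pf(prev))
            tail, _, dep, _ = self.edge_endpoints(*_pf(step))
            if tail != head or dep != arr:
                raise ValueError("inconsistent path: orientation mismatch at internal vertex")
            s += self.edge_seq(*_pf(step))[self.vlen(head) :]
            prev = step
        return s

    # -- debug dumps --------------------------------------------------------

    def to_gfa(self, path) -> None:
        """Write-only GFA1 dump: segments are edge strings, links share vertices."""
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for eid in sorted(self.edges):
                fh.write(f"S\tE{eid}\t{self.edge_seq(eid)}\n")
            for x in sorted(self.adj):
                fwd_side, rev_side = self.sides(x)
                for ea, _ in rev_side:
                    for eb, _ in fwd_side:
                        fh.write(f"L\tE{ea}\t+\tE{eb}\t+\t{self.vlen(x)}M\n")

    def to_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph overlap {\n")
            for eid, e in sorted(self.edges.items()):
                fh.write(
                    f'  {e.u} -- {e.v} [label="E{eid} d={self.edge_len(eid)} '
                    f'k={self.k(eid)} f={e.flow}"];\n'
                )
            fh.write("}\n")


def _pf(step):
    return step[0], step[1]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_graph(
    reads: ReadSet,
    M: int,
    incremental: bool = True,
    fuzz: int = 0,
) -> OverlapGraph:
    """Construct the transitively reduced bidirected string-overlap graph.

    Exact duplicate reads (also across strands) collapse to one vertex with a
    multiplicity counter; reads contained in a longer read attach to the host
    vertex and contribute to read counts but not to topology.  With
    ``incremental`` the reduction runs during construction (the default); the
    full build-then-reduce path serves as an oracle.
    """
    if not reads.uniform_length:
        logger.warning("non-uniform read lengths: ℓ taken as the maximum")
    ell = reads.length
    if M > ell:
        raise ValueError("minimum overlap exceeds read length")

    g = OverlapGraph(M, ell)
    g.read_lengths = {r.read_id: len(r) for r in reads}
    canon_index: Dict[str, int] = {}
    for r in reads:
        canon = min(r.sequence, reverse_complement(r.sequence))
        x = canon_index.get(canon)
        if x is None:
            x = g.add_vertex(r.sequence)
            canon_index[canon] = x
        f = FWD if r.sequence == g.vseq[x] else REV
        g.members[x].append((r.read_id, f))

    overlaps, containments = find_overlaps(g.vseq, M)

    # resolve containments (host of a contained vertex may itself be contained)
    by_inner: Dict[int, Tuple[int, int, int]] = {}
    for inner, host, off, strand in sorted(containments):
        if inner not in by_inner:
            by_inner[inner] = (host, off, strand)
    for inner in list(by_inner):
        host, off, strand = by_inner[inner]
        seen = {inner}
        while host in by_inner:
            if host in seen:
                break
            seen.add(host)
            h2, off2, s2 = by_inner[host]
            if s2 == FWD:
                off = off2 + off
            else:
                off = off2 + (g.vlen(host) - off - g.vlen(inner))
            strand ^= s2
            host = h2
        by_inner[inner] = (host, off, strand)
    for inner, (host, off, strand) in by_inner.items():
        g.contained_in[inner] = host
        g.host_contents[host].append((inner, off, strand))

    # drop overlaps touching contained vertices
    topo = {
        k: o
        for k, o in overlaps.items()
        if g.contained_in[k[0]] is None and g.contained_in[k[1]] is None
    }

    lengths = [g.vlen(x) for x in range(g.n_vertices)]
    if incremental:
        kept, red = reduce_records_incremental(topo, lengths, fuzz)
        g.construction_peak_edges = red.peak_live
    else:
        kept, _ = reduce_records_full(topo, lengths, fuzz)
        g.construction_peak_edges = len(topo)
    g.full_overlap_count = len(topo)

    for (u, v, su, sv), o in sorted(kept.items()):
        g.add_edge(BidirectedEdge(-1, u, v, su, sv, olen=o))
    logger.info(
        "graph: %d vertices, %d overlaps, %d edges after transitive reduction",
        g.n_vertices,
        len(topo),
        len(g.edges),
    )
    return g
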