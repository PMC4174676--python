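"""Tour of the bidirected overlap graph on a handful of reads.

Shows overlap detection over both strands, the string associated with an
edge, and transitive reduction removing the redundant short overlap.
"""

from olga.graph import build_graph, find_overlaps
from olga.seqio import Read, ReadSet

# three reads tiling a toy sequence; the outer pair also overlaps directly
reads = ReadSet()
reads.reads = [
    Read("a", "ACGTACGGTTCAGC"),
    Read("b", "GGTTCAGCAATTGG"),
    Read("c", "CAGCAATTGGCTTA"),
]

overlaps, _ = find_overlaps([r.sequence for r in reads], M=4)
print("overlaps (u, v, strand_u, strand_v) -> length:")
for key, olen in sorted(overlaps.items()):
    print(f"  {key} -> {olen}")

g = build_graph(reads, M=4)
print(f"after transitive reduction: {len(g.edges)} edges "
      f"(the short a-c overlap is implied by a-b-c and was removed)")
for eid in sorted(g.edges):
    e = g.edges[eid]
    print(f"  edge {e.u}-{e.v} overlap {e.olen}: {g.edge_seq(eid)}")

# the string of the two-edge path spells the union of all three reads
e1, e2 = sorted(g.edges)
print("path string:", g.path_string([(e1, True), (e2, True)]))
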