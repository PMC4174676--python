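# Methods

This note describes the model behind `olga`, the choices made where the
design was genuinely open, and what the bundled simulator does and does not
emulate.

## The bidirected overlap graph

DNA is double-stranded, so a read and its reverse complement are the same
molecule.  We represent both by one vertex and give every edge an
orientation at each end.  Internally an edge stores the strand pair
`(su, sv)` of its canonical u→v traversal: the overlap identity is
`suffix(strand(u,su)) == prefix(strand(v,sv))` and the edge string is
`strand(u,su) + strand(v,sv)[olen:]`; the reverse traversal spells the
reverse complement.  A walk is consistent when it leaves each internal
vertex on the strand it arrived with.  In the orientation vocabulary of the
bidirected-graph literature, `out` at u corresponds to `su = forward` and
`out` at v to `sv = reverse`; same-strand overlaps give (out,in)/(in,out)
and the two opposite-strand overlap types give (out,out) and (in,in).  Any
single global convention works; this one is used everywhere.

Only reads over {A,C,G,T} enter the graph (the 2-bit packing admits no
ambiguity codes); reads with other symbols are dropped and counted, or
optionally masked with seeded random bases.  Exact duplicates — also across
strands — collapse into one vertex with a multiplicity counter, and a read
occurring as a substring of a longer read attaches to the host vertex: both
contribute to read counts (arrival-rate semantics) but not to topology.
Read-start offsets on an edge are therefore non-decreasing rather than
strictly increasing — collapsed duplicates share an offset.

## Overlap detection

Whenever two reads overlap by at least M bases, a prefix or suffix of
length ≥ M of one occurs inside the other.  We hash every prefix and suffix
of length `w = min{32, M}` of every read and reverse complement (at 2
bits/base, 32 bases fill one 64-bit word; a stated window of 64 bases would
need two words, so the single-word window is the default capacity) and
scan each read's windows with O(1) rolling updates.  Every hit is verified
by full character comparison before an edge is emitted; per vertex pair and
strand combination only the maximal overlap is kept.  A brute-force
all-pairs, both-strand oracle (`find_overlaps_bruteforce`) defines
correctness in the tests.

## Transitive reduction during construction

An edge is transitive when a consistent two-edge path through a third
vertex spells exactly its string; the two longer constituent overlaps are
more reliable, so the edge is redundant.  With exact (error-corrected)
overlaps the string identity reduces to a combinatorial certificate —
matching strands and `o_e = o_1 + o_2 − ℓ_w` — which the implementation
uses; a configurable fuzz (default 0 bases) widens the length match for
inexact data, and an independent oracle re-checks the actual strings.

To avoid holding the full graph, edges are inserted grouped by their
smaller endpoint.  A vertex is reduced once every edge incident to it or to
a neighbour has arrived; a marked edge (u,z) is physically deleted once
every vertex whose reduction could consult it — u, z, and all their
neighbours — has been reduced.  Marked edges still serve as certificates
until deleted, exactly as in the full build-then-reduce algorithm, so the
final edge set is identical (asserted over seeded instances) and the
retained-edge count never exceeds the unreduced graph size.

## Cleaning

Maximal paths of degree-(1,1) vertices compress into composite edges that
store the merged string and all read placements.  Residual errors produce
two artifacts: *tips* — dead-end edges with few reads — and *bubbles* —
parallel edges with nearly identical strings and very different coverage.
Defaults (all configurable; the model gives no canonical values): a tip is
removed when its read count is below 5 and its length at most 3ℓ (the
length cap protects genuine long dead ends); a bubble branch is removed
when global-alignment identity (edlib, unit costs) is ≥ 0.95 and the read
count ratio ≥ 3.  Cleaning alternates tips and bubbles with re-compression
to a fixpoint, capped at 10 rounds.

## Multiplicity statistics and genome length

With n reads sampled uniformly from a genome of length L, the reads landing
on an edge whose string occurs m times follow Poisson(m·λ), λ = (n/L)·d.
The log-odds of m against m+1 copies given k observed reads is

    R(e, m) = λ − k·ln((m+1)/m),

which at m = 1 is the A-statistic `(n/L)·d − k·ln 2`.  For edges the
arrival rate uses the *effective* length d−ℓ+1 (a read must fit on the
edge); the raw d is used in the L update below, which keeps the
single-edge case exact (one edge containing all n reads gives L̂ = d).

L is unknown at first, so it is bootstrapped: edges of ≥ 1000 bases start
as "unique"; each round sets `L = n·Σd/Σk` over the unique set and keeps as
unique the long edges with R(e,1) ≥ 20; iteration stops when the set is
stable (cap 20 rounds; in practice ≤ 5).

The insert-size model (μ, σ) is the sample mean/standard deviation of the
outer (5'-to-5') distance over mate pairs whose two reads are placed on one
edge with opposite strands; ambiguously placed reads are excluded.  The
outer-distance convention matches the simulator.

## Copy counts as min-cost bidirected flow

The genome corresponds to a collection of consistent walks; an edge's copy
count f_e is the number of traversals.  Maximizing the Poisson likelihood
of the observed per-edge read counts x_e is minimizing the separable convex

    cost_e(f) = λ_e·f − x_e·ln f   (f ≥ 1; the additive constant is dropped),

minimized near f* = x_e/λ_e.  Capacity bounds come from the statistics, in
priority order: long (≥ 1000 bp) edges with R(e,1) ≥ T are pinned to
l = u = 1; long edges with a confident multiplicity (smallest m with
R(e,m−1) ≤ −T and R(e,m) ≥ T) get l = m; other long edges l = 1; short
composite edges with ≥ 30 reads l = 1; the rest l = 0.  T = 3 by default.
Edges allowed zero flow pay `λ_e + x_e·ln(x_e+1)` at f = 0 — the cost of
explaining their reads as noise — so well-covered edges keep flow.  Every
vertex carries a lower bound of 1: its read must appear in the assembly.

Each cost is given a ≤ 3-piece linear approximation interpolating the exact
cost at the breakpoints {l, (1 if l=0), f*, horizon} with non-decreasing
slopes; the horizon for unbounded edges is max(4, ⌈2·x_e/λ_e⌉).  The
bidirected instance reduces to a directed min-cost circulation: each vertex
splits into forward- and reverse-strand states (each further split by an
internal arc enforcing the vertex lower bound), and each edge becomes a
mirror pair of arc bundles, one per traversal direction.  Because linear
genomes and coverage gaps mean the walks have endpoints, a ground node
offers start/end arcs at every vertex at a per-endpoint penalty (default
10, on the scale of a few units of edge cost: large enough not to fragment
the flow, small enough never to outweigh routing flow through a long wrong
edge).  The network simplex solves the instance exactly on integers; the
mirror symmetry guarantees a symmetric optimum, recovered by averaging the
two mirror flows.  Bidirected flow polytopes are only half-integral in
general; if the average is half-integral the instance is re-solved exactly
as an integer program (scipy's MILP), which preserves the exact-optimality
contract.  Conservation and bounds are asserted after every solve.  Per-read
copy counts are looked up from the read's edge; reads on several edges
(junction reads) take the maximum.

## Resolution, mate support, scaffolding

After flows are known: vertices with a single edge on one side are
collapsed (the in-edge string is spliced onto each out-edge, which keeps
its flow); a vertex with a self-loop and exactly two flank edges is
replaced by one edge with the loop string inserted flow-many times (loops
whose orientations forbid repeated traversal are left alone, and unequal
flank flows take the minimum with a warning).

Remaining vertices with ≥ 2 edges on both sides are ambiguous.  A mate
pair supports the traversal (in-edge, vertex, out-edge) when *every* path
between the mates whose implied outer distance lies within μ±3σ passes
through it; path enumeration is a bounded DFS (cap 500 paths / 20 000
expansions per pair; capped pairs are unusable).  Merging requires support
≥ 5; the merged edge takes min(f₁,f₂), the lower-flow constituent is
deleted and the other decremented (both deleted on a tie).  Merges apply in
descending support order; equal-support merges competing for one edge end
are all skipped.  Pairs with *no* in-range path vote to join two edge ends
when the flank distances sum below μ+3σ and both edges have non-zero flow
or ≥ 100 bp; with ≥ 5 votes the edges are joined, the gap μ−(a₁+a₂)
averaged over votes, filled with N's when positive, and checked for a real
sequence overlap when non-positive.  Whether disconnected-mate joining
reuses the same support threshold of 5 was an open choice; we reuse it.

Contigs are the strings of edges with flow ≥ 1 and length ≥ 100, reported
on the canonical strand (lexicographically smaller of the two) and ordered
by length for reproducible output.  N50 is the length of the shortest
contig in the minimal set covering half the assembly; NG50 uses half the
reference length.

## The simulator

The generator emulates exactly the sampling model the statistics assume:
i.i.d. uniform bases; planted repeat families (copy number, length,
identity) at non-overlapping recorded positions; read starts uniform over
both strands at a stated coverage; mate pairs with normally distributed
outer distance (FR orientation, truncated to the genome); substitution
errors at a per-base rate confined to a stated fraction of reads.  One
unpaired read is pinned at each genome end by default (`anchor_ends`),
emulating complete terminal coverage — under pure uniform sampling a few
terminal bases are almost surely uncovered, which is a property of
sampling, not of the assembler.  All randomness derives from the seed.

It does **not** emulate: coverage bias (GC, mappability), indel or
platform-specific error profiles, quality values, chimeric fragments, or
diploidy.  Passing tests therefore show the algorithms are correct under
their own model, not that the assembler is robust to real-library
artifacts; the error-injection conditions probe the cleaning heuristics
only.

## Problem sizes and defaults

Simulation-scale checks run on 100 kb genomes at 30× coverage of 100 bp
reads (≈ 30 000 reads, ≈ 450 000 overlap candidates), with M = 50 — wide
enough that expected coverage breaks over 100 kb are ≪ 1, small enough to
keep the graph dense in overlaps; combinatorial cross-checks (overlap
completeness, reduction equivalence) use many seeded instances of ≤ 500
reads where the quadratic oracles are cheap.  Defaults follow the model
where it states them (T = 3, uniqueness length 1000 bp and log-odds 20,
short-edge read count 30, support 5, minimum contig 100 bp); the rest
(tip/bubble thresholds, walk-end penalty, path caps, fuzz 0) are documented
package choices above.

## Known limitations

Inexact overlaps are out of scope (reads are assumed error-corrected;
residual errors are handled by cleaning, not alignment).  Bubble popping is
restricted to two-edge bubbles; superbubbles are not detected.  Scaffolding
uses a single insert library and joins at most one partner per edge end.
The incremental reducer's deletion schedule is conservative (neighbourhood
radius 2), trading some peak memory for provable equivalence with the full
reduction.  Genomes are treated as linear; circular genomes assemble into a
cyclic graph whose closure is not explicitly reported.
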