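"""Genome-length bootstrap and insert-size estimation from the graph alone.

Neither quantity needs the reference: L comes from matching the arrival rate
of reads on long (assumed unique) edges to the genome-wide rate, and the
insert model from mate pairs that land on a single edge.
"""

from olga.graph import build_graph
from olga.simplify import clean
from olga.simulate import SimulationConfig, simulate_genome, simulate_reads
from olga.stats import estimate_genome_length, estimate_insert_size

cfg = SimulationConfig(
    genome_length=50_000, coverage=30, read_length=100, mu=300, sigma=30, seed=5,
)
ref, ann = simulate_genome(cfg)
reads, truth = simulate_reads(ref, cfg, ann)

g = build_graph(reads, M=50)
clean(g)

L, iters, unique = estimate_genome_length(g, n=g.total_reads)
print(f"true genome length 50000, estimate {L:.0f} "
      f"({100 * abs(L - 50_000) / 50_000:.2f}% off, {iters} iterations)")

pairs = [(reads.reads[i].read_id, reads.reads[j].read_id)
         for i, j in reads.mate_pairs()]
model = estimate_insert_size(g, pairs)
print(f"true insert 300±30, estimate {model.mu:.1f}±{model.sigma:.1f} "
      f"from {model.n_pairs_used} same-edge pairs")
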