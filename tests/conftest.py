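"""Shared fixtures: simulated datasets and hand-built toy graphs."""

from __future__ import annotations

import random

import pytest

from olga.graph import FWD, BidirectedEdge, OverlapGraph
from olga.pipeline import PipelineConfig, run_assemble
from olga.simulate import SimulationConfig, simulate_genome, simulate_reads


def simulate_dataset(**kw):
    cfg = SimulationConfig(**kw)
    ref, ann = simulate_genome(cfg)
    rs, truth = simulate_reads(ref, cfg, ann)
    return ref, ann, rs, truth


@pytest.fixture(scope="session")
def plain_100k():
    """100 kb error-free repeat-free genome, 30x single-end 100 bp reads,
    fully assembled."""
    ref, ann, rs, truth = simulate_dataset(
        genome_length=100_000, coverage=30.0, read_length=100, seed=1
    )
    result = run_assemble(rs, PipelineConfig(M=50))
    return ref, rs, truth, result


@pytest.fixture(scope="session")
def errors_100k():
    """Same conditions with 1% substitution errors in 5% of the reads."""
    ref, ann, rs, truth = simulate_dataset(
        genome_length=100_000,
        coverage=30.0,
        read_length=100,
        error_rate=0.01,
        fraction_reads_with_errors=0.05,
        seed=2,
    )
    result = run_assemble(rs, PipelineConfig(M=50))
    return ref, rs, truth, result


# ---------------------------------------------------------------------------
# toy graphs with explicit composite edges
# ---------------------------------------------------------------------------

_rng = random.Random(99)


def _rand_dna(n, rng=None):
    rng = rng or _rng
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_toy_graph(n_vertices: int, ell: int = 10, M: int = 5, seed: int = 7) -> OverlapGraph:
    """Graph with ``n_vertices`` random distinct vertex reads of length ℓ."""
    rng = random.Random(seed)
    g = OverlapGraph(M=M, read_len=ell)
    for i in range(n_vertices):
        seq = _rand_dna(ell, rng)
        x = g.add_vertex(seq)
        g.members[x].append((f"v{i}", 0))
        g.read_lengths[f"v{i}"] = ell
    return g


_edge_counter = [0]


def add_toy_edge(
    g: OverlapGraph,
    u: int,
    v: int,
    su: int = FWD,
    sv: int = FWD,
    d: int = 300,
    k: int = 10,
    flow: int = 0,
    seed: int = 0,
):
    """Composite edge whose string starts with strand(u,su) and ends with
    strand(v,sv) (the invariant splice_path relies on), with k read
    placements spread along it."""
    rng = random.Random((u, v, su, sv, d, seed).__hash__() & 0x7FFFFFFF)
    lu, lv = g.vlen(u), g.vlen(v)
    assert d >= lu + lv, "toy edge must be long enough to contain both endpoint reads"
    middle = _rand_dna(d - lu - lv, rng)
    seq = g.vstrand(u, su) + middle + g.vstrand(v, sv)
    _edge_counter[0] += 1
    tag = _edge_counter[0]
    ell = g.read_len
    reads = []
    for j in range(k):
        off = min(int(j * max(d - ell, 1) / max(k, 1)), max(d - ell, 0))
        reads.append((f"e{tag}_r{j}", off, FWD))
        g.read_lengths[f"e{tag}_r{j}"] = ell
    e = BidirectedEdge(
        -1, u, v, su, sv, seq=seq, reads=sorted(reads, key=lambda t: (t[1], t[0])),
        composite=True, flow=flow,
    )
    g.add_edge(e)
    return e
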