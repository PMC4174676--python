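"""End-to-end assembly pipeline.

Stage order: overlap-graph construction with incremental transitive
reduction → cleaning (compression, tips, bubbles) → genome-length and
insert-size estimation → copy-count bounds and min-cost-flow solve →
flow-guided resolution and mate-supported merging → contig extraction →
scaffolding of disconnected mate-supported edge pairs.  The run is
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

from . import contigs as contigs_mod
from . import flow as flow_mod
from . import resolve as resolve_mod
from . import simplify as simplify_mod
from . import stats as stats_mod
from .graph import OverlapGraph, build_graph
from .seqio import ReadSet

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully resolved assembly configuration; every run logs it."""

    M: int = 50
    T: float = 3.0
    unique_len: int = 1000
    short_edge_reads: int = 30
    tip_min_reads: int = 5
    tip_len_factor: float = 3.0
    bubble_identity_min: float = 0.95
    bubble_coverage_ratio_min: float = 3.0
    min_support: int = 5
    min_contig_len: int = 100
    mu: Optional[float] = None
    sigma: Optional[float] = None
    walk_end_penalty: float = 10.0
    path_cap: int = 500
    incremental_reduction: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssemblyResult:
    graph: OverlapGraph
    contigs: List[contigs_mod.Contig]
    scaffolds: List[contigs_mod.Contig]
    genome_length: float
    bootstrap_iterations: int
    insert_model: Optional[stats_mod.InsertSizeModel]
    copy_counts: Optional[flow_mod.CopyCountSolution]
    metrics: Dict[str, float] = field(default_factory=dict)


def run_assemble(reads: ReadSet, config: PipelineConfig | None = None) -> AssemblyResult:
    """Assemble a read set into contigs and scaffolds."""
    config = config or PipelineConfig()
    logger.info("assembly config: %s", config.to_dict())
    metrics: Dict[str, float] = {}

    if config.M > reads.length:
        raise ValueError("minimum overlap exceeds read length")

    g = build_graph(reads, config.M, incremental=config.incremental_reduction)
    n = g.total_reads
    metrics["n_reads"] = n
    metrics["n_vertices"] = g.n_vertices
    metrics["overlaps"] = g.full_overlap_count
    metrics["edges_after_reduction"] = len(g.edges)
    metrics["construction_peak_edges"] = g.construction_peak_edges

    cleaning = simplify_mod.CleaningParams(
        tip_min_reads=config.tip_min_reads,
        tip_len_factor=config.tip_len_factor,
        bubble_identity_min=config.bubble_identity_min,
        bubble_coverage_ratio_min=config.bubble_coverage_ratio_min,
    )
    simplify_mod.clean(g, cleaning)
    metrics["edges_after_cleaning"] = len(g.edges)

    L_hat, iters, unique = stats_mod.estimate_genome_length(
        g, n=n, unique_len=config.unique_len
    )
    metrics["genome_length"] = L_hat
    metrics["bootstrap_iterations"] = iters
    metrics["unique_edges"] = len(unique)

    pairs = reads.mate_pairs()
    pair_ids = [(reads.reads[i].read_id, reads.reads[j].read_id) for i, j in pairs]
    insert_model = None
    if config.mu is not None:
        insert_model = stats_mod.InsertSizeModel(config.mu, config.sigma or 0.0)
    elif pair_ids:
        try:
            insert_model = stats_mod.estimate_insert_size(g, pair_ids)
            metrics["insert_mu"] = insert_model.mu
            metrics["insert_sigma"] = insert_model.sigma
        except ValueError as exc:
            logger.warning("insert size estimation failed: %s", exc)

    flow_cfg = flow_mod.FlowConfig(
        T=config.T,
        unique_len=config.unique_len,
        short_edge_reads=config.short_edge_reads,
        walk_end_penalty=config.walk_end_penalty,
    )
    solution = flow_mod.solve_copy_counts(g, n=n, L=L_hat, config=flow_cfg)
    metrics["flow_objective"] = solution.objective
    metrics["walk_endpoints"] = solution.walk_endpoints

    resolve_mod.resolve_graph(
        g, pair_ids, insert_model, min_support=config.min_support, path_cap=config.path_cap
    )
    metrics["edges_after_resolution"] = len(g.edges)

    contig_list = contigs_mod.extract_contigs(g, config.min_contig_len)

    scaffolds = contig_list
    if insert_model is not None and pair_ids:
        _supports, votes = resolve_mod.compute_mate_support(
            g, pair_ids, insert_model, config.path_cap
        )
        resolve_mod.merge_disconnected_mates(g, votes, config.min_support)
        scaffolds = contigs_mod.extract_contigs(g, config.min_contig_len)
    metrics["n_contigs"] = len(contig_list)
    metrics["n_scaffolds"] = len(scaffolds)

    return AssemblyResult(
        graph=g,
        contigs=contig_list,
        scaffolds=scaffolds,
        genome_length=L_hat,
        bootstrap_iterations=iters,
        insert_model=insert_model,
        copy_counts=solution,
        metrics=metrics,
    )
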