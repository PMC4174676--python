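"""Edge-multiplicity statistics, genome-length bootstrap, insert-size model.

Under uniform sampling of n reads from a genome of length L, the number of
reads landing on an edge of (effective) length d is Poisson with mean m·λ,
λ = (n/L)·d, when the edge's string occurs m times in the genome.  The
log-odds of multiplicity m against m+1 given k observed reads is

    R(e, m) = ln P(k; m·λ) − ln P(k; (m+1)·λ) = λ − k·ln((m+1)/m),

the generalization of the classical A-statistic, which is recovered at m=1:
R(e, 1) = d·(n/L) − k·ln 2.  Large positive R(e,1) marks single-copy
("unique") edges; the bootstrap below alternates between estimating L from
the current unique set and re-selecting unique edges under the new L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Set, Tuple

from .graph import OverlapGraph

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    """Global quantities of one assembly problem: read count n, read length ℓ,
    (estimated) genome length L and the minimum overlap M."""

    n: int
    ell: int
    L: float
    M: int

    def __post_init__(self):
        if self.n < 1 or self.L <= 0 or not (1 <= self.M <= self.ell):
            raise ValueError("require n >= 1, L > 0, 1 <= M <= ℓ")


@dataclass
class InsertSizeModel:
    """Mean and standard deviation of the mate-pair outer (5'-to-5') distance,
    estimated from pairs co-placed on a single edge."""

    mu: float
    sigma: float
    n_pairs_used: int = 0


def logodds_R(d: int, k: int, m: int, n: int, L: float) -> float:
    """Log-odds R(e, m) of an edge with d bases and k reads having multiplicity
    m versus m+1.  Strictly increasing in m (for k > 0), decreasing in k.

    ``d`` is used exactly as given; pass the effective length d−ℓ+1 when
    scoring composite edges (see :func:`edge_logodds`).
    """
    if m < 1:
        raise ValueError("multiplicity m must be >= 1")
    if d < 1:
        raise ValueError("edge length d must be >= 1")
    lam = (n / L) * d
    return lam - k * math.log((m + 1) / m)


def a_statistic(d: int, k: int, n: int, L: float) -> float:
    """Classical A-statistic, identically R(e, 1)."""
    return logodds_R(d, k, 1, n, L)


def effective_length(d: int, ell: int) -> int:
    """Positions where a read of length ℓ can start on a d-base string."""
    return d - ell + 1 if d >= ell else d


def edge_logodds(g: OverlapGraph, eid: int, m: int, n: int, L: float) -> float:
    """R(e, m) for a graph edge, using the effective length for the arrival
    rate (a read must fit entirely on the edge)."""
    d_eff = effective_length(g.edge_len(eid), g.read_len)
    return logodds_R(d_eff, g.k(eid), m, n, L)


def estimate_genome_length(
    g: OverlapGraph,
    n: Optional[int] = None,
    unique_len: int = 1000,
    unique_logodds: float = 20.0,
    max_iter: int = 20,
) -> Tuple[float, int, Set[int]]:
    """Bootstrap estimate of the genome length L.

    Edges of length >= ``unique_len`` are initially assumed unique.  Each
    round estimates L by matching the unique edges' arrival rate to the
    genome-wide rate, L = n·Σd / Σk over the unique set, then keeps as unique
    only edges with R(e,1) >= ``unique_logodds`` under the new L; iteration
    stops when the unique set is stable.  Returns (L̂, iterations, unique set).
    """
    if n is None:
        n = g.total_reads
    unique = {eid for eid in g.edges if g.edge_len(eid) >= unique_len}
    if not unique:
        raise ValueError(
            f"no edge of length >= {unique_len} bp; lower the uniqueness length"
        )
    L_hat = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        total_d = sum(g.edge_len(eid) for eid in unique)
        total_k = sum(g.k(eid) for eid in unique)
        if total_k == 0:
            raise ValueError("unique edges carry no reads; cannot estimate L")
        L_hat = n * total_d / total_k
        new_unique = {
            eid
            for eid in g.edges
            if g.edge_len(eid) >= unique_len
            and edge_logodds(g, eid, 1, n, L_hat) >= unique_logodds
        }
        if not new_unique:
            logger.warning("unique set emptied at iteration %d; keeping previous", iterations)
            break
        if new_unique == unique:
            break
        unique = new_unique
    else:
        logger.warning("genome-length bootstrap hit the iteration cap (%d)", max_iter)
    logger.info("estimated genome length %.0f after %d iterations", L_hat, iterations)
    return L_hat, iterations, unique


def same_edge_insert_lengths(g: OverlapGraph, mate_pairs: Iterable[Tuple[str, str]]) -> List[int]:
    """Outer distances implied by mate pairs whose two reads are placed on one
    edge with opposite strands (the only pairs whose distance is known)."""
    placements = {}
    for eid in g.edges:
        for rid, off, s in g.edge_reads(eid):
            placements.setdefault(rid, []).append((eid, off, s))
    lengths = []
    for r1, r2 in mate_pairs:
        p1s, p2s = placements.get(r1), placements.get(r2)
        if not p1s or not p2s or len(p1s) > 1 or len(p2s) > 1:
            continue  # absent or ambiguously placed
        (e1, o1, s1), (e2, o2, s2) = p1s[0], p2s[0]
        if e1 != e2 or s1 == s2:
            continue
        l1 = g.read_lengths.get(r1, g.read_len)
        l2 = g.read_lengths.get(r2, g.read_len)
        five1 = o1 if s1 == 0 else o1 + l1
        five2 = o2 if s2 == 0 else o2 + l2
        span = abs(five2 - five1)
        if span > 0:
            lengths.append(span)
    return lengths


def estimate_insert_size(g: OverlapGraph, mate_pairs: Iterable[Tuple[str, str]]) -> InsertSizeModel:
    """Sample mean and standard deviation of the outer distance over usable
    same-edge mate pairs.  Raises when fewer than two pairs are usable, in
    which case the caller must supply μ and σ."""
    lengths = same_edge_insert_lengths(g, mate_pairs)
    if len(lengths) < 2:
        raise ValueError(
            "fewer than 2 same-edge mate pairs; supply the insert size mean/stddev"
        )
    mu = sum(lengths) / len(lengths)
    var = sum((x - mu) ** 2 for x in lengths) / (len(lengths) - 1)
    return InsertSizeModel(mu=mu, sigma=math.sqrt(var), n_pairs_used=len(lengths))
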