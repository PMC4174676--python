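"""Contig extraction and assembly summary statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .graph import OverlapGraph
from .seqio import reverse_complement, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class Contig:
    """An output sequence with provenance.

    The sequence is reported on its canonical strand (lexicographically
    smaller of string/reverse-complement); N's occur only inside the recorded
    gap spans, which come from scaffolding.
    """

    contig_id: str
    sequence: str
    source_edge_id: int
    n_gap_spans: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_contigs(g: OverlapGraph, min_contig_len: int = 100) -> List[Contig]:
    """One contig per edge with non-zero flow and length >= min_contig_len.

    Deterministic ordering: length descending, then source edge id.
    """
    out = []
    for eid in sorted(g.edges):
        e = g.edges[eid]
        d = g.edge_len(eid)
        if e.flow < 1 or d < min_contig_len:
            continue
        seq = g.edge_seq(eid)
        rc = reverse_complement(seq)
        if rc < seq:
            seq = rc
            gaps = g.edge_gaps(eid, forward=False)
        else:
            gaps = g.edge_gaps(eid, forward=True)
        out.append(Contig("", seq, eid, sorted(gaps)))
    if not out:
        logger.warning("no edges qualify as contigs")
    out.sort(key=lambda c: (-c.length, c.source_edge_id))
    for i, c in enumerate(out, start=1):
        c.contig_id = f"contig_{i}"
    return out


def assembly_summary(
    contigs: Sequence[Contig], reference_length: Optional[int] = None
) -> dict:
    """Total length, count, N50 (and NG50 when a reference length is given).

    N50 is the length of the shortest contig in the minimal set of longest
    contigs covering at least half the total assembly length; NG50 uses half
    the reference length instead and is 0 when unreachable.
    """
    if not contigs:
        return {"count": 0, "total_length": 0, "n50": 0, "ng50": 0, "n_gap_bases": 0}
    lengths = sorted((c.length for c in contigs), reverse=True)
    total = sum(lengths)

    def _nx50(target: float) -> int:
        acc = 0
        for ln in lengths:
            acc += ln
            if acc >= target:
                return ln
        return 0

    summary = {
        "count": len(contigs),
        "total_length": total,
        "n50": _nx50(total / 2),
        "n_gap_bases": sum(ln for c in contigs for _st, ln in c.n_gap_spans),
    }
    if reference_length is not None:
        summary["ng50"] = _nx50(reference_length / 2)
    return summary


def write_contigs(contigs: Sequence[Contig], path) -> None:
    write_fasta(((c.contig_id, c.sequence) for c in contigs), path)


def write_summary_tsv(summary: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
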