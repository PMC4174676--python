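"""Synthetic genomes, reads and mate pairs with known ground truth.

The generator emulates the sampling model the assembler assumes: reads drawn
uniformly from both strands of a linear genome at a stated coverage, optional
substitution errors confined to a fraction of reads, and mate pairs whose
outer (5'-to-5') distance is normally distributed.  Every output is a pure
function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .seqio import Read, ReadSet, reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``repeat_spec`` plants exact (or degraded-identity) repeat families:
    each entry is (copy_number, repeat_length, identity).  ``error_rate`` is
    a per-base substitution probability applied to ``fraction_reads_with_errors``
    of the reads.  ``mu``/``sigma`` describe the outer-distance insert model;
    leave ``mu`` unset for single-end data.  All randomness derives from
    ``seed``.
    """

    genome_length: int = 100_000
    repeat_spec: List[Tuple[int, int, float]] = field(default_factory=list)
    coverage: float = 30.0
    read_length: int = 100
    mu: Optional[float] = None
    sigma: float = 0.0
    error_rate: float = 0.0
    fraction_reads_with_errors: float = 0.0
    anchor_ends: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.read_length <= 0 or self.coverage < 0:
            raise ValueError("genome_length, read_length > 0 and coverage >= 0 required")
        if self.error_rate < 0 or not (0 <= self.fraction_reads_with_errors <= 1):
            raise ValueError("invalid error configuration")


@dataclass
class RepeatCopy:
    start: int
    end: int
    family: int
    copy_number: int


def simulate_genome(config: SimulationConfig):
    """Random genome with planted repeat copies.

    Returns ``(reference, annotation)``; the annotation lists every repeat
    copy's interval and family copy number.  Planted copies never overlap.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    ref = _BASES[rng.integers(0, 4, size=L)]
    annotation: List[RepeatCopy] = []
    occupied: List[Tuple[int, int]] = []
    for fam, (copies, rlen, identity) in enumerate(config.repeat_spec):
        if copies * rlen > L:
            raise ValueError("planted repeats do not fit in the genome")
        unit = _BASES[rng.integers(0, 4, size=rlen)]
        placed = 0
        attempts = 0
        while placed < copies:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place repeats without overlap")
            start = int(rng.integers(0, L - rlen + 1))
            if any(start < e and start + rlen > s for s, e in occupied):
                continue
            copy = unit.copy()
            if identity < 1.0:
                nmut = rng.binomial(rlen, 1.0 - identity)
                pos = rng.choice(rlen, size=nmut, replace=False)
                for p in pos:
                    copy[p] = _BASES[(np.flatnonzero(_BASES == copy[p])[0] + rng.integers(1, 4)) % 4]
            ref[start : start + rlen] = copy
            occupied.append((start, start + rlen))
            annotation.append(RepeatCopy(start, start + rlen, fam, copies))
            placed += 1
    return "".join(ref), annotation


def _copy_count_at(annotation: Sequence[RepeatCopy], start: int, length: int) -> int:
    """True copy count of a read whose origin interval lies mostly inside a
    planted repeat copy; 1 elsewhere."""
    mid = start + length // 2
    for rc in annotation:
        if rc.start <= mid < rc.end and start >= rc.start - length // 2:
            return rc.copy_number
    return 1


@dataclass
class ReadTruth:
    origin: int
    strand: int  # 0 fwd, 1 rev
    copy_count: int
    has_errors: bool


def simulate_reads(reference: str, config: SimulationConfig, annotation=()):
    """Sample reads (and mate pairs when ``mu`` is set) from the reference.

    Returns ``(ReadSet, truth)`` where ``truth`` maps read_id to a
    :class:`ReadTruth` with the origin position, strand and the copy count of
    the repeat family the read was sampled from.  Error positions are i.i.d.
    substitutions at ``error_rate`` within the chosen fraction of reads.
    """
    rng = np.random.default_rng(config.seed + 1)
    L, ell = len(reference), config.read_length
    if ell > L:
        raise ValueError("read_length exceeds genome length")
    n_target = int(round(config.coverage * L / ell))
    rc_ref = reverse_complement(reference)
    rs = ReadSet()
    truth = {}

    def add_read(rid: str, start: int, strand: int) -> Read:
        if strand == 0:
            seq = reference[start : start + ell]
        else:
            seq = rc_ref[L - start - ell : L - start]
        errors = False
        if config.error_rate > 0 and rng.random() < config.fraction_reads_with_errors:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(ell) < config.error_rate)
            if len(hits):
                errors = True
                for p in hits:
                    cur = chr(arr[p])
                    choices = [b for b in "ACGT" if b != cur]
                    arr[p] = ord(choices[rng.integers(0, 3)])
                seq = arr.tobytes().decode()
        read = Read(rid, seq)
        rs.reads.append(read)
        truth[rid] = ReadTruth(start, strand, _copy_count_at(annotation, start, ell), errors)
        return read

    if config.mu is None:
        for i in range(n_target):
            start = int(rng.integers(0, L - ell + 1))
            strand = int(rng.integers(0, 2))
            add_read(f"r{i}", start, strand)
    else:
        if config.mu < ell:
            raise ValueError("insert size mean smaller than read length is infeasible")
        n_pairs = n_target // 2
        for i in range(n_pairs):
            frag = int(round(rng.normal(config.mu, config.sigma)))
            frag = max(ell, min(frag, L))
            start = int(rng.integers(0, L - frag + 1))
            # FR pair: fragment [start, start+frag) on the forward strand, one
            # read from each end pointing inward; a fair coin decides which
            # physical read is the first mate (equivalently, which strand the
            # fragment was sequenced from)
            a_first = bool(rng.integers(0, 2))
            ra = add_read(f"p{i}/1" if a_first else f"p{i}/2", start, 0)
            rb = add_read(f"p{i}/2" if a_first else f"p{i}/1", start + frag - ell, 1)
            first, second = (ra, rb) if a_first else (rb, ra)
            first.mate_id, first.mate_end = second.read_id, "first"
            second.mate_id, second.mate_end = first.read_id, "second"
    if config.anchor_ends:
        # one error-free unpaired read pinned at each genome end, emulating
        # complete terminal coverage (uniform sampling a.s. leaves a few
        # terminal bases uncovered)
        rs.reads.append(Read("anchorL", reference[:ell]))
        truth["anchorL"] = ReadTruth(0, 0, _copy_count_at(annotation, 0, ell), False)
        rs.reads.append(Read("anchorR", rc_ref[:ell]))
        truth["anchorR"] = ReadTruth(L - ell, 1, _copy_count_at(annotation, L - ell, ell), False)
    return rs, truth


def check_contigs_against_truth(contig_seqs: Sequence[str], reference: str):
    """Exact-match evaluation of contigs against the simulated reference.

    Each contig is split at N-gaps; every piece is tested for exact substring
    membership in the reference or its reverse complement (a failing piece is
    a misjoin).  Coverage is the fraction of reference bases covered by the
    union of all exact matches.

    Returns a dict with ``coverage``, ``misjoins`` and per-contig
    ``exact_match`` flags.
    """
    L = len(reference)
    rc = reverse_complement(reference)
    covered = np.zeros(L, dtype=bool)
    misjoins = 0
    flags = []
    for seq in contig_seqs:
        pieces = [p for p in seq.split("N") if p]
        ok = True
        for piece in pieces:
            found = False
            for hay, revmap in ((reference, False), (rc, True)):
                start = hay.find(piece)
                while start != -1:
                    found = True
                    if revmap:
                        covered[L - start - len(piece) : L - start] = True
                    else:
                        covered[start : start + len(piece)] = True
                    start = hay.find(piece, start + 1)
            if not found:
                misjoins += 1
                ok = False
        flags.append(ok)
    return {
        "coverage": float(covered.sum()) / L,
        "misjoins": misjoins,
        "exact_match": flags,
    }
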