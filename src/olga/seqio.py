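"""Sequence input/output and strand-aware primitives.

Reads are plain DNA strings over {A,C,G,T}; a read and its reverse complement
always denote the same molecule, so every operation downstream treats the two
strands symmetrically.  Parsing goes through Biopython's SeqIO; records holding
symbols outside the 4-letter alphabet are dropped (the 2-bit packing used by
overlap detection admits no ambiguity codes) and counted.
"""

from __future__ import annotations

import gzip
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"

#: maximum number of bases packed into one integer key (2 bits/base per
#: machine word; a second word would be needed beyond this)
KEY_CAPACITY = 32


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement.  Involution: rc(rc(s)) == s."""
    if any(c not in "ACGTN" for c in s):
        raise ValueError(f"non-ACGT symbol in sequence: {s[:20]!r}...")
    return s.translate(_COMPLEMENT)[::-1]


def encode_2bit(s: str) -> int:
    """Pack a DNA string into an integer, 2 bits per base (A=0,C=1,G=2,T=3).

    Injective on fixed-length inputs.  Supports O(1) rolling updates via
    :func:`roll_2bit`.
    """
    if len(s) > KEY_CAPACITY:
        raise ValueError(
            f"sequence length {len(s)} exceeds key capacity {KEY_CAPACITY}"
        )
    key = 0
    try:
        for c in s:
            key = (key << 2) | _CODE[c]
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc} in sequence") from None
    return key


def decode_2bit(key: int, length: int) -> str:
    out = []
    for i in range(length):
        out.append(_BASE[(key >> (2 * (length - 1 - i))) & 3])
    return "".join(out)


def roll_2bit(key: int, new_base: str, window: int) -> int:
    """Slide a fixed-length window one base: drop the leading base, append
    ``new_base``.  Identity: roll(encode(s[i:i+w]), s[i+w], w) == encode(s[i+1:i+w+1])."""
    mask = (1 << (2 * window)) - 1
    return ((key << 2) | _CODE[new_base]) & mask


@dataclass
class Read:
    """One input read.  ``mate_id`` links the two reads of a mate pair."""

    read_id: str
    sequence: str
    mate_id: Optional[str] = None
    mate_end: Optional[str] = None  # "first" | "second"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """Ordered collection of sanitized reads.

    ``n`` is the read count and, for uniform-length inputs, ``length`` is the
    common read length ℓ.
    """

    reads: list = field(default_factory=list)
    dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.reads)

    @property
    def uniform_length(self) -> bool:
        return len({len(r) for r in self.reads}) <= 1

    @property
    def length(self) -> int:
        """Read length ℓ (the maximum length for non-uniform inputs)."""
        if not self.reads:
            return 0
        return max(len(r) for r in self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def mate_pairs(self) -> list:
        """Unordered mate pairs as (index1, index2), each pair once."""
        index = {r.read_id: i for i, r in enumerate(self.reads)}
        pairs = []
        for i, r in enumerate(self.reads):
            if r.mate_id is not None and r.mate_end == "first":
                j = index.get(r.mate_id)
                if j is not None:
                    pairs.append((i, j))
        return pairs


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: not FASTA/FASTQ (first record starts {line[:1]!r})")
    raise ValueError(f"{path}: empty input")


def _iter_records(path, fmt: str):
    with _open_text(path) as fh:
        num = 0
        try:
            for rec in SeqIO.parse(fh, fmt):
                num += 1
                yield rec
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record {num + 1}: {exc}") from exc
    if num == 0:
        raise ValueError(f"{path}: empty input")


def _strip_pair_suffix(name: str) -> Tuple[str, Optional[str]]:
    if name.endswith("/1"):
        return name[:-2], "first"
    if name.endswith("/2"):
        return name[:-2], "second"
    return name, None


def parse_reads(
    path,
    format: str = "auto",
    mate_path=None,
    non_acgt: str = "drop",
    seed: int = 0,
) -> ReadSet:
    """Parse FASTQ/FASTA into a :class:`ReadSet`.

    Mate linkage is inferred from a second file (``mate_path``, paired by
    record order) or from /1, /2 read-name suffixes of interleaved input.
    Reads containing non-ACGT symbols are dropped and counted
    (``non_acgt="drop"``) or have those symbols replaced by seeded random
    bases (``non_acgt="mask"``).  Quality strings are read and discarded.
    """
    if non_acgt not in ("drop", "mask"):
        raise ValueError("non_acgt must be 'drop' or 'mask'")
    rng = random.Random(seed)
    rs = ReadSet()

    def sanitize(seq: str) -> Optional[str]:
        seq = seq.upper()
        if all(c in "ACGT" for c in seq):
            return seq
        if non_acgt == "drop":
            return None
        return "".join(c if c in "ACGT" else rng.choice("ACGT") for c in seq)

    def load(p) -> list:
        fmt = _sniff_format(p) if format == "auto" else format
        out = []
        for rec in _iter_records(p, fmt):
            seq = sanitize(str(rec.seq))
            if seq is None:
                rs.dropped += 1
                continue
            out.append(Read(rec.id, seq))
        return out

    if mate_path is not None:
        first = load(path)
        second = load(mate_path)
        for a, b in zip(first, second):
            a.mate_id, a.mate_end = b.read_id, "first"
            b.mate_id, b.mate_end = a.read_id, "second"
            if a.read_id == b.read_id:  # identical names in both files
                a.read_id += "/1"
                b.read_id += "/2"
                a.mate_id, b.mate_id = b.read_id, a.read_id
        rs.reads = first + second
    else:
        reads = load(path)
        # pair interleaved /1,/2 names
        by_stem = {}
        for r in reads:
            stem, end = _strip_pair_suffix(r.read_id)
            if end is not None:
                by_stem.setdefault(stem, {})[end] = r
        for stem, ends in by_stem.items():
            if "first" in ends and "second" in ends:
                a, b = ends["first"], ends["second"]
                a.mate_id, a.mate_end = b.read_id, "first"
                b.mate_id, b.mate_end = a.read_id, "second"
        rs.reads = reads

    if rs.dropped:
        logger.info("dropped %d reads containing non-ACGT symbols", rs.dropped)
    if rs.n == 0:
        raise ValueError("no usable reads after sanitization")
    return rs


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 70) -> None:
    """Write (id, sequence) records as FASTA with fixed line width.

    N symbols are permitted (scaffold gaps).  Duplicate ids are an error.
    """
    records = list(records)
    seen = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r}")
        seen.add(rid)
    if not records:
        logger.warning("write_fasta: no records, writing empty file %s", path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
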