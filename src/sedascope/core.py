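"""Shared primitive types: reads, alignments, nucleotide encoding.

Coordinates are 0-based half-open everywhere. Reference sequences are
circular; alignment coordinates live on the linearised circle (start in
[0, L), end may exceed L for origin-spanning reads) and are mapped back
modulo L when consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: nucleotide → integer code; N = 4 (matches nothing, scored as mismatch)
BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class MalformedRecordError(ValueError):
    """A read record violates its structural contract (e.g. seq/qual length)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def is_transversion(a: str, b: str) -> bool:
    """True if a↔b is a purine↔pyrimidine substitution."""
    return (a in PURINES) != (b in PURINES) and a != b and {a, b} <= set("ACGT")


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise MalformedRecordError(f"non-ACGTN character {exc.args[0]!r}") from exc


@dataclass
class Read:
    """A sequencing read: id, nucleotide string, phred+33 quality string.

    ``meta`` carries simulation truth (species, donor, contaminant flag, ...)
    when the read came from the simulator; it is never consulted by the
    analysis stages.
    """

    id: str
    seq: str
    qual: str
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        if len(self.seq) != len(self.qual):
            raise MalformedRecordError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


@dataclass
class ReadAlignment:
    """Placement of a read on a circular reference.

    The alignment is between the *oriented* read (the read as sequenced for
    '+' hits, its reverse complement for '-' hits) and the forward reference
    starting at ``ref_start`` on the linearised circle. ``cigar`` is a list
    of (op, length) with op in {'M','I','D'}: M consumes both, I consumes
    oriented-read only, D consumes reference only.
    """

    read: Read
    species_id: str
    ref_start: int
    strand: str  # '+' or '-'
    cigar: list = None  # defaults to a single full-length M

    def __post_init__(self):
        if self.cigar is None:
            self.cigar = [("M", len(self.read.seq))]

    @property
    def oriented_seq(self) -> str:
        return self.read.seq if self.strand == "+" else revcomp(self.read.seq)

    @property
    def n_aligned_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    def aligned_pairs(self):
        """Yield (oriented_read_pos, ref_pos_on_linearised_circle) for M columns."""
        q = 0
        r = self.ref_start
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield q + k, r + k
                q += n
                r += n
            elif op == "I":
                q += n
            elif op == "D":
                r += n
            else:  # pragma: no cover - contract guard
                raise ValueError(f"unknown cigar op {op!r}")
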