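"""Read-level QC: poly-A trimming, length, base-quality and duplicate filters.

Filter order is fixed: (0) trim a terminal poly-A run, (1) drop reads shorter
than 30 nt, (2) drop reads where ≥25% of bases are below Q30 (boundary
inclusive), (3) drop exact sequence duplicates keeping the first occurrence.
Duplicates are defined on the nucleotide string only — dereplication happens
before alignment, where qualities play no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MalformedRecordError, Read

#: minimum run length for a 3' poly-A tail to be trimmed (the tail-trimming
#: threshold is a package default; only the fact of trimming is prescribed)
POLYA_MIN_RUN = 8


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_short: int = 0
    n_removed_lowq: int = 0
    n_removed_duplicate: int = 0
    n_passed: int = 0

    def validate(self) -> None:
        removed = self.n_removed_short + self.n_removed_lowq + self.n_removed_duplicate
        assert self.n_input == self.n_passed + removed, "QC counts must chain"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def trim_poly_a(read: Read, min_run: int = POLYA_MIN_RUN) -> Read:
    """Remove a terminal run of >= min_run A's from the 3' end."""
    seq = read.seq
    n = len(seq)
    k = n
    while k > 0 and seq[k - 1] == "A":
        k -= 1
    if n - k >= min_run:
        return Read(read.id, seq[:k], read.qual[:k], read.meta)
    return read


def filter_reads(
    reads: list,
    min_length: int = 30,
    qual_threshold: int = 30,
    max_lowq_fraction: float = 0.25,
    trim_polya: bool = True,
    polya_min_run: int = POLYA_MIN_RUN,
):
    """Apply the QC cascade; returns (passed_reads, QCReport).

    A read fails the quality filter when the fraction of bases with phred
    quality < ``qual_threshold`` is >= ``max_lowq_fraction`` (boundary inclusive).
    """
    report = QCReport(n_input=len(reads))
    passed = []
    seen = set()
    for read in reads:
        read.validate()
        if trim_polya:
            read = trim_poly_a(read, polya_min_run)
        if len(read.seq) < min_length:
            report.n_removed_short += 1
            continue
        n_lowq = sum(1 for q in read.qual if ord(q) - 33 < qual_threshold)
        if n_lowq / len(read.seq) >= max_lowq_fraction:
            report.n_removed_lowq += 1
            continue
        if read.seq in seen:
            report.n_removed_duplicate += 1
            continue
        seen.add(read.seq)
        passed.append(read)
    report.n_passed = len(passed)
    report.validate()
    return passed, report
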