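"""Pileups, masked majority-rule consensus, and the MAF diversity statistic.

Consensus: a site is called as the most frequent base when depth >= 5,
masked to N below that or on an exact tie (masking is the conservative
choice for phylogenetic use). Diversity: only sites with depth strictly
greater than 5 are considered; a site is variable when the second most
frequent base has frequency > 0.21 with at least 2 supporting reads —
counted over all substitutions, and separately over transversions only,
which deamination (a transition process) cannot create.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BASES, ReadAlignment, is_transversion


class PileupError(RuntimeError):
    """An alignment fell outside the doubled-reference frame."""


def build_pileup(alignments: list, reference: str) -> np.ndarray:
    """Per-position A/C/G/T counts, shape (L, 4); circular wrap via modulo.

    Aligned read bases only: insertions are ignored, deletions contribute
    nothing, N bases are excluded.
    """
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    code = {b: i for i, b in enumerate(BASES)}
    for aln in alignments:
        oriented = aln.oriented_seq
        for q, r in aln.aligned_pairs():
            if r >= 2 * L or r < 0:
                raise PileupError(
                    f"read {aln.read.id}: position {r} outside doubled reference"
                )
            c = code.get(oriented[q])
            if c is not None:
                counts[r % L, c] += 1
    return counts


@dataclass
class ConsensusGenome:
    sequence: str  # over {A,C,G,T,N}
    depth: np.ndarray
    n_called: int
    mean_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


def call_consensus(pileup: np.ndarray, min_depth: int = 5) -> ConsensusGenome:
    """Majority allele per site; N below ``min_depth`` or on a top-count tie."""
    depth = pileup.sum(axis=1)
    top = pileup.max(axis=1)
    argtop = pileup.argmax(axis=1)
    tie = (pileup == top[:, None]).sum(axis=1) > 1
    callable_ = (depth >= min_depth) & ~tie
    bases = np.array(list(BASES))
    seq = np.where(callable_, bases[argtop], "N")
    return ConsensusGenome(
        sequence="".join(seq),
        depth=depth,
        n_called=int(callable_.sum()),
        mean_coverage=float(depth.mean()) if depth.size else float("nan"),
    )


@dataclass
class SiteRecord:
    position: int  # 0-based
    depth: int
    major: str
    major_freq: float
    minor: str
    minor_freq: float
    minor_count: int
    is_transversion: bool


@dataclass
class DiversityReport:
    n_sites_considered: int
    n_variable_all: int
    n_variable_tv: int
    records: list = field(default_factory=list)
    mode: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def variable_sites(
    pileup: np.ndarray,
    min_depth_exclusive: int = 5,
    maf_min: float = 0.21,
    min_minor_reads: int = 2,
    mode: str = "all",
) -> DiversityReport:
    """Variable-position scan of a pileup.

    MAF is the frequency of the second most frequent base (third alleles are
    ignored for the MAF but count toward depth). ``mode='transversions_only'``
    restricts the reported records to sites whose major/minor pair is a
    purine↔pyrimidine change; both counts are always reported.
    """
    if mode not in ("all", "transversions_only"):
        raise ValueError(f"unknown mode {mode!r}")
    depth = pileup.sum(axis=1)
    considered = np.flatnonzero(depth > min_depth_exclusive)
    n_all = 0
    n_tv = 0
    records = []
    for pos in considered:
        row = pileup[pos]
        order = np.argsort(row, kind="stable")[::-1]
        major_i, minor_i = int(order[0]), int(order[1])
        minor_count = int(row[minor_i])
        d = int(depth[pos])
        maf = minor_count / d
        if not (maf > maf_min and minor_count >= min_minor_reads):
            continue
        tv = is_transversion(BASES[major_i], BASES[minor_i])
        n_all += 1
        if tv:
            n_tv += 1
        if mode == "all" or tv:
            records.append(
                SiteRecord(
                    position=int(pos),
                    depth=d,
                    major=BASES[major_i],
                    major_freq=float(row[major_i]) / d,
                    minor=BASES[minor_i],
                    minor_freq=maf,
                    minor_count=minor_count,
                    is_transversion=tv,
                )
            )
    return DiversityReport(
        n_sites_considered=int(considered.size),
        n_variable_all=n_all,
        n_variable_tv=n_tv,
        records=records,
        mode=mode,
    )


@dataclass
class MultiDonorEvidence:
    flag: bool
    n_transversion_sites: int
    sites: list  # supporting transversion SiteRecords


def multi_donor_flag(report: DiversityReport) -> MultiDonorEvidence:
    """Multiple-individual evidence: any variable transversion site.

    Transversions cannot be produced by deamination, so a single supported
    transversion site (MAF > 0.21, >= 2 reads) indicates a second donor
    haplotype rather than damage.
    """
    tv_sites = [r for r in report.records if r.is_transversion]
    return MultiDonorEvidence(
        flag=report.n_variable_tv >= 1,
        n_transversion_sites=report.n_variable_tv,
        sites=tv_sites,
    )
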