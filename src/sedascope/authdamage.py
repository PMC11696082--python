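"""Empirical deamination profiles, read-length summaries, authentication gates.

The damage profile is computed directly from aligned reads: at 5' read
offset i, the C→T frequency is the number of aligned columns where the
reference (read-oriented) base is C and the read base is T, divided by the
number of columns with a reference C at that offset; mirrored as G→A from
the 3' end. Frequencies with a zero denominator are undefined (NaN), never 0.

Authentication follows the double-stranded-library criterion: a taxon is
accepted as ancient only with >= 50 assigned reads and terminal conversion
rates strictly above 0.2 on *both* ends. Phylogeny-grade genomes additionally
require mean coverage strictly above 5x and a terminal rate above 0.4 on at
least one end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Read, ReadAlignment, complement


@dataclass
class DamageProfile:
    five_prime_ct: np.ndarray  # C→T frequency at 5' offsets 0..K-1 (NaN if undefined)
    three_prime_ga: np.ndarray  # G→A frequency at 3' offsets 0..K-1
    denom_5p: np.ndarray  # reference-C counts per 5' offset
    denom_3p: np.ndarray  # reference-G counts per 3' offset

    @property
    def terminal_5p(self) -> float:
        return float(self.five_prime_ct[0])

    @property
    def terminal_3p(self) -> float:
        return float(self.three_prime_ga[0])


def damage_profile(alignments: list, reference: str, K: int = 15) -> DamageProfile:
    """Terminal C→T / G→A frequencies over the first/last K read positions.

    ``alignments`` are :class:`~sedascope.core.ReadAlignment` records on the
    given circular reference; gap columns are skipped. Reads aligned on the
    '-' strand are profiled in sequencing orientation (the reference base is
    complemented, the offset mirrored), because deamination lives on the
    molecule's ends as sequenced, not on the genome's.
    """
    L = len(reference)
    num5 = np.zeros(K, dtype=np.int64)
    den5 = np.zeros(K, dtype=np.int64)
    num3 = np.zeros(K, dtype=np.int64)
    den3 = np.zeros(K, dtype=np.int64)
    for aln in alignments:
        seq = aln.read.seq
        n = len(seq)
        minus = aln.strand == "-"
        for q, r in aln.aligned_pairs():
            ref_base = reference[r % L]
            if minus:
                p = n - 1 - q
                ref_base = complement(ref_base)
            else:
                p = q
            read_base = seq[p]
            if p < K and ref_base == "C":
                den5[p] += 1
                if read_base == "T":
                    num5[p] += 1
            p3 = n - 1 - p
            if p3 < K and ref_base == "G":
                den3[p3] += 1
                if read_base == "A":
                    num3[p3] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), np.nan)
        f3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), np.nan)
    return DamageProfile(
        five_prime_ct=f5, three_prime_ga=f3, denom_5p=den5, denom_3p=den3
    )


@dataclass
class LengthSummary:
    n: int
    mean: float
    median: float
    min: int
    max: int
    histogram: dict  # length -> count

    @classmethod
    def empty(cls) -> "LengthSummary":
        return cls(0, float("nan"), float("nan"), 0, 0, {})


def length_summary(reads: list) -> LengthSummary:
    lengths = np.array([len(r.seq if isinstance(r, Read) else r) for r in reads])
    if lengths.size == 0:
        return LengthSummary.empty()
    values, counts = np.unique(lengths, return_counts=True)
    return LengthSummary(
        n=int(lengths.size),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        min=int(lengths.min()),
        max=int(lengths.max()),
        histogram={int(v): int(c) for v, c in zip(values, counts)},
    )


def mean_coverage(alignments: list, ref_length: int) -> float:
    """Total aligned read bases over the full reference length."""
    return sum(a.n_aligned_bases for a in alignments) / ref_length


@dataclass
class TaxonProfile:
    taxon_id: str
    n_reads: int
    damage: DamageProfile
    lengths: LengthSummary
    mean_coverage: float = float("nan")
    authenticated: bool = False
    phylo_grade: bool = False


def profile_taxon(taxon_id: str, alignments: list, reference: str, K: int = 15) -> TaxonProfile:
    return TaxonProfile(
        taxon_id=taxon_id,
        n_reads=len(alignments),
        damage=damage_profile(alignments, reference, K=K),
        lengths=length_summary([a.read for a in alignments]),
        mean_coverage=mean_coverage(alignments, len(reference)),
    )


@dataclass
class Decision:
    passed: bool
    reasons: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def authenticate(
    profile: TaxonProfile, min_reads: int = 50, min_terminal: float = 0.2
) -> Decision:
    """Ancient-DNA presence call: read support and damage on both ends.

    Strict inequalities throughout (">20%" means 0.20 exactly fails).
    """
    reasons = []
    if profile.n_reads < min_reads:
        reasons.append(f"read count {profile.n_reads} < {min_reads}")
    t5, t3 = profile.damage.terminal_5p, profile.damage.terminal_3p
    for label, value in (("5p C>T", t5), ("3p G>A", t3)):
        if np.isnan(value):
            reasons.append(f"{label}: insufficient terminal context")
        elif not value > min_terminal:
            reasons.append(f"{label} terminal rate {value:.3f} not > {min_terminal}")
    return Decision(passed=not reasons, reasons=reasons)


def grade_for_phylogenetics(
    profile: TaxonProfile, min_mean_cov: float = 5.0, min_terminal: float = 0.4
) -> Decision:
    """Partial-genome gate: mean coverage > 5x and strong terminal damage."""
    reasons = []
    if not profile.mean_coverage > min_mean_cov:
        reasons.append(
            f"mean coverage {profile.mean_coverage:.2f} not > {min_mean_cov}"
        )
    t5, t3 = profile.damage.terminal_5p, profile.damage.terminal_3p
    if np.isnan(t5) and np.isnan(t3):
        reasons.append("terminal damage undefined: insufficient terminal context")
    else:
        best = np.nanmax([t5, t3])
        if not best > min_terminal:
            reasons.append(f"terminal rate {best:.3f} not > {min_terminal}")
    return Decision(passed=not reasons, reasons=reasons)


def profile_table(profiles: list) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "taxon": p.taxon_id,
                "n_reads": p.n_reads,
                "terminal_5p_ct": p.damage.terminal_5p,
                "terminal_3p_ga": p.damage.terminal_3p,
                "mean_coverage": p.mean_coverage,
                "mean_length": p.lengths.mean,
                "authenticated": p.authenticated,
                "phylo_grade": p.phylo_grade,
            }
        )
    return pd.DataFrame(rows)
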