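"""Synthetic sedaDNA: taxonomies, mitogenome panels, donors, damaged reads.

The generator emulates the signal structure of capture-enriched sediment
libraries: very short fragments (modal length 40–60 nt, with a tail below the
30-nt QC cut), terminal cytosine deamination read as C→T at the 5' end and
G→A at the 3' end of double-stranded libraries, independent per-base
sequencing error, undamaged modern contaminant molecules, and mixtures of
several donor haplotypes per species distinguished by private variants.

Damage follows a geometric decay from each read end: a 5' C at 0-based
offset ``i`` is converted with probability ``d_max_5p * decay**i`` and
symmetrically for 3' G→A. Damage is applied to the read *as sequenced*
(after orientation), since deamination is a fragment-end phenomenon.
Fragment lengths are lower-truncated normal; note that truncation raises the
mean of the emitted law above the configured location parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BASES, Read, ReadAlignment, is_transversion, revcomp

_HIGH_QUAL = "I"  # phred 40
_LOW_QUAL = "#"  # phred 2


class ParameterError(ValueError):
    """A simulation parameter is outside its documented domain."""


@dataclass
class SimTaxonomy:
    """Rank-labelled rooted taxonomy: (id, parent_id, rank) rows.

    The root has parent_id == its own id (NCBI convention). Ranks are
    root / family / genus / species.
    """

    nodes: list
    seed: int = 0

    def validate(self) -> None:
        ids = [n[0] for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ParameterError("duplicate taxonomy ids")
        parent = {i: p for i, p, _ in self.nodes}
        rank = {i: r for i, _, r in self.nodes}
        roots = [i for i, p, r in self.nodes if r == "root"]
        if len(roots) != 1 or parent[roots[0]] != roots[0]:
            raise ParameterError("taxonomy must have exactly one self-parented root")
        for sp in self.species_ids():
            seen = set()
            node = sp
            lineage_ranks = set()
            while parent[node] != node:
                if node in seen:
                    raise ParameterError("taxonomy contains a cycle")
                seen.add(node)
                node = parent[node]
                lineage_ranks.add(rank[node])
            if not {"genus", "family"} <= lineage_ranks:
                raise ParameterError(f"species {sp} lacks a genus or family ancestor")

    def species_ids(self) -> list:
        return [i for i, _, r in self.nodes if r == "species"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nodes, columns=["id", "parent_id", "rank"])


@dataclass
class DamageModel:
    """Terminal-deamination + sequencing-error model.

    d_max_5p / d_max_3p: conversion probability at the terminal base;
    decay: geometric per-offset decay ratio in (0, 1];
    seq_error: independent per-base miscall probability.
    """

    d_max_5p: float = 0.3
    d_max_3p: float = 0.3
    decay: float = 0.5
    seq_error: float = 0.001

    def __post_init__(self):
        for name in ("d_max_5p", "d_max_3p", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ParameterError(f"decay={self.decay} outside (0, 1]")

    @classmethod
    def none(cls) -> "DamageModel":
        return cls(0.0, 0.0, 1.0, 0.0)


@dataclass
class DonorSet:
    """Haplotypes of the individuals contributing a species' fragments."""

    species_id: str
    haplotypes: list
    private_variants: list = field(default_factory=list)  # (pos, ref, alt, is_tv)
    mixture_weights: list = None

    def __post_init__(self):
        if not self.haplotypes:
            raise ParameterError("DonorSet needs at least one haplotype")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ParameterError("haplotypes must have equal length")
        if self.mixture_weights is None:
            self.mixture_weights = [1.0 / len(self.haplotypes)] * len(self.haplotypes)
        if len(self.mixture_weights) != len(self.haplotypes):
            raise ParameterError("one mixture weight per haplotype required")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")


@dataclass
class TruthRow:
    read_id: str
    species_id: str
    donor: int
    start: int  # 0-based on the circular reference
    strand: str
    length: int
    damage_offsets: tuple  # read-as-sequenced offsets altered by deamination
    error_offsets: tuple  # offsets altered by sequencing error
    contaminant: bool = False


def truth_to_frame(truth: list) -> pd.DataFrame:
    rows = [
        (
            t.read_id, t.species_id, t.donor, t.start, t.strand, t.length,
            ",".join(map(str, t.damage_offsets)),
            ",".join(map(str, t.error_offsets)),
            int(t.contaminant),
        )
        for t in truth
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "species_id", "donor", "start", "strand", "length",
            "damage_offsets", "error_offsets", "contaminant",
        ],
    )


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a uniform other base."""
    out = seq_codes.copy()
    hits = np.flatnonzero(rng.random(out.shape[0]) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def build_panel(
    n_families: int,
    genera_per_family: int,
    species_per_genus: int,
    ref_length: int,
    divergence: float,
    seed: int,
):
    """Simulate a taxonomy and one circular reference per species.

    A random root sequence is mutated independently along each edge of the
    root→family→genus→species tree at ``divergence`` substitutions per site
    per edge, so within-genus species pairs are ~2·divergence apart and
    between-family pairs ~6·divergence.
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise ParameterError("all taxon counts must be >= 1")
    if not 0.0 < divergence <= 0.3:
        raise ParameterError(f"divergence={divergence} outside (0, 0.3]")
    if ref_length < 200:
        raise ParameterError(f"ref_length={ref_length} < 200")

    rng = np.random.default_rng(seed)
    root_codes = rng.integers(0, 4, ref_length).astype(np.int8)
    nodes = [("root", "root", "root")]
    entries = {}
    for f in range(1, n_families + 1):
        fam = f"fam{f}"
        nodes.append((fam, "root", "family"))
        fam_codes = _mutate(root_codes, divergence, rng)
        for g in range(1, genera_per_family + 1):
            gen = f"{fam}_gen{g}"
            nodes.append((gen, fam, "genus"))
            gen_codes = _mutate(fam_codes, divergence, rng)
            for s in range(1, species_per_genus + 1):
                sp = f"{gen}_sp{s}"
                nodes.append((sp, gen, "species"))
                entries[sp] = _decode(_mutate(gen_codes, divergence, rng))
    taxonomy = SimTaxonomy(nodes=nodes, seed=seed)
    taxonomy.validate()
    return taxonomy, entries


def make_donors(
    species_id: str,
    reference: str,
    n_donors: int,
    n_private_variants: int,
    seed: int,
    transversions_only: bool = False,
    weights: list = None,
) -> DonorSet:
    """Derive donor haplotypes from a reference by planting private variants.

    Donor 0 carries the reference; each variant is private to one of the
    other donors (round-robin). With ``transversions_only`` every planted
    allele is a purine↔pyrimidine change, i.e. immune to deamination mimicry.
    """
    if n_donors < 1:
        raise ParameterError("n_donors must be >= 1")
    rng = np.random.default_rng(seed)
    haps = [list(reference) for _ in range(n_donors)]
    variants = []
    if n_donors > 1 and n_private_variants > 0:
        positions = rng.choice(len(reference), size=n_private_variants, replace=False)
        for k, pos in enumerate(sorted(int(p) for p in positions)):
            donor = 1 + k % (n_donors - 1)
            ref_base = reference[pos]
            if transversions_only:
                alts = [b for b in BASES if is_transversion(ref_base, b)]
            else:
                alts = [b for b in BASES if b != ref_base]
            alt = alts[rng.integers(0, len(alts))]
            haps[donor][pos] = alt
            variants.append((pos, ref_base, alt, is_transversion(ref_base, alt)))
    return DonorSet(
        species_id=species_id,
        haplotypes=["".join(h) for h in haps],
        private_variants=variants,
        mixture_weights=weights,
    )


def _apply_damage(seq: list, d5: float, d3: float, decay: float, rng) -> list:
    """C→T from the 5' end, G→A from the 3' end; returns altered offsets."""
    n = len(seq)
    offsets = []
    if d5 > 0:
        for i in range(n):
            p = d5 * decay**i
            if p < 1e-12:
                break
            if seq[i] == "C" and rng.random() < p:
                seq[i] = "T"
                offsets.append(i)
    if d3 > 0:
        for k in range(n):
            p = d3 * decay**k
            if p < 1e-12:
                break
            i = n - 1 - k
            if seq[i] == "G" and rng.random() < p:
                seq[i] = "A"
                offsets.append(i)
    return sorted(set(offsets))


def simulate_reads(
    reference: str,
    donors: DonorSet,
    n_reads: int,
    length_law: tuple = (45.0, 10.0, 30),
    damage: DamageModel = None,
    seed: int = 0,
    read_prefix: str = None,
    contaminant: bool = False,
    lower_error_qual: bool = False,
):
    """Draw damaged short reads from a circular reference / donor mixture.

    length_law = (mean, sd, min_emitted): lower-truncated normal, rounded to
    int. Start positions are uniform on the circle, strands uniform. Returns
    (reads, truth) where truth is a list of :class:`TruthRow`.
    """
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    mean, sd, min_emitted = length_law
    if min_emitted < 15:
        raise ParameterError("min_emitted must be >= 15")
    if mean <= min_emitted:
        raise ParameterError("length mean must exceed min_emitted")
    damage = damage or DamageModel()
    rng = np.random.default_rng(seed)
    prefix = read_prefix or donors.species_id
    L = len(reference)

    a = (min_emitted - mean) / sd
    lengths = stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=n_reads, random_state=rng
    )
    lengths = np.maximum(np.rint(lengths).astype(int), int(min_emitted))
    donor_idx = rng.choice(len(donors.haplotypes), size=n_reads, p=donors.mixture_weights)
    starts = rng.integers(0, L, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)

    reads, truth = [], []
    for k in range(n_reads):
        length = int(lengths[k])
        start = int(starts[k])
        hap = donors.haplotypes[int(donor_idx[k])]
        frag = (hap + hap)[start : start + length]  # doubled string handles wrap
        strand = "+" if strands[k] == 0 else "-"
        seq = list(frag) if strand == "+" else list(revcomp(frag))
        dmg = _apply_damage(seq, damage.d_max_5p, damage.d_max_3p, damage.decay, rng)
        errs = []
        if damage.seq_error > 0:
            for i in np.flatnonzero(rng.random(length) < damage.seq_error):
                i = int(i)
                seq[i] = BASES[(BASES.index(seq[i]) + int(rng.integers(1, 4))) % 4]
                errs.append(i)
        qual = [_HIGH_QUAL] * length
        if lower_error_qual:
            for i in errs:
                qual[i] = _LOW_QUAL
        rid = f"{prefix}_r{k}"
        reads.append(
            Read(
                id=rid,
                seq="".join(seq),
                qual="".join(qual),
                meta={"species_id": donors.species_id, "contaminant": contaminant},
            )
        )
        truth.append(
            TruthRow(
                read_id=rid,
                species_id=donors.species_id,
                donor=int(donor_idx[k]),
                start=start,
                strand=strand,
                length=length,
                damage_offsets=tuple(dmg),
                error_offsets=tuple(errs),
                contaminant=contaminant,
            )
        )
    return reads, truth


def simulate_contamination(
    reference: str,
    n_reads: int,
    seed: int = 0,
    species_id: str = "contaminant",
    length_law: tuple = (80.0, 15.0, 30),
    read_prefix: str = None,
):
    """Undamaged modern reads: longer fragments, zero deamination."""
    donors = DonorSet(species_id=species_id, haplotypes=[reference])
    return simulate_reads(
        reference,
        donors,
        n_reads,
        length_law=length_law,
        damage=DamageModel.none(),
        seed=seed,
        read_prefix=read_prefix or f"{species_id}_modern",
        contaminant=True,
    )


def alignments_from_truth(reads: list, truth: list, species_id: str = None) -> list:
    """Gapless :class:`ReadAlignment` records straight from simulation truth.

    Bypasses the aligner for stages whose contract takes alignments as
    input (damage profiling, pileups); coordinates are exact by construction.
    """
    by_id = {t.read_id: t for t in truth}
    out = []
    for read in reads:
        t = by_id[read.id]
        if species_id is not None and t.species_id != species_id:
            continue
        out.append(
            ReadAlignment(
                read=read,
                species_id=t.species_id,
                ref_start=t.start,
                strand=t.strand,
                cigar=[("M", len(read.seq))],
            )
        )
    return out
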