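"""Taxonomic read assignment: panel alignment, hit retention, LCA, call gates.

Each read is aligned semi-globally against every panel mitogenome (doubled,
to honour circularity) in both orientations; the best hit per species is
kept. Hits below 90% identity are dropped and, of the survivors, those
within 10% of the best score are retained (the MEGAN-style top-percent
rule). The read is assigned to the lowest common ancestor of the retained
species. Presence calls then require 50 fragments per family and 100
supporting reads per genus/species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .core import MalformedRecordError, Read, ReadAlignment, encode, revcomp


class TaxonomyError(KeyError):
    """Unknown taxonomy node referenced."""


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


@dataclass
class AlignmentHit:
    read_id: str
    species_id: str
    score: int
    identity: float  # matched columns / aligned columns (gap columns count)
    ref_start: int  # 0-based on the linearised circle, < reference length
    ref_end: int  # exclusive; may exceed reference length for wrapping hits
    strand: str
    cigar: list = field(default_factory=list)

    def to_alignment(self, read: Read) -> ReadAlignment:
        return ReadAlignment(
            read=read,
            species_id=self.species_id,
            ref_start=self.ref_start,
            strand=self.strand,
            cigar=list(self.cigar),
        )


class Taxonomy:
    """Rooted rank-labelled taxonomy with LCA queries.

    Accepts the simulator's node list or a (id, parent_id, rank) TSV. Small
    trees (a capture panel, not nt): ancestor chains are walked directly.
    """

    def __init__(self, nodes: list):
        self.nodes = list(nodes)
        self.parent = {i: p for i, p, _ in self.nodes}
        self.rank = {i: r for i, _, r in self.nodes}
        roots = [i for i, p, _ in self.nodes if p == i]
        if len(roots) != 1:
            raise TaxonomyError("taxonomy must have exactly one self-parented root")
        self.root = roots[0]
        self._children = {}
        for i, p, _ in self.nodes:
            if i != p:
                self._children.setdefault(p, []).append(i)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        return cls(list(df[["id", "parent_id", "rank"]].itertuples(index=False, name=None)))

    def ancestors(self, node: str) -> list:
        """node itself up to the root, inclusive."""
        if node not in self.parent:
            raise TaxonomyError(f"unknown taxonomy node {node!r}")
        chain = [node]
        while self.parent[chain[-1]] != chain[-1]:
            chain.append(self.parent[chain[-1]])
        return chain

    def descendants(self, node: str) -> list:
        out = [node]
        stack = list(self._children.get(node, []))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children.get(n, []))
        return out

    def ancestor_at_rank(self, node: str, rank: str):
        for a in self.ancestors(node):
            if self.rank[a] == rank:
                return a
        return None

    def species_ids(self) -> list:
        return [i for i, _, r in self.nodes if r == "species"]


def lca(species: set, taxonomy: Taxonomy) -> str:
    """Lowest node ancestral to every species in the set (itself included)."""
    species = list(species)
    if not species:
        raise TaxonomyError("LCA of an empty set is undefined")
    common = set(taxonomy.ancestors(species[0]))
    for sp in species[1:]:
        common &= set(taxonomy.ancestors(sp))
    # the lowest common node is the one with the longest chain to the root
    return max(common, key=lambda n: len(taxonomy.ancestors(n)))


class PanelIndex:
    """Encoded doubled references plus an optional k-mer seed index."""

    def __init__(self, entries: dict, k: int = 12):
        self.entries = dict(entries)
        self.k = k
        self.lengths = {sp: len(seq) for sp, seq in self.entries.items()}
        self.doubled = {sp: encode(seq + seq) for sp, seq in self.entries.items()}
        self._kmer_index = None

    def kmer_index(self) -> dict:
        """kmer string → list of (species, strand, ref_offset_on_doubled)."""
        if self._kmer_index is None:
            idx = {}
            k = self.k
            for sp, seq in self.entries.items():
                for strand, s in (("+", seq + seq), ("-", revcomp(seq + seq))):
                    for j in range(len(s) - k + 1):
                        idx.setdefault(s[j : j + k], []).append((sp, strand, j))
            self._kmer_index = idx
        return self._kmer_index


def _hit_from_orientation(read_codes, ref_codes, L, scoring, j_end=None, margin=32):
    sc = scoring
    if j_end is None:
        score, j_end = _align.sg_score(
            read_codes, ref_codes, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
        )
    else:
        score = None
    tb = _align.traceback_window(
        read_codes, ref_codes, int(j_end), sc.match, sc.mismatch, sc.gap_open,
        sc.gap_extend, margin=margin,
    )
    if score is not None and tb[0] < score:
        # the default window truncated a long-gap alignment; a 3·read span
        # bounds every alignment that can beat an all-mismatch placement
        tb = _align.traceback_window(
            read_codes, ref_codes, int(j_end),
            sc.match, sc.mismatch, sc.gap_open, sc.gap_extend,
            margin=3 * read_codes.shape[0],
        )
    score, rs, re, n_match, n_cols, cigar = tb
    shift = (rs // L) * L if rs >= L else 0
    return score, rs - shift, re - shift, n_match, n_cols, cigar


def align_read(
    read,
    panel,
    scoring: Scoring = Scoring(),
    method: str = "exhaustive",
) -> list:
    """Best semi-global hit per panel species, over both orientations.

    ``panel`` is a species→sequence mapping or a prebuilt :class:`PanelIndex`.
    ``method='exhaustive'`` scans every species/strand with full DP (exact).
    ``method='seeded'`` only aligns (species, strand) pairs sharing at least
    one k-mer with the read, each within a window around the seed diagonals —
    the standard seed-and-extend shortcut; reads too diverged to share any
    k-mer with a reference produce no hit for it (such hits could never reach
    the 90% identity gate anyway).
    """
    seq = read.seq if isinstance(read, Read) else read
    rid = read.id if isinstance(read, Read) else ""
    if len(seq) < 15:
        raise MalformedRecordError(f"read {rid or seq!r}: shorter than 15 nt")
    if not isinstance(panel, PanelIndex):
        panel = PanelIndex(panel)
    if not panel.entries:
        raise MalformedRecordError("empty reference panel")
    codes = {"+": encode(seq), "-": encode(revcomp(seq))}
    sc = scoring

    hits = []
    if method == "exhaustive":
        for sp, ref_codes in panel.doubled.items():
            L = panel.lengths[sp]
            best = None
            for strand in "+-":
                res = _hit_from_orientation(codes[strand], ref_codes, L, sc)
                if best is None or res[0] > best[1][0]:
                    best = (strand, res)
            strand, (score, rs, re, n_match, n_cols, cigar) = best
            hits.append(
                AlignmentHit(
                    read_id=rid, species_id=sp, score=score,
                    identity=n_match / n_cols if n_cols else 0.0,
                    ref_start=rs, ref_end=re, strand=strand, cigar=cigar,
                )
            )
    elif method == "seeded":
        hits = _align_read_seeded(rid, seq, codes, panel, sc)
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    hits.sort(key=lambda h: (-h.score, h.species_id))
    return hits


def _align_read_seeded(rid, seq, codes, panel, sc):
    k = panel.k
    if len(seq) < k:
        return []
    index = panel.kmer_index()
    # candidate end columns per (species, strand): diagonal + read length
    diagonals = {}
    for q in range(len(seq) - k + 1):
        for sp, strand, j in index.get(seq[q : q + k], ()):
            # seed found on strand s of the reference means the read aligns
            # forward to that strand: oriented read = read for '+', and for
            # '-' the seed position maps to the forward frame by reflection
            if strand == "+":
                diag = j - q
            else:
                n2 = 2 * panel.lengths[sp]
                # read position q on revcomp(ref2) ↔ forward position n2-k-j
                rq = len(seq) - k - q  # position of the seed in revcomp(read)
                diag = (n2 - k - j) - rq
            if diag >= 0:
                diagonals.setdefault((sp, strand), set()).add(diag)
    hits = {}
    for (sp, strand), diags in diagonals.items():
        ref_codes = panel.doubled[sp]
        L = panel.lengths[sp]
        m = len(seq)
        merged = []
        for d in sorted(diags):
            if merged and d - merged[-1][1] <= 8:
                merged[-1][1] = d
            else:
                merged.append([d, d])
        best = None
        for d0, d1 in merged:
            j_end = min(d1 + m + 8, ref_codes.shape[0])
            res = _hit_from_orientation(
                codes[strand], ref_codes, L, sc,
                j_end=j_end, margin=max(32, d1 - d0 + 40),
            )
            if best is None or res[0] > best[0]:
                best = res
        score, rs, re, n_match, n_cols, cigar = best
        prev = hits.get(sp)
        if prev is None or score > prev.score:
            hits[sp] = AlignmentHit(
                read_id=rid, species_id=sp, score=score,
                identity=n_match / n_cols if n_cols else 0.0,
                ref_start=rs, ref_end=re, strand=strand, cigar=cigar,
            )
    return list(hits.values())


def retain_hits(hits: list, min_identity: float = 0.90, top_fraction: float = 0.10) -> set:
    """Species whose hits survive the identity gate and the top-percent rule."""
    survivors = [h for h in hits if h.identity >= min_identity]
    if not survivors:
        return set()
    best = max(h.score for h in survivors)
    floor = (1.0 - top_fraction) * best
    return {h.species_id for h in survivors if h.score >= floor}


@dataclass
class ReadAssignment:
    read_id: str
    node: str  # taxonomy id, or None when unassigned
    retained_species: set
    best_identity: float = float("nan")
    n_hits: int = 0


def assign_read(
    read,
    panel,
    taxonomy: Taxonomy,
    scoring: Scoring = Scoring(),
    min_identity: float = 0.90,
    top_fraction: float = 0.10,
    method: str = "exhaustive",
):
    """align → retain → LCA for one read; returns (assignment, hits)."""
    hits = align_read(read, panel, scoring=scoring, method=method)
    retained = retain_hits(hits, min_identity=min_identity, top_fraction=top_fraction)
    node = lca(retained, taxonomy) if retained else None
    best_ident = max((h.identity for h in hits), default=float("nan"))
    rid = read.id if isinstance(read, Read) else ""
    return (
        ReadAssignment(
            read_id=rid, node=node, retained_species=retained,
            best_identity=best_ident, n_hits=len(hits),
        ),
        hits,
    )


@dataclass
class TaxonCallTable:
    """Support counts and pass/fail flags per taxonomy node.

    ``n_assigned_reads`` of a node counts reads assigned at the node or any
    descendant, so species counts sum into their genus and genus into family;
    reads assigned above a rank count toward ancestors only.
    """

    table: pd.DataFrame
    called_nodes: list  # most specific called nodes (species, or genus without one)
    retained_read_ids: dict  # called node -> list of read ids at/below it

    def to_frame(self) -> pd.DataFrame:
        return self.table


def call_taxa(
    assignments: list,
    taxonomy: Taxonomy,
    family_min: int = 50,
    support_min: int = 100,
) -> TaxonCallTable:
    """Apply the family support gate then genus/species presence calls.

    Families with fewer than ``family_min`` assigned fragments (summing every
    assignment at or below the family) fail and their reads are discarded.
    Within passing families a genus is present with >= ``support_min`` reads
    at the genus or below; a species is called when >= ``support_min`` reads
    resolve to that species specifically. Only reads assigned at or below a
    called node are retained downstream.
    """
    exact = {}
    reads_at = {}
    for a in assignments:
        if a.node is None:
            continue
        exact[a.node] = exact.get(a.node, 0) + 1
        reads_at.setdefault(a.node, []).append(a.read_id)

    def subtree_count(node):
        return sum(exact.get(n, 0) for n in taxonomy.descendants(node))

    def subtree_reads(node):
        out = []
        for n in taxonomy.descendants(node):
            out.extend(reads_at.get(n, []))
        return out

    rows = []
    called_nodes = []
    retained = {}
    families = [i for i, _, r in taxonomy.nodes if r == "family"]
    for fam in families:
        fam_n = subtree_count(fam)
        if fam_n == 0:
            continue
        fam_pass = fam_n >= family_min
        rows.append((fam, "family", fam_n, fam_pass))
        if not fam_pass:
            continue
        for gen in (n for n in taxonomy.descendants(fam) if taxonomy.rank[n] == "genus"):
            gen_n = subtree_count(gen)
            if gen_n == 0:
                continue
            gen_pass = gen_n >= support_min
            rows.append((gen, "genus", gen_n, gen_pass))
            species_called = []
            for sp in (n for n in taxonomy.descendants(gen) if taxonomy.rank[n] == "species"):
                sp_n = exact.get(sp, 0)
                if sp_n == 0:
                    continue
                sp_pass = sp_n >= support_min
                rows.append((sp, "species", sp_n, sp_pass))
                if sp_pass:
                    species_called.append(sp)
            if species_called:
                for sp in species_called:
                    called_nodes.append(sp)
                    retained[sp] = reads_at.get(sp, [])
            elif gen_pass:
                called_nodes.append(gen)
                retained[gen] = subtree_reads(gen)
    table = pd.DataFrame(rows, columns=["taxon", "rank", "n_assigned_reads", "passed"])
    return TaxonCallTable(table=table, called_nodes=called_nodes, retained_read_ids=retained)
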