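"""Alignment, hit retention, LCA and presence-call gates.

The aligner is cross-checked against an independent dynamic-programming
oracle (Biopython's PairwiseAligner configured to the same scoring scheme);
LCA is checked against brute-force ancestor-set intersection.
"""

import itertools

import numpy as np
import pytest
from Bio import Align

from sedascope import (
    DamageModel,
    DonorSet,
    align_read,
    build_panel,
    call_taxa,
    lca,
    retain_hits,
    simulate_reads,
)
from sedascope.core import MalformedRecordError, revcomp
from sedascope.taxassign import (
    AlignmentHit,
    PanelIndex,
    ReadAssignment,
    Taxonomy,
    TaxonomyError,
    assign_read,
)

from conftest import make_read


def oracle_aligner():
    """Independent semi-global DP: read global, reference ends free."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -3  # first gap base costs open+extend = -2 + -1
    al.extend_gap_score = -1
    al.end_deletion_score = 0.0  # free (unpenalised) reference overhangs
    return al


class TestAlignRead:
    def test_exact_substring(self, small_panel):
        _, panel = small_panel
        sp = "fam1_gen1_sp1"
        read = panel[sp][50:90]
        hits = align_read(make_read(read), panel)
        best = hits[0]
        assert best.species_id == sp
        assert best.score == 40
        assert best.identity == 1.0
        assert (best.ref_start, best.ref_end, best.strand) == (50, 90, "+")

    def test_reverse_strand_exact(self, small_panel):
        _, panel = small_panel
        sp = "fam1_gen1_sp1"
        read = revcomp(panel[sp][50:90])
        best = align_read(make_read(read), panel)[0]
        assert best.species_id == sp
        assert best.identity == 1.0
        assert best.strand == "-"
        assert (best.ref_start, best.ref_end) == (50, 90)

    def test_circular_origin_spanning(self, small_panel):
        """A read across the origin aligns at identity 1.0 (doubled reference)."""
        _, panel = small_panel
        sp = "fam1_gen1_sp1"
        L = len(panel[sp])
        read = (panel[sp] * 2)[L - 20 : L + 20]
        best = align_read(make_read(read), panel)[0]
        assert best.species_id == sp
        assert best.identity == 1.0
        assert best.ref_start == L - 20 and best.ref_end == L + 20

    @pytest.mark.parametrize("trial", range(12))
    def test_scores_match_dp_oracle(self, small_panel, trial):
        """Every per-species score equals the brute-force DP optimum."""
        _, panel = small_panel
        rng = np.random.default_rng(100 + trial)
        sp = list(panel)[rng.integers(0, 8)]
        kind = trial % 3
        if kind == 0:  # random read
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        else:  # planted, optionally mutated
            st = int(rng.integers(0, 300))
            read = (panel[sp] * 2)[st : st + 40]
            if kind == 2:
                read = list(read)
                for _ in range(5):
                    read[rng.integers(0, 40)] = "ACGT"[rng.integers(0, 4)]
                read = "".join(read)
        al = oracle_aligner()
        hits = align_read(make_read(read), panel)
        assert len(hits) == len(panel)
        for h in hits:
            ref2 = panel[h.species_id] * 2
            expected = max(al.score(ref2, read), al.score(ref2, revcomp(read)))
            assert h.score == expected

    def test_seeded_agrees_on_real_hits(self, small_panel):
        """Seed-and-extend returns the same score as the exhaustive scan."""
        _, panel = small_panel
        rng = np.random.default_rng(77)
        index = PanelIndex(panel)
        for _ in range(20):
            sp = list(panel)[rng.integers(0, 8)]
            st = int(rng.integers(0, 300))
            read = list((panel[sp] * 2)[st : st + 45])
            for _ in range(3):
                read[rng.integers(0, 45)] = "ACGT"[rng.integers(0, 4)]
            read = "".join(read)
            if rng.integers(0, 2):
                read = revcomp(read)
            exhaustive = {h.species_id: h.score for h in align_read(make_read(read), index)}
            seeded = {
                h.species_id: h.score
                for h in align_read(make_read(read), index, method="seeded")
            }
            for sp_id, score in seeded.items():
                assert score == exhaustive[sp_id]
            assert max(seeded.values()) == max(exhaustive.values())

    def test_malformed_read_rejected(self, small_panel):
        _, panel = small_panel
        with pytest.raises(MalformedRecordError):
            align_read(make_read("ACGTXACGTACGTACGT"), panel)
        with pytest.raises(MalformedRecordError):
            align_read(make_read("ACGTACGTACGT"), panel)  # < 15 nt

    def test_n_scores_as_mismatch(self, small_panel):
        _, panel = small_panel
        sp = "fam1_gen1_sp1"
        read = panel[sp][50:90]
        read_n = "N" + read[1:]
        best = align_read(make_read(read_n), panel)[0]
        assert best.score == 38  # one match replaced by a mismatch


class TestRetainHits:
    def _hits(self, scores, identity=0.95):
        return [
            AlignmentHit(
                read_id="r", species_id=f"sp{i}", score=s, identity=identity,
                ref_start=0, ref_end=40, strand="+",
            )
            for i, s in enumerate(scores)
        ]

    def test_top_percent_rule(self):
        """Scores {100, 91, 89}: 89 falls below 90% of the best score."""
        retained = retain_hits(self._hits([100, 91, 89]))
        assert retained == {"sp0", "sp1"}

    def test_identity_gate(self):
        hits = self._hits([100], identity=0.89)
        assert retain_hits(hits) == set()

    def test_empty(self):
        assert retain_hits([]) == set()

    def test_monotone_in_identity(self, small_panel):
        _, panel = small_panel
        read = panel["fam1_gen1_sp1"][10:55]
        hits = align_read(make_read(read), panel)
        sizes = [
            len(retain_hits(hits, min_identity=t)) for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert sizes == sorted(sizes, reverse=True)


def brute_force_lca(species, taxonomy):
    """Oracle: intersect full ancestor paths, take the deepest member."""
    paths = [set(taxonomy.ancestors(sp)) for sp in species]
    common = set.intersection(*paths)
    return max(common, key=lambda n: len(taxonomy.ancestors(n)))


class TestLCA:
    def test_singleton(self, small_taxonomy):
        assert lca({"fam1_gen1_sp1"}, small_taxonomy) == "fam1_gen1_sp1"

    def test_same_genus(self, small_taxonomy):
        assert lca({"fam1_gen1_sp1", "fam1_gen1_sp2"}, small_taxonomy) == "fam1_gen1"

    def test_cross_family_is_root(self, small_taxonomy):
        assert lca({"fam1_gen1_sp1", "fam2_gen2_sp1"}, small_taxonomy) == "root"

    def test_all_subsets_match_oracle(self, small_taxonomy):
        species = small_taxonomy.species_ids()
        for r in range(1, len(species) + 1):
            for subset in itertools.combinations(species, r):
                assert lca(set(subset), small_taxonomy) == brute_force_lca(
                    subset, small_taxonomy
                )

    def test_unknown_id_raises(self, small_taxonomy):
        with pytest.raises(TaxonomyError):
            lca({"no_such_species"}, small_taxonomy)


def assignments_at(node, n, start=0):
    return [
        ReadAssignment(read_id=f"{node}_{start + i}", node=node, retained_species=set())
        for i in range(n)
    ]


class TestCallTaxa:
    def test_family_gate_49_reads(self, small_taxonomy):
        """A family with 49 fragments fails the 50-fragment cutoff."""
        calls = call_taxa(assignments_at("fam1_gen1_sp1", 49), small_taxonomy)
        assert calls.called_nodes == []
        fam_row = calls.table[calls.table.taxon == "fam1"]
        assert not fam_row.passed.item()

    def test_species_promotion_at_100(self, small_taxonomy):
        calls = call_taxa(assignments_at("fam1_gen1_sp1", 100), small_taxonomy)
        assert "fam1_gen1_sp1" in calls.called_nodes
        assert len(calls.retained_read_ids["fam1_gen1_sp1"]) == 100

    def test_split_genus_not_promoted(self, small_taxonomy):
        """60+60 reads across two species: genus called, neither species."""
        assignments = assignments_at("fam1_gen1_sp1", 60) + assignments_at(
            "fam1_gen1_sp2", 60, start=60
        )
        calls = call_taxa(assignments, small_taxonomy)
        assert calls.called_nodes == ["fam1_gen1"]
        assert len(calls.retained_read_ids["fam1_gen1"]) == 120
        table = calls.table.set_index("taxon")
        assert table.loc["fam1_gen1", "n_assigned_reads"] == 120
        assert not table.loc["fam1_gen1_sp1", "passed"]

    def test_hierarchical_count_consistency(self, small_taxonomy):
        assignments = (
            assignments_at("fam1_gen1_sp1", 70)
            + assignments_at("fam1_gen1_sp2", 40, start=70)
            + assignments_at("fam1_gen1", 15, start=110)
            + assignments_at("fam1_gen2_sp1", 30, start=125)
        )
        calls = call_taxa(assignments, small_taxonomy)
        table = calls.table.set_index("taxon")
        assert table.loc["fam1_gen1", "n_assigned_reads"] == 70 + 40 + 15
        assert table.loc["fam1", "n_assigned_reads"] == 70 + 40 + 15 + 30

    def test_support_monotonicity(self, small_taxonomy):
        """Raising support_min never increases the number of called taxa."""
        assignments = assignments_at("fam1_gen1_sp1", 120) + assignments_at(
            "fam1_gen2_sp1", 80, start=120
        )
        n_called = [
            len(call_taxa(assignments, small_taxonomy, support_min=m).called_nodes)
            for m in (50, 80, 100, 121, 500)
        ]
        assert n_called == sorted(n_called, reverse=True)


class TestEndToEndAssignment:
    def test_species_accuracy_clean_reads(self):
        """Clean reads (no damage/error) resolve to the true species.

        At 0.15 substitutions/site per edge sibling species are ~0.3 apart,
        so the top-10% rule keeps only the true hit for essentially every
        read >= 35 nt; on the same panel every read must at least land on
        the true lineage.
        """
        taxonomy, panel = build_panel(2, 2, 2, 800, 0.15, seed=21)
        taxo = Taxonomy(taxonomy.nodes)
        index = PanelIndex(panel)
        sp = "fam1_gen1_sp1"
        donors = DonorSet(species_id=sp, haplotypes=[panel[sp]])
        reads, _ = simulate_reads(
            panel[sp], donors, 150, length_law=(45, 8, 35),
            damage=DamageModel.none(), seed=22,
        )
        n_species = n_lineage = 0
        for read in reads:
            a, _ = assign_read(read, index, taxo, method="seeded")
            if a.node == sp:
                n_species += 1
            if a.node in taxo.ancestors(sp):
                n_lineage += 1
        assert n_species / len(reads) >= 0.99
        assert n_lineage == len(reads)
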