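"""End-to-end orchestration: qc → assign → authenticate → consensus → phylo.

The stage boundary rule is hard: only reads classified at (or below) a
called taxon are retained, so damage profiles and pileups never see
unclassified reads. All thresholds default to the study values
(30 nt / Q30 / 25%; 50 fragments per family; 100 supporting reads;
top 10% of hits at 90% identity; terminal damage > 0.2 on both ends;
consensus depth >= 5; diversity depth > 5, MAF > 0.21, >= 2 minor reads;
partial genomes at mean coverage > 5x; phylogeny grade > 0.4 terminal).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .authdamage import (
    authenticate,
    grade_for_phylogenetics,
    profile_table,
    profile_taxon,
)
from .consensus_div import (
    build_pileup,
    call_consensus,
    multi_donor_flag,
    variable_sites,
)
from .readqc import filter_reads
from .simulate import (
    DamageModel,
    build_panel,
    make_donors,
    simulate_contamination,
    simulate_reads,
    truth_to_frame,
)
from .taxassign import PanelIndex, Scoring, Taxonomy, assign_read, call_taxa


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run (defaults listed above)."""

    reads_fastq: str = None
    panel_fasta: str = None
    taxonomy_tsv: str = None
    outdir: str = None
    seed: int = 0
    # readqc
    min_length: int = 30
    qual_threshold: int = 30
    max_lowq_fraction: float = 0.25
    # taxassign
    min_identity: float = 0.90
    top_fraction: float = 0.10
    family_min: int = 50
    support_min: int = 100
    aligner: str = "seeded"  # 'seeded' (fast) or 'exhaustive' (exact DP scan)
    # authdamage
    auth_min_reads: int = 50
    auth_min_terminal: float = 0.2
    damage_K: int = 15
    # consensus / diversity
    consensus_min_depth: int = 5
    partial_genome_min_cov: float = 5.0  # strict >
    div_min_depth_exclusive: int = 5
    maf_min: float = 0.21
    min_minor_reads: int = 2
    # phylogeny grade
    phylo_min_terminal: float = 0.4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TaxonResult:
    taxon: str
    rank: str
    reference_species: str
    profile: object
    auth: object
    consensus: object = None
    diversity: object = None
    multi_donor: object = None
    phylo: object = None


@dataclass
class RunManifest:
    config: dict
    stage_counts: dict = field(default_factory=dict)
    taxa: list = field(default_factory=list)  # TaxonResult records
    taxon_table: pd.DataFrame = None
    consensus: dict = field(default_factory=dict)  # taxon -> ConsensusGenome
    qc_report: object = None
    calls: object = None

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stage_counts": self.stage_counts}, indent=2
        )


def run_pipeline(
    config: RunConfig,
    reads=None,
    panel=None,
    taxonomy=None,
) -> RunManifest:
    """Execute the full cascade; in-memory objects override file inputs."""
    if reads is None:
        reads = sio.read_fastq(config.reads_fastq)
    if panel is None:
        panel = sio.read_fasta(config.panel_fasta)
    if taxonomy is None:
        taxonomy = Taxonomy.from_frame(sio.read_taxonomy_frame(config.taxonomy_tsv))
    elif not isinstance(taxonomy, Taxonomy):
        taxonomy = Taxonomy(taxonomy.nodes)

    manifest = RunManifest(config=config.to_dict())
    counts = manifest.stage_counts
    counts["input_reads"] = len(reads)

    # stage 1: QC
    passed, qc_report = filter_reads(
        reads,
        min_length=config.min_length,
        qual_threshold=config.qual_threshold,
        max_lowq_fraction=config.max_lowq_fraction,
    )
    counts["qc_passed"] = len(passed)
    manifest.qc_report = qc_report

    # stage 2: alignment + LCA assignment
    index = PanelIndex(panel)
    scoring = Scoring()
    assignments = []
    hits_by_read = {}
    for read in passed:
        assignment, hits = assign_read(
            read,
            index,
            taxonomy,
            scoring=scoring,
            min_identity=config.min_identity,
            top_fraction=config.top_fraction,
            method=config.aligner,
        )
        assignments.append(assignment)
        hits_by_read[read.id] = {h.species_id: h for h in hits}
    counts["assigned_reads"] = sum(1 for a in assignments if a.node is not None)

    # stage 3: support gates
    calls = call_taxa(
        assignments,
        taxonomy,
        family_min=config.family_min,
        support_min=config.support_min,
    )
    manifest.calls = calls
    counts["called_taxa"] = len(calls.called_nodes)
    counts["retained_reads"] = sum(len(v) for v in calls.retained_read_ids.values())

    reads_by_id = {r.id: r for r in passed}
    exact_counts = {}
    for a in assignments:
        if a.node is not None:
            exact_counts[a.node] = exact_counts.get(a.node, 0) + 1

    # stages 4-6: per-taxon profiling, authentication, consensus, diversity
    results = []
    for node in calls.called_nodes:
        rank = taxonomy.rank[node]
        if rank == "species":
            ref_species = node
        else:
            # genus-level call: profile against the genus' best-supported
            # species reference (the study picks the most likely species
            # reference for unresolved genera)
            candidates = [
                s for s in taxonomy.descendants(node) if taxonomy.rank[s] == "species"
            ]
            ref_species = max(
                candidates, key=lambda s: (exact_counts.get(s, 0), s)
            )
        reference = panel[ref_species]
        alignments = []
        for rid in calls.retained_read_ids[node]:
            hit = hits_by_read.get(rid, {}).get(ref_species)
            if hit is not None:
                alignments.append(hit.to_alignment(reads_by_id[rid]))
        profile = profile_taxon(node, alignments, reference, K=config.damage_K)
        auth = authenticate(
            profile,
            min_reads=config.auth_min_reads,
            min_terminal=config.auth_min_terminal,
        )
        profile.authenticated = auth.passed
        result = TaxonResult(
            taxon=node,
            rank=rank,
            reference_species=ref_species,
            profile=profile,
            auth=auth,
        )
        if profile.mean_coverage > config.partial_genome_min_cov:
            pileup = build_pileup(alignments, reference)
            result.consensus = call_consensus(
                pileup, min_depth=config.consensus_min_depth
            )
            result.diversity = variable_sites(
                pileup,
                min_depth_exclusive=config.div_min_depth_exclusive,
                maf_min=config.maf_min,
                min_minor_reads=config.min_minor_reads,
                mode="all",
            )
            result.multi_donor = multi_donor_flag(result.diversity)
            manifest.consensus[node] = result.consensus
        phylo = grade_for_phylogenetics(
            profile,
            min_mean_cov=config.partial_genome_min_cov,
            min_terminal=config.phylo_min_terminal,
        )
        profile.phylo_grade = phylo.passed
        result.phylo = phylo
        results.append(result)

    manifest.taxa = results
    table = profile_table([r.profile for r in results])
    if not table.empty:
        table["rank"] = [r.rank for r in results]
        table["reference_species"] = [r.reference_species for r in results]
        table["n_variable_all"] = [
            r.diversity.n_variable_all if r.diversity else pd.NA for r in results
        ]
        table["n_variable_tv"] = [
            r.diversity.n_variable_tv if r.diversity else pd.NA for r in results
        ]
        table["multi_donor"] = [
            bool(r.multi_donor.flag) if r.multi_donor else False for r in results
        ]
        table["auth_reasons"] = ["; ".join(r.auth.reasons) for r in results]
    manifest.taxon_table = table

    if config.outdir:
        _write_outputs(config, manifest, qc_report, assignments, calls)
    return manifest


def _write_outputs(config, manifest, qc_report, assignments, calls):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    sio.write_tsv(qc_report.to_frame(), outdir / "qc_report.tsv")
    assign_df = pd.DataFrame(
        [
            (a.read_id, a.node or "unassigned", a.n_hits, a.best_identity)
            for a in assignments
        ],
        columns=["read_id", "node", "n_hits", "best_identity"],
    )
    sio.write_tsv(assign_df, outdir / "assignments.tsv")
    sio.write_tsv(calls.table, outdir / "taxon_calls.tsv")
    if manifest.taxon_table is not None and not manifest.taxon_table.empty:
        sio.write_tsv(manifest.taxon_table, outdir / "taxon_report.tsv")
    if manifest.consensus:
        sio.write_fasta(
            {t: c.sequence for t, c in manifest.consensus.items()},
            outdir / "consensus.fasta",
        )
    div_frames = [
        r.diversity.to_frame().assign(taxon=r.taxon)
        for r in manifest.taxa
        if r.diversity and r.diversity.records
    ]
    if div_frames:
        sio.write_tsv(pd.concat(div_frames), outdir / "diversity.tsv")
    (outdir / "manifest.json").write_text(manifest.to_json())


# ---------------------------------------------------------------------------
# demo scene


@dataclass
class DemoScene:
    taxonomy: object
    panel: dict
    reads: list
    truth: list
    donors: dict
    multi_donor_species: str
    contaminant_species: str
    damaged_species: list

    def truth_frame(self) -> pd.DataFrame:
        return truth_to_frame(self.truth)


def make_demo_scene(
    seed: int = 0,
    outdir=None,
    ref_length: int = 2000,
    divergence: float = 0.12,
    reads_per_species: int = 2500,
    contaminant_reads: int = 2000,
    damage: DamageModel = None,
) -> DemoScene:
    """Bundled synthetic inputs: 8 species / 2 families, ~20k reads.

    One species carries two donor haplotypes differing at 10 private
    transversions (50:50); one species contributes only undamaged modern
    (contaminant) reads; the remaining six are single-donor ancient taxa with
    terminal damage 0.35. Fragment lengths straddle the 30-nt QC cut.
    """
    damage = damage or DamageModel(d_max_5p=0.35, d_max_3p=0.35, decay=0.5, seq_error=0.001)
    taxonomy, panel = build_panel(
        n_families=2,
        genera_per_family=2,
        species_per_genus=2,
        ref_length=ref_length,
        divergence=divergence,
        seed=seed,
    )
    species = taxonomy.species_ids()
    multi_sp = species[0]
    contam_sp = species[-1]
    reads, truth, donors = [], [], {}
    for i, sp in enumerate(species):
        sub_seed = (seed * 1009 + 7 * i + 1) % (2**31)
        if sp == contam_sp:
            r, t = simulate_contamination(
                panel[sp], contaminant_reads, seed=sub_seed, species_id=sp,
                read_prefix=f"{sp}_modern",
            )
            donors[sp] = None
        else:
            n_donors = 2 if sp == multi_sp else 1
            dset = make_donors(
                sp, panel[sp], n_donors=n_donors, n_private_variants=10,
                seed=sub_seed + 1, transversions_only=True,
            )
            donors[sp] = dset
            r, t = simulate_reads(
                panel[sp], dset, reads_per_species,
                length_law=(45.0, 10.0, 25),
                damage=damage, seed=sub_seed,
            )
        reads.extend(r)
        truth.extend(t)
    scene = DemoScene(
        taxonomy=taxonomy,
        panel=panel,
        reads=reads,
        truth=truth,
        donors=donors,
        multi_donor_species=multi_sp,
        contaminant_species=contam_sp,
        damaged_species=[sp for sp in species if sp != contam_sp],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_fastq(reads, outdir / "reads.fastq")
        sio.write_fasta(panel, outdir / "panel.fasta")
        sio.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        sio.write_tsv(scene.truth_frame(), outdir / "truth.tsv")
        with open(outdir / "scene.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "seed": seed,
                    "ref_length": ref_length,
                    "divergence": divergence,
                    "reads_per_species": reads_per_species,
                    "contaminant_reads": contaminant_reads,
                    "damage": dataclasses.asdict(damage),
                    "multi_donor_species": multi_sp,
                    "contaminant_species": contam_sp,
                },
                fh,
                sort_keys=False,
            )
    return scene
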