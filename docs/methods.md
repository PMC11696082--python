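# Methods

This note documents the models, thresholds and numerical choices behind
`sedascope`, in the order the pipeline applies them, plus what the
synthetic-data generator does and does not emulate.

## The problem setting

Sediment-derived ancient DNA consists of very short (~30–80 nt) fragments
from many taxa at once, enriched by hybridisation capture against a panel of
mammalian mitogenomes. Two failure modes dominate: mis-assignment of reads
between closely related mitogenomes, and modern contamination masquerading
as ancient presence. The pipeline addresses the first with conservative
LCA assignment and hard support gates, and the second with terminal
deamination profiling — post-mortem cytosine deamination produces C→T
substitutions at 5' fragment ends (read as G→A at 3' ends in double-stranded
libraries), at rates modern DNA cannot show.

## Read QC

Order is fixed: 3' poly-A trim (run length ≥ 8; the minimum run is a package
default — capture libraries are conventionally poly-A trimmed but no
standard run length exists), then length < 30 nt, then low quality (fraction of bases
below Q30 **≥** 0.25; the boundary is inclusive), then exact
sequence duplicates keeping the first occurrence. Duplicates are defined on
the nucleotide string only, since dereplication precedes alignment where
qualities play no role. Filtering is idempotent; permuting the input can
change *which* duplicate survives, never how many reads pass.

## Alignment and taxonomic assignment

Every read is aligned against every panel species with a semi-global
(glocal) affine-gap dynamic program: the read aligns end to end, reference
ends are free. Scoring is match +1, mismatch −1, and a gap of length L costs
2 + L (gap_open −2, gap_extend −1, first gap base pays both); `N` matches
nothing. References are treated as circles by aligning against the doubled
sequence and mapping coordinates back modulo the length; both read
orientations are scanned and the best hit per species kept. Identity is
matched columns over all aligned columns, gap columns included, so the 90%
identity gate is exactly defined.

Two execution modes exist. `exhaustive` runs the full DP against every
species and strand — exact by construction, and cross-checked in the test
suite against an independent dynamic-programming oracle (Biopython's
`PairwiseAligner` configured to the identical scheme). `seeded` (the
pipeline default) is standard seed-and-extend: a 12-mer index over both
strands of the doubled references proposes diagonals, and the DP runs in a
window around each diagonal cluster. A (species, strand) pair sharing no
12-mer with the read produces no hit; such an alignment could not approach
the 90% identity gate for reads of the lengths seen here, and on seeded
test panels the two modes return identical scores for every reported hit.
Windows are re-run at triple width in the rare case the narrow window
truncates a long-gap alignment, which keeps windowed scores equal to the
full-scan optimum.

Hit retention is the MEGAN-style top-percent rule: drop hits below 90%
identity, keep survivors scoring at least 90% of the best score, assign the
read to the LCA of the retained species. Ties across species are all
retained — the LCA absorbs the ambiguity; there is no random tie-breaking
anywhere in the pipeline. Damage-tolerant scoring (down-weighting C→T/G→A
mismatches) is deliberately not used: the thresholds downstream are
calibrated for standard alignment, and damage tolerance would double-count
the signal the authentication stage depends on.

Presence gates: families need ≥ 50 assigned fragments (counting every
assignment at or below the family) or all their reads are discarded; within
passing families a genus is present at ≥ 100 reads at-or-below it, and a
species is called when ≥ 100 reads resolve to that species specifically —
the common case in panels carrying one species per genus, where genus and
species support coincide. Only reads assigned at or below a called node
are retained — a hard stage boundary, so damage and coverage statistics
never see unclassified reads. For a genus called without a resolved species,
downstream profiling uses the genus' best-supported species reference.

## Damage profiling and authentication

At 5' offset *i*, the C→T frequency is (# aligned columns with reference C
and read T) / (# aligned columns with reference C), gap columns skipped;
mirrored from the 3' end for G→A. Reads aligned on the '-' strand are
profiled in sequencing orientation (offset mirrored, reference base
complemented): deamination is a property of the molecule's ends as
sequenced, not of the genome strand. Zero denominators leave the frequency
undefined (NaN), never zero. K = 15 profile positions by default — the
conventional window for damage plots; configurable.

Authentication requires n_reads ≥ 50 AND terminal rate > 0.2 on **both**
ends, evaluated at the single terminal base (offset 0), the standard
double-stranded-library criterion. All inequalities are strict: a terminal
rate of exactly 0.20, or a mean coverage of exactly 5.0, fails. Phylogeny grading
requires mean coverage > 5 and max(5' terminal, 3' terminal) > 0.4. Mean
coverage is total aligned bases divided by the *full* reference length
(uncovered sites included), which makes the 5× gate exact. Undefined
terminal frequencies fail with an explicit "insufficient terminal context"
reason rather than being coerced to 0.

## Consensus and diversity

Pileups count aligned read bases per reference position (A/C/G/T only;
insertions ignored, deletions contribute nothing; circular coordinates
folded modulo the length). Consensus: majority base at depth ≥ 5, otherwise
N; an exact top-count tie also masks to N — the majority rule does not
define ties, and masking is the conservative choice for phylogenetic use.

Diversity deliberately uses a *different* depth rule, following the wording
of each step literally: sites enter the scan only at depth **> 5**, while
consensus calls at depth **≥ 5**. A site is variable when the second most
frequent base has frequency > 0.21 and at least 2 supporting reads — the
single-carrier exclusion is expressed as minor-allele support ≥ 2, which
also covers the case where the reference allele happens to be the minor
one. MAF uses the top two bases only; third alleles count toward
depth but not the MAF. The MAF filter is applied to raw counts in
all-substitutions mode — no damage pre-masking — because the
transversions-only mode exists precisely to exclude damage: deamination
creates transitions, so a supported variable transversion site is
damage-immune evidence of a second donor haplotype, and the multi-donor
flag is simply n_variable_tv ≥ 1.

## Distance placement

Pairwise p-distance with pairwise deletion: comparable sites are positions
where both rows hold a plain base (A/C/G/T); N and '-' are excluded per
pair, not per column, which is what heavily masked sedaDNA consensus
genomes require. Transversions-only distance counts only purine↔pyrimidine
differences over the same comparable-site denominator. Pairs with fewer
than 100 comparable sites (a package default guarding against noise) are
flagged undefined; neighbor joining refuses matrices with undefined pairs.
NJ is the classic Q-criterion/Saitou–Nei agglomeration with lowest-index
tie-breaking (deterministic output), final three lineages resolved by the
three-point formulas, negative branch lengths clamped to zero with the
clamping counted. NJ stands in for maximum-likelihood inference: it is
exactly testable (additive matrices are recovered perfectly) and supports
the same nearest-lineage statements; bootstraps and clock calibration are
out of scope. Multiple sequence alignment is consumed, not computed —
consensus genomes built on the same reference share its coordinate frame by
construction.

## The simulator: what a green test establishes

The generator states a world and the tests check the pipeline recovers it:

- **Panel**: a random root sequence mutated independently along each edge of
  the root→family→genus→species tree at a configurable substitution rate per
  site per edge (Jukes–Cantor-style uniform replacement). Within-genus pairs
  sit ~2 edges apart, between-family pairs ~6.
- **Fragments**: start uniform on the circle, strand uniform, length from a
  lower-truncated normal — note the truncation raises the emitted mean above
  the location parameter (≈ 46.4 for mean 45, sd 10, floor 30); tests assert
  against the truncated-law mean. The demo scene truncates at 25 nt so the
  30-nt QC cut has work to do.
- **Damage**: geometric decay from each end, rate `d_max · decay^offset`,
  C→T from 5', G→A from 3', applied after orientation (reverse-strand reads
  are emitted reverse-complemented first) — the simplest decreasing-from-
  terminus model consistent with canonical damage curves. Defaults d = 0.35,
  decay 0.5 sit inside the 0.2–0.5 terminal range typical of Pleistocene
  sediment libraries; sequencing error 0.001 per base to a uniform other
  base.
- **Donors**: one haplotype per individual; private variants planted at
  distinct positions (optionally transversions only), mixture weights
  configurable.
- **Contaminants**: zero damage, longer fragments (mean 80 nt), flagged in
  the truth table.

Truth tables record species, donor, coordinates, strand and every altered
offset, enabling binomial parameter-recovery oracles. What the simulator
does **not** emulate: single-stranded library chemistry, indel damage,
PCR-duplicate structure beyond exact copies, quality-score miscalibration,
adapter read-through, GC-biased capture efficiency, or alignment reference
bias from true inter-population divergence. A green suite therefore
certifies the inference logic under the stated generative model, not
performance on any particular sequencing run.

The bundled demo scene fixes 8 species / 2 families, 2 kb circular
references (mitogenome-scale, reduced for runtime), per-edge divergence 0.12
(mammalian mtDNA inter-genus scale), ~2,500 reads per ancient species,
2,000 contaminant reads, one 50:50 two-donor species with 10 private
transversions. Everything is seed-deterministic down to bytes.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internal; 1-based only in
  human-readable output.
- Empty inputs are defined, not errors: an empty FASTQ yields a manifest of
  zeros; an empty hit list retains nothing; a zero-denominator damage
  frequency is NaN and fails authentication with a reason.
- LCA of an empty set is an error (a read with no retained hits is
  *unassigned*, a distinct state).
- Seeded sub-streams: the demo scene derives per-species seeds as
  `(1009·seed + 7i + 1) mod 2^31` so species draws are independent but
  reproducible from one integer.
- The aligner reports, per species, the single best (score, strand) hit;
  equal-scoring strand ties resolve to '+'.

## Known limitations

- The seeded aligner can miss hits for reads sharing no 12-mer with a
  reference; at ≥ 40% divergence this is the desired behaviour, but reads
  shorter than ~25 nt with several damage hits may occasionally lose their
  true hit that the exhaustive mode would find (and the identity gate would
  usually discard anyway).
- Genus-level calls are profiled against a single species reference chosen
  by read support, which slightly inflates mismatch-based statistics when
  the true donor species is absent from the panel.
- The diversity statistic assumes independent reads; PCR families beyond
  exact duplicates would violate the ≥ 2-carrier rule's intent.
- p-distances are uncorrected; at the divergences where placement is useful
  (< ~0.3) this is the standard desk choice, but long branches compress.
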