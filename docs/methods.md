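# Methods

This note documents the models and procedures beepirna implements, the
defaults it ships, and the design decisions taken where more than one
reasonable choice existed. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The identification protocol

piRNAs are defined operationally, as is standard for sRNA-seq surveys without
Piwi immunoprecipitation:

1. clean reads are collapsed into unique-sequence *tags* with exact
   per-replicate occurrence counts (read order never matters);
2. tags are mapped to the genome on both strands. The built-in mapper is
   exact-match (seed k-mer index, every hit re-verified by direct sequence
   comparison); a `max_mismatches > 0` mode uses a numpy sliding-window scan
   and reports only the best mismatch stratum. Both are adequate for
   desk-scale genomes; for larger genomes an external aligner's SAM/BAM can
   be ingested (`discover.ingest_sam`), with coordinates re-verified against
   the FASTA;
3. tags overlapping annotated rRNA, tRNA, snRNA, snoRNA or scRNA features by
   at least `min_overlap_frac` (default 0.5) of the tag length — on either
   strand — are subtracted. The subtraction is annotation-interval based
   rather than a live Rfam search, which keeps the step deterministic and
   database-free; the overlap fraction is configurable;
4. tags exactly matching a known miRNA sequence (or overlapping a miRNA
   locus by the same rule) are subtracted;
5. remaining tags are candidate piRNAs iff their length lies in the
   inclusive 24–33 nt window **and** they align to exactly one genomic
   position at the best mismatch stratum. "Unique position" is read
   strictly: exactly one best-stratum alignment across both strands.

Candidate identity is the tag sequence (IDs are sequence-derived hashes),
because downstream counting is per read sequence, not per locus. Every
subtraction stage emits a ledger row, so
`tags_in == candidates + ledger rows` holds exactly at all times.

All intervals are 0-based half-open internally; GFF3 I/O converts to/from
the 1-based closed file convention.

## Normalisation and differential expression

TPM = T·10⁶/N with N the library's **total** clean small-RNA tags (including
reads later subtracted as ncRNA/miRNA), not the catalog-restricted total.
Group-level TPM pools counts and library sizes before scaling. Fold change is
log₂(max(TPM₁, floor)) − log₂(max(TPM₂, floor)) with floor 0.01 TPM; the
difference-of-logs form makes swapping numerator and denominator negate the
value exactly, and the floor produces finite extreme values for
present/absent piRNAs (e.g. 100 TPM vs 0 → log₂FC ≈ 13.29).

The default significance test is Audic–Claverie on pooled counts: under the
null, y | x is negative-binomial with x+1 successes and success probability
N₁/(N₁+N₂), and the two-sided p doubles the smaller inclusive tail (capped
at 1). A "minlike" variant (mass of all outcomes no more likely than the
observed one) is also provided. The conditional test is orientation-
asymmetric; `de_test` therefore evaluates it in a canonical orientation
(conditioning on the smaller pooled count) so that reversing a comparison
preserves every p-value exactly. Welch's t-test on replicate TPMs is
available as an alternative when replicate-level inference is wanted.

A piRNA is called DE at p ≤ 0.05 **and** |log₂FC| ≥ 1, both boundaries
inclusive; no multiple-testing correction is applied by default (BH
adjustment is available behind a flag). Up/down lists are ranked by |log₂FC|
descending, then p ascending, then ID.

**Calibration caveat.** The pooled count test assumes Poisson-level sampling
of the pooled counts. With negative-binomial replicate noise (dispersion φ:
var = μ + φμ²) the pooled counts are overdispersed by a factor ≈ 1 + φμ/k
for k replicates, which at realistic depths makes the raw p anticonservative
by an order of magnitude or more. It is the joint p-and-fold-change rule
that controls the practical false-positive rate: at the default study
conditions the caller's false-positive rate stays around 1–2% (measured by
the test suite and the acceptance script), because null log₂ ratios
concentrate well inside ±1. Users who need calibrated per-test p-values
under replicate overdispersion should use a replicate-aware NB GLM, which is
deliberately out of scope here.

The 2^−ΔΔCt calculator is plain arithmetic:
ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,ctrl − Ct_ref,ctrl).

## Target prediction

piRNAs are assumed to bind targets in a miRNA-like antisense duplex, so
target prediction is a complementarity scan, not a seed-match heuristic.
The penalty scheme follows the published plant-miRNA target-finder scheme:
mismatch 1.0, G:U wobble 0.5, gap 1.0, all doubled within the core (piRNA
positions 2–13 from the 5′ end), site reported when the total penalty is at
most 4.0. Alignments are banded to at most 2 gaps in total — piRNA–target
duplexes are near-contiguous, and the band bounds the scan to O(L·n) per
transcript. The scanner is a gap-count-limited semi-global dynamic program
vectorised across transcript positions; among overlapping candidate
alignments the lowest-score (ties: leftmost) site is reported. Its results
are checked against exhaustive enumeration of all banded antisense
alignments on short transcripts.

Duplex free energy uses a simplified nearest-neighbor model at 37 °C:

ΔG = ΔG_init + Σ stacks over consecutive paired columns
    + defect penalty × internal mismatch/gap columns
    + terminal A:U / G:U end penalties,

with ΔG_init = +4.09 kcal/mol, defect penalty +1.0, end penalty +0.45, and
Turner-2004 Watson–Crick stack values. Wobble-containing stacks carry fixed
representative values (−1.30 with one G:U pair, +0.50 with two) instead of
the full Turner wobble tables; full loop thermodynamics (RNAhybrid/ViennaRNA
grade) is out of scope. The table ships with the package, covers all ordered
WC/GU dinucleotide stacks, and respects the dyad symmetry
ΔG(WX/YZ) = ΔG(ZY/XW). Defect columns outside the first/last paired column
are not part of the duplex and are ignored, so a duplex with zero paired
positions costs exactly the initiation term.

Binding relationships are retained iff ΔG is **strictly** below the gate
(default −15.0 kcal/mol; a site at exactly −15.0 is excluded). Under this
model every perfect antisense site of ≥ 24 nt clears the gate, including the
weakest-stacking (poly-A:U) case. Because only the gate value, not the
energy program, is standard across studies, absolute ΔG values should not be
expected to match any external thermodynamics tool exactly.

## Enrichment and networks

Term enrichment uses the two-sided Fisher exact test on the 2×2 table
(targeted vs background-only × in-term vs not), with the background
defaulting to all genes in the supplied transcript set (configurable).
Significance is p < 0.05, strict, with no multiple-testing correction by
default, BH optional. Annotation itself is an input (gene → term TSVs), not
a live database query.

Networks are tripartite: DEpiRNA → target gene edges (carrying ΔG,
comparison and direction) and gene → pathway edges. Genes enter iff
annotated to at least one pathway of the configured categories; the shipped
default category config mirrors the development / immune / energy-metabolism
split used for honey-bee gut studies (Wnt, Hippo, Notch, mTOR, TGF-β,
Hedgehog, FoxO; endocytosis, Jak/STAT, ubiquitin-mediated proteolysis,
lysosome, phagosome, Toll/Imd, apoptosis; sulfur metabolism, nitrogen
metabolism, oxidative phosphorylation). Hub statistics rank piRNAs by
distinct gene neighbours (degree descending, ID ascending). Exports are
tab-delimited SIF (tabs keep whitespace-containing IDs intact) and GraphML
with all attributes; both round-trip.

## The synthetic-study generator

The generator emulates the design the analysis assumes: three ordered
developmental groups (Am4, Am5, Am6) × three biological replicates, piRNA
loci of 24–33 nt with a C-dominant first base (default weights C 0.55,
U 0.20, A 0.15, G 0.10, matching the qualitative 1C bias of bee gut piRNAs;
an optional flag plants the ping-pong 10A signature), non-overlapping ncRNA
and miRNA loci whose reads provide contamination, and random transcripts
carrying planted antisense sites for the DE loci.

Count model: replicate counts are negative-binomial with var = μ + φμ²,
φ = 0.1 by default — typical small-RNA overdispersion. Baseline relative
abundances are lognormal (σ = 0.8). A `de_fraction` subset of loci (default
10%) receives a signed log₂ step (default magnitude 2) at one group
transition, assigned round-robin over transitions; group means are not
renormalised afterwards, so null loci stay exactly null. Reads are exact
locus copies by default (the pipeline starts from clean tags; a uniform
substitution rate is available for robustness experiments), contaminant
rates default to 25% ncRNA-window and 5% miRNA reads relative to the piRNA
depth — library composition after QC varies widely in practice, so these are
explicitly arbitrary and configurable.

What the generator does **not** emulate: adapter/quality artifacts, base-
quality models, genome repeat structure, piRNA cluster organisation, and
isoform-level transcript complexity. Passing tests on synthetic data
therefore demonstrate the correctness of the implemented procedures and
their behaviour under the declared noise model — not performance on real
libraries, where mapping ambiguity and annotation incompleteness dominate.

Determinism: one integer seed drives every random draw through numpy's
Generator; identical config + seed reproduces every output file byte for
byte, and FASTQ record order never affects any output.

## Problem sizes and numerical choices

The reference study conditions used by the acceptance checks are 500 piRNA
loci, 10⁵ reads per replicate and a 200 kb genome — small enough to run the
whole chain in about a minute on one CPU while leaving hundreds of counts
per locus, the regime the pooled test and fold-change gate are meant for.
Oracle-equivalence checks run on deliberately tiny inputs (counts ≤ 50,
2×2 tables, transcripts ≤ 60 nt) where exact enumeration is feasible.

Tie-breaks are deterministic everywhere: candidate catalogs sort by pooled
count then sequence; DE rankings by |log₂FC|, p, ID; scan hits by score then
leftmost position; hub rankings by degree then ID. Degenerate inputs are
defined rather than accidental: empty miRNA sets subtract nothing, an empty
group raises an explicit error, both-groups-zero counts give p = 1 with a
warning flag, and zero-depth simulations produce empty FASTQ files and
all-zero count matrices.

## Known limitations

- The exact-match mapper and numpy mismatch scan target desk-scale genomes;
  genome-scale work should go through SAM ingest.
- No replicate-aware NB GLM, batch correction, piRNA cluster calling, or
  ping-pong amplification analysis beyond the optional 10A flag.
- The energy model is a stack-sum approximation; gate decisions near the
  threshold are parameterisation-dependent.
- Enrichment treats genes as exchangeable; no topology- or length-aware
  correction.
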