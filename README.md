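# beepirna

Tools for characterising Piwi-interacting RNAs (piRNAs) in bulk small-RNA
sequencing of honey-bee (*Apis mellifera*) larval guts — and, more generally,
in any small desk-scale sRNA-seq study with grouped replicates. The package
covers the whole analysis chain:

1. **Discovery** — collapse clean reads into unique-sequence tags, map them to
   the genome, subtract annotated rRNA/tRNA/snRNA/snoRNA/scRNA and known
   miRNAs, then keep tags of 24–33 nt that align to exactly one genomic
   position. Summaries: first-base bias (bee gut piRNAs show a 1C bias),
   length histograms, and Venn-style shared/unique partitions across groups.
2. **Differential expression** — tags-per-million normalisation
   (TPM = T·10⁶/N, N the library's total clean tags), log₂ fold change of
   floored pooled TPMs, and the Audic–Claverie exact conditional test on
   pooled counts (Welch's t on replicate TPMs as an option). A piRNA is
   called differentially expressed when p ≤ 0.05 and |log₂FC| ≥ 1, both
   boundaries inclusive. A 2^−ΔΔCt calculator supports RT-qPCR follow-up.
3. **Target prediction** — antisense scanning of transcripts with a
   plant-miRNA-style penalty score (mismatch 1, G:U 0.5, gap 1, doubled in
   the piRNA 5′ core positions 2–13, cutoff 4), banded to ≤ 2 gaps, plus a
   nearest-neighbor RNA/RNA duplex free-energy estimate. Binding
   relationships are screened at ΔG strictly below −15 kcal/mol.
4. **Enrichment and networks** — two-sided Fisher exact enrichment of
   GO/KEGG-style terms among target genes (significant at p < 0.05), and
   tripartite DEpiRNA → gene → pathway-category networks (development,
   immune, energy metabolism) exported as Cytoscape-ready SIF and GraphML.
5. **Simulation** — a fully seeded synthetic-study generator (genome,
   annotations, grouped FASTQ replicates with negative-binomial counts,
   contaminating ncRNA/miRNA reads, planted fold changes and target sites,
   truth tables) so every stage can be validated against known ground truth.

The statistical core in brief: the Audic–Claverie conditional distribution of
a count *y* given *x* with library sizes N₁, N₂ is negative-binomial,
p(y|x) = C(x+y, y) N₁^{x+1} N₂^y / (N₁+N₂)^{x+y+1}, and the two-sided p
doubles the smaller tail. Duplex energies follow
ΔG = ΔG_init + Σ stacks + defect and terminal A:U/G:U penalties, with
Turner-2004 Watson–Crick stack values at 37 °C.

## Worked example

```python
from beepirna import pipeline
from beepirna.simulate import SimulationConfig
from beepirna.discover import first_base_bias, group_set_partition

cfg = SimulationConfig(seed=4, genome_length=60_000, n_pirna_loci=60,
                       n_ncrna_loci={"rRNA": 5, "tRNA": 5, "snRNA": 3,
                                     "snoRNA": 3, "scRNA": 2},
                       n_mirna=20, n_transcripts=80, mean_depth=4_000)
run = pipeline.run_study(cfg, "demo")

print(f"candidate piRNAs: {len(run.discovery.candidates)}")
print("first-base bias (Am4):",
      {b: round(f, 3) for b, f in first_base_bias(run.discovery.candidates, "Am4").items()})
for comp, table in run.expression.items():
    print(comp, (table["direction"] == "up").sum(), "up,",
          (table["direction"] == "down").sum(), "down")
```

prints

```
candidate piRNAs: 60
first-base bias (Am4): {'A': 0.217, 'C': 0.483, 'G': 0.117, 'U': 0.183}
Am4 vs Am5: 1 up, 2 down
Am5 vs Am6: 2 up, 2 down
```

All 60 planted piRNA loci are recovered (and nothing else: contaminant reads
are fully removed by the annotation subtraction), the first-base mode is C as
designed, and the planted fold changes surface as up/down calls in the two
developmental comparisons. `run.metrics` holds the truth-based scores
(recovery, DE sensitivity/false-positive rate, planted-site recovery, …).

The same steps are available from the shell:

```bash
beepirna sim --config cfg.yaml --outdir study --seed 4
beepirna discover --reads manifest.tsv --genome study/genome.fa \
    --annot study/annotations.gff3 --mirna study/mirna.fa --out disc
beepirna diffexpr --counts disc/pirna_catalog.tsv --libsizes disc/library_sizes.tsv \
    --compare Am4:Am5 --compare Am5:Am6 --out de
beepirna targetscan --pirnas de_pirnas.tsv --transcripts study/transcripts.fa --out targets
beepirna netenrich --de de/de_up_Am4_vs_Am5.tsv --hits targets/gated_hits.tsv \
    --terms study/terms.tsv --categories study/categories.yaml --out net
```

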