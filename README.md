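# cas12akit

Desk-scale toolkit for designing compact Cas12a pre-crRNA knockout
libraries and analysing the pooled screens run with them. Two library
formats are supported: **dual** (four spacers per gene split across two
2-spacer constructs) and **quad** (one 4-spacer array per gene, with extra
arrays when isoform coverage demands it). Everything runs on synthetic
mini-genomes and simulated screens — no downloads required.

## What it does

* **genome_model** (`cas12akit.genome`) — FASTA + GFF3 (+ optional Pfam /
  non-coding BED tracks) into a validated, 0-based half-open object model;
  canonical-isoform resolution; genomic position → spliced-CDS fraction.
* **spacer_design** (`cas12akit.spacers`) — enumeration of 23-mer spacers
  at TTTV PAMs whose cut site falls in the canonical CDS; hard filters
  (poly-T, GC < 20% / > 80%, EcoRI/KpnI sites in cloning context, ambiguous
  bases); mismatch-tolerant CDS off-target counting; a pluggable on-target
  activity surrogate.
* **library_builder** (`cas12akit.library`) — optimal pair/quad selection
  under the spacing rules (≥ 25 nt within a pair, ≥ 50 nt between pairs),
  non-coding-element avoidance, Pfam / first-85%-of-CDS prioritisation and
  soft exon diversity; 500 validated non-targeting controls per library;
  DR-interleaved cassette + cloning-oligo assembly (TCCC/AAAC overhangs).
* **screen_counting** (`cas12akit.counting`) — DR-anchored spacer
  extraction from FASTQ into a construct × sample count matrix; log-CPM.
* **screen_stats** (`cas12akit.stats`) — per-construct linear models with
  lowess mean-variance (voom-style) weights, empirical-Bayes variance
  moderation, moderated t/F tests, mean-t gene aggregation against an NTC
  or normal null, BH FDR, hypergeometric gene-set enrichment,
  essential-gene depletion QC, top-abundance hit calling, 4-way plot
  export.
* **synthetic_data** (`cas12akit.simulate`) — designable-by-construction
  mini-genomes with planted multi-isoform genes, non-coding elements and
  Pfam intervals (plus a truth record); negative-binomial screen counts
  with planted effects; array-amplicon FASTQ reads.

## CLI

```sh
# synthetic inputs
cas12akit simulate genome --n-genes 20 --seed 1 --outdir sim/
cas12akit simulate screen --lib lib.tsv --seed 1 --out counts.tsv
cas12akit simulate reads  --lib lib.tsv --n-reads 10000 --out reads.fq

# library design
cas12akit design dual --fasta sim/genome.fa --gff sim/genome.gff3 \
    --pfam-bed sim/pfam.bed --ncrna-bed sim/ncrna.bed \
    --out lib.tsv --seed 1
cas12akit design quad ...            # same options
cas12akit make-ntc --fasta sim/genome.fa --n 500 --mode dual --out ntc.tsv
cas12akit assemble --lib lib.tsv --dr-file drs.txt --out lib2.tsv

# screen analysis
cas12akit count --samples samples.tsv --lib lib.tsv --out counts.tsv
cas12akit screen test --counts counts.tsv --samples counts.samples.tsv \
    --contrasts contrasts.tsv --lib lib.tsv --fdr 0.2 --outdir results/
```

`samples.tsv` columns: `sample_id  fastq  condition  replicate  timepoint`;
`contrasts.tsv` columns: `name  group_a  group_b`.

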