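# pseudoscope

Parent genes and their pseudogenes can be nearly sequence-identical — for
*GBA1* and its pseudogene *GBAP1*, about 96% over the coding sequence. Short
RNA-seq reads from such loci often align to both copies, and because standard
pipelines quantify genes from uniquely mapped reads only, the expression
ratio of the pair comes out wrong: the highly expressed parent gene is
disproportionately under-counted and the measured log2 fold-change is pulled
toward 0. Long reads that span whole transcripts resolve the ambiguity but
bring their own artifacts (intrapriming, reverse-transcriptase template
switching) and expose how incomplete the reference annotation is.

`pseudoscope` implements this full analysis as a reusable, tested pipeline
that runs end to end on synthetic data — no downloads:

* **`pseudoscope.sim`** — a simulator that builds a two-locus genome: a
  multi-exon parent gene and a pseudogene copy at configurable per-base
  identity, with annotated and novel isoforms, planted artifact transcripts,
  per-sample full-length-read counts, and short paired-end alignments whose
  NH (number-of-hits) values come from an exhaustive mismatch-bounded
  placement search.
* **`pseudoscope.multimap`** — locus-level short-read analysis: CIGAR
  reference widths, selection of paired first-mate reads fully inside a
  stranded locus, unique-mapping percentage, cross-locus multimapper share,
  the parent/pseudogene log2 ratio, Shapiro–Wilk, and Grubbs' single-outlier
  test.
* **`pseudoscope.qc`** — long-read isoform QC: removal of intrapriming
  (>80% genomic A in the 20 bp downstream of the 3' end), RT-switch
  (8 bp direct repeat at a junction) and off-target transcripts, then
  full-length-read normalization and retention.
* **`pseudoscope.classify`** — structural classification against the
  reference (FSM / ISM / NIC / NNC), longest-ORF prediction, the 50-nt NMD
  rule, a 7-way final category, and CAGE-peak TSS support (≤50 bp).
* **`pseudoscope.gaps`** — annotation-incompleteness survey: junction QC
  (≥25 bp introns, blacklist), junction novelty labelling, the ≥5%-of-samples
  gene flagging rule, the group proportion P_Tj = j/x, and the two-sided
  Wilcoxon rank-sum comparison.
* **`pseudoscope.catalog`** — pseudogene biotype clustering
  (Processed/Unprocessed/Unitary/Other), binary expression calls
  (median TPM > 0), alternative-splicing rates, and parent-CDS percent
  identity by global alignment.

## The quantities at the core

Full-length-read (FLR) quantification of transcript *T* in sample *i*, for a
gene with *M* transcripts and *N* samples:

```
NFLR_Ti = 100 · FLR_Ti / Σ_{T=1..M} FLR_Ti        (percent of sample total)
NFLR_T  = (1/N) Σ_{i=1..N} NFLR_Ti                (mean across samples)
```

Isoforms are retained when NFLR_Ti ≥ 0.1 in ≥80% of samples and
NFLR_T ≥ 0.3 (all thresholds inclusive).

Short-read vs long-read quantification is compared with the convention
log2FC = log2(parent / pseudogene), and a long-read estimate is tested
against a background of short-read estimates with Grubbs' maximum normalized
residual test, G = max|x_i − x̄| / s.

## Worked example

```bash
python analysis/02_multimapping_bias.py
```

prints (ten replicate simulations at 96% identity, true parent:pseudogene
ratio 4:1, 100-bp paired-end reads):

```
true log2FC (parent/pseudogene): 2.00
unique-read estimate:      1.75 +/- 0.11
full-length-read estimate: 2.01 +/- 0.02
unique-read estimate attenuated toward 0 in 10/10 seeds
parent unique mapping: 41.0% +/- 7.9%
parent multimappers also at pseudogene: 100.0%
```

Only ~41% of reads at the parent locus map uniquely and essentially all its
multimappers also hit the pseudogene, so the unique-read ratio is biased
toward 0 while full-length-read quantification recovers the simulated truth.
The other drivers: `analysis/01_simulate_locus.py` writes the synthetic
dataset, `analysis/03_isoform_pipeline.py` runs artifact filtering + NFLR +
classification (category shares per gene sum to 100%), and
`analysis/04_annotation_survey.py` computes P_Tj for a panel of simulated
genes with and without unannotated isoforms and compares the groups by
Wilcoxon rank-sum.

The same stages are available as subcommands of the `pseudoscope` CLI
(`simulate`, `catalog`, `multimap`, `isoforms`, `classify`, `survey`,
`bias-experiment`), reading and writing standard FASTA/GTF/BED/SAM/TSV.

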