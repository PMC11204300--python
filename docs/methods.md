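# Methods

## The problem being modelled

A pseudogene is a defective genomic copy of a parent gene: *processed*
copies arise by retrotransposition of spliced mRNA (intronless), *unprocessed*
copies by segmental duplication (intron-containing). When the two copies are
nearly identical, short sequencing reads from either locus align to both; in
SAM terms the read's NH tag exceeds 1 and standard gene-level pipelines drop
it. The package quantifies the consequence — a biased parent:pseudogene
expression ratio — and implements the long-read counterpart analyses:
isoform artifact QC, full-length-read quantification, structural
classification, and a survey of annotation incompleteness.

## The simulator

`sim.build_locus_pair` constructs one contig containing a multi-exon parent
gene and a pseudogene copy separated by ≥10 kb of random sequence, both on
the minus strand by default. The parent gene carries:

* **T1** — the canonical isoform (all exons, annotated). An open reading
  frame is planted in its spliced sequence: ATG at transcript position 60, a
  TAA ending 21 nt into the 3'-terminal exon (so the annotated isoform is
  not a nonsense-mediated-decay target), and every internal in-frame stop
  broken by a middle-base substitution. The CDS is recorded in the
  annotation and defines the reference proteome.
* **T2** — an exon-skipping isoform (annotated).
* **N1** — an unannotated isoform whose donor at one internal junction is
  shifted 6 bp into the intron (a novel splice site).
* **N2** — an unannotated isoform whose 5'-terminal exon extends 120 bp
  upstream (a novel TSS).
* **ART_IP** — an intraprimed truncation of T1: the genome is edited so the
  20 bp immediately downstream of its 3' end are 18/20 adenosine on the
  transcript strand (90% > the 80% filter threshold).
* **ART_RTS** — an RT-switch isoform: a 60-bp segment of the 3' UTR is
  spliced out and the genome is edited so the 8 exonic bases ending at the
  donor equal the 8 intronic bases ending at the acceptor — the direct-repeat
  signature the detector looks for. Both artifact signatures live in the 3'
  UTR, downstream of the stop codon, so planting them cannot disturb the ORF.

The pseudogene is derived from T1: a *processed* copy is the spliced
sequence, an *unprocessed* copy the full genomic span, mutated base-by-base
with independent substitution probability 1 − identity (no indels, so
realised identity is exactly binomial and CIGARs stay simple). A processed
copy additionally carries 250 bp of unique 3' sequence in its transcript, a
deliberate modelling choice: real processed pseudogene transcripts include
integration-site and diverged sequence, and without *any* unique pseudogene
sequence the read loss to multimapping would be perfectly symmetric between
the loci and no ratio bias could arise. The tail length is configurable
(`pseudo_tail_len`, 0 disables it).

### Full-length-read counts

Per sample, transcript counts are drawn multinomially at the sample's
library size (default 10,000 reads across 5 samples), so per-sample totals
are exact. The expression split is `gene_ratio` between the genes (default
0.8 / 0.2, i.e. a true log2FC of 2) times `true_abundances` within each gene
(default parent 0.60/0.15/0.15/0.10 over T1/T2/N1/N2). A fraction of the
parent's read mass (default 5% + 5%) is reassigned to the two artifact
transcripts; the artifact reads are still reads of the gene, which is why
the gene-level long-read estimate in the bias experiment sums over all of a
gene's isoforms, while the isoform-level pipeline removes them.

### Short-read alignments

Paired 100-bp reads are sampled from the clean transcripts' spliced
sequences. Fragment starts are uniform over the transcript and fragments
running off the 3' end are truncated, so first mates cover the entire
transcript; mate 1 reads the transcript sense strand (the stranded-library
convention the read-selection rule assumes).

Placements are found by an exhaustive mismatch-bounded search (pigeonhole
seeding plus full verification — identical in output to a brute-force scan)
against the genome **and the annotated transcript sequences**. This emulates
an annotation-guided splice-aware aligner: reads are spliced only across
annotated junctions, and reads crossing N1's novel junction go unplaced —
annotation incompleteness costs the parent gene coverage exactly as it does
in real data. Placements whose reference footprints overlap are merged to
one alignment per genomic window, preferring fewer mismatches and, on ties,
the spliced form (the annotated-junction bonus real aligners apply); NH is
the number of surviving placements and every one is emitted, with spliced
footprints written as `M…N…M` CIGARs. The default mismatch cap is 4 per
100-bp read (≈ the tolerance of ENCODE-style alignment at 4% divergence).

### What the simulator does not model

Sequencing errors, indels, quality strings, fragment-size distributions,
expression variation between samples beyond multinomial noise, more than two
loci per simulation, and GC or positional coverage bias. Passing tests
therefore demonstrate the *logic* of the analyses — selection rules,
normalization algebra, filter boundaries, classification relations, bias
direction and approximate magnitude — not calibrated error rates on real
libraries.

## Short-read multimapping analysis

Reads are selected exactly as the locus-level analysis prescribes: paired,
first-mate, on the locus strand, with the CIGAR-derived reference footprint
fully inside the locus, and NH ≤ 10 (half the common ENCODE multimapping
cap; configurable). The unique-mapping rate is 100·|NH=1|/|selected|;
the cross-locus share asks what fraction of one locus's multimappers appear
by read name among the other's. log2 fold-changes always put the parent
gene in the numerator, and zero or negative inputs are loud errors rather
than pseudocounts.

Grubbs' single-outlier test is implemented natively: G = max|x_i − x̄|/s on
the pooled background-plus-candidate sample, with the two-sided p obtained
by inverting the standard critical-value identity
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile on
n−2 df; the candidate is called an outlier only if the test rejects *and*
the candidate is the maximal residual. Shapiro–Wilk and the Wilcoxon
rank-sum test delegate to scipy (Royston AS R94; exact enumeration for
tie-free n ≤ 20, else normal approximation with midranks, tie and
continuity correction).

## Isoform QC (order matters)

The stage runs **filter → normalize → retain**: artifact transcripts
(intrapriming perc_A > 80, strictly; RT-switch direct repeat, default 8 bp;
wrong gene) are removed *before* the per-sample percentage normalization, so
genuine isoforms' shares are not deflated by artifact reads; an optional
collapse-support pre-filter (≥2 full-length reads total, configurable)
mirrors upstream practice. Retention uses inclusive thresholds and compares
the sample fraction as an exact rational (4/5 of 5 samples is exactly 80%).
The 0.3% criterion applies to the across-sample mean NFLR_T by default; a
per-sample variant is available via `mean_criterion="per_sample"`.

perc_A is computed on the transcript strand (reference T's count as A for
minus-strand transcripts) in the 20-bp window strictly downstream of the
3' end, truncated at contig edges with the denominator shrinking.

## Structural classification

The junction chain (ordered introns, 5'→3') is the unit of comparison:
FSM = identical chain to a reference isoform; ISM = the chain equals a
3'-anchored contiguous sub-chain of a reference (a 5'-truncated isoform —
general sub-chains do **not** qualify, so 3'-truncated intrapriming
artifacts classify as NIC rather than ISM, a deliberate divergence from
classifiers that allow arbitrary sub-chains); NIC = all donors and acceptors
individually known to the overlapping gene but the chain or pairing is new;
NNC = at least one novel splice site. Mono-exonic queries are FSM when
contained in a mono-exonic reference and otherwise NIC (never NNC — they
have no junctions). Terminal ends within 50 bp (configurable) of the matched
reference count as a complete match; farther deviations give alt5/alt3.

ORFs are predicted as the longest ATG-initiated reading frame ending at an
in-frame stop (ties to the 5'-most start; ≥50 aa; an ORF running off the
transcript end counts as noncoding). NMD uses the 50-nt rule, inclusive:
stop codon ending ≥50 nt upstream of the final junction. The 7-way final
category is a pure function of (structural class, coding, NMD, end status),
with "known" keyed strictly off full-splice-match status. "Novel ORF" means
the predicted protein is not an exact member of the reference proteome; a
pure truncation therefore counts as novel (the call is exposed per
transcript so callers can narrow it).

## Annotation-incompleteness survey

Junctions follow the intron convention (donor = first intronic base,
acceptor = last, 0-based half-open internally, 1-based inclusive in TSV).
QC drops implied introns <25 bp and blacklist overlaps. A junction belongs
to the single gene whose span contains both sites; junctions contained in no
gene or in several are discarded and counted. A gene is flagged when ≥1
novel junction has nonzero counts in ≥5% of the tissue's samples (exact
rational, inclusive), and P_Tj = j/x per group and tissue. In long-read
mode, the per-gene rate counts transcripts with a novel splice site inside
the predicted CDS *and* a novel ORF.

## Numerical and design choices

* Coordinates: 0-based half-open internally; GTF written 1-based inclusive;
  BED 0-based half-open.
* CDS identity: Needleman–Wunsch global alignment, match +1, mismatch −1,
  gap open −2, gap extend −0.5; identity = identical columns / parent CDS
  length. The published parent–pseudogene identity metric is not specified
  precisely anywhere public, so this reproducible convention is documented
  instead; on substitution-only simulations it recovers 100·identity within
  one percentage point for sequences ≥2 kb.
* Determinism: every stage derives its generator as
  `default_rng([seed, stream, index])`; identical configurations give
  byte-identical FASTA/GTF/SAM outputs.
* Degenerate inputs error loudly (empty read sets, zero-total count columns
  naming the sample, zero-variance statistics) rather than yielding NaN.
* Problem sizes in tests and the acceptance script (10,000 reads × 5 samples;
  2,000 read pairs; 10 seeds for the bias experiment; 200 classifier
  perturbations) were chosen so the whole battery runs in well under a
  minute while keeping multinomial noise far below every asserted margin.

## Known limitations

* The multimapping model is substitution-only; real parent–pseudogene pairs
  also differ by indels and structural variation, which create CIGAR
  complexity and alignment soft-clipping the simulator does not produce.
* The RT-switch detector implements the canonical direct-repeat signature
  with an exact-match rule; published detectors use likelihood models and
  will disagree near the threshold.
* The longest-ORF rule approximates dedicated ORF predictors; transcripts
  whose true ORF is not the longest will be misclassified.
* The survey's simulated panel gives a clean separation between gene groups
  (novel junctions are either present or absent); real tissues show graded
  proportions, so the Wilcoxon comparison on simulated data exercises the
  machinery rather than estimating realistic effect sizes.
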