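#!/usr/bin/env python
"""Generate the reference synthetic dataset: a GBA1/GBAP1-like locus pair.

Writes the genome, annotation, truth tables and full-length-read counts under
results/simdata/ (small text files) and the short-read alignments under
scratch/simdata/ (bulky). Prints a summary of what was planted.
"""

import os

import pandas as pd

from pseudoscope import io
from pseudoscope.sim import (
    SimConfig,
    build_locus_pair,
    simulate_flr_counts,
    simulate_short_read_alignments,
)

OUT = "results/simdata"
SCRATCH = "scratch/simdata"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    os.makedirs(SCRATCH, exist_ok=True)
    cfg = SimConfig(seed=1)
    truth = build_locus_pair(cfg)
    flr = simulate_flr_counts(truth, cfg)
    reads = simulate_short_read_alignments(truth, cfg)

    io.write_fasta({truth.contig: truth.genome}, f"{OUT}/genome.fa")
    io.write_gtf(f"{OUT}/annotation.gtf", truth.annotation, truth.genes)
    io.write_gtf(f"{OUT}/true_transcripts.gtf", truth.true_transcripts, truth.genes)
    flr.sort_index().to_csv(f"{OUT}/flr_counts.tsv", sep="\t")
    pd.Series(truth.artifact_labels, name="label").sort_index().rename_axis(
        "transcript_id"
    ).to_csv(f"{OUT}/artifact_labels.tsv", sep="\t")
    io.write_sam(f"{SCRATCH}/alignments.sam", reads, {truth.contig: len(truth.genome)})

    n_novel = sum(
        1 for t in truth.true_transcripts
        if t.transcript_id not in {a.transcript_id for a in truth.annotation}
        and truth.artifact_labels[t.transcript_id] == "clean"
    )
    print(f"genome: {len(truth.genome)} bp, parent span {truth.parent_span}, "
          f"pseudogene span {truth.pseudo_span} (identity {cfg.identity})")
    print(f"transcripts: {len(truth.annotation)} annotated, {n_novel} novel, "
          f"2 planted artifacts; {len(reads)} alignment records "
          f"({len(truth.true_nh)} mates) -> {SCRATCH}/alignments.sam")
    print(f"full-length reads: {flr.values.sum()} across {cfg.n_samples} samples "
          f"-> {OUT}/flr_counts.tsv")


if __name__ == "__main__":
    main()
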