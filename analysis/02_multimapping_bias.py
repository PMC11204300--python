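#!/usr/bin/env python
"""Quantify the short-read multimapping bias at the simulated locus pair.

Simulates ten replicate loci at 96% identity with a true 4:1
parent:pseudogene expression ratio, quantifies both genes from uniquely
mapped short reads and from full-length reads, and tabulates the log2
fold-changes. The expected finding: the unique-read estimate is pulled
toward 0 (the parent gene is under-quantified) while the full-length
estimate recovers the truth.
"""

import os

import numpy as np
import pandas as pd

from pseudoscope.pipeline import run_bias_experiment_over_seeds
from pseudoscope.sim import SimConfig

OUT = "results"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cfg = SimConfig(identity=0.96)
    reports = run_bias_experiment_over_seeds(cfg, list(range(10)))
    frame = pd.DataFrame([r.to_dict() for r in reports])
    frame.to_csv(f"{OUT}/bias_experiment.tsv", sep="\t", index=False)

    uniq = frame["unique_log2fc"]
    flr = frame["flr_log2fc"]
    wins = int((uniq.abs() < flr.abs()).sum())
    print(f"true log2FC (parent/pseudogene): {reports[0].true_log2fc:.2f}")
    print(f"unique-read estimate:      {uniq.mean():.2f} +/- {uniq.std():.2f}")
    print(f"full-length-read estimate: {flr.mean():.2f} +/- {flr.std():.2f}")
    print(f"unique-read estimate attenuated toward 0 in {wins}/10 seeds")
    print(f"parent unique mapping: {frame['unique_pct_parent'].mean():.1f}% "
          f"+/- {frame['unique_pct_parent'].std():.1f}%")
    print(f"parent multimappers also at pseudogene: "
          f"{frame['cross_share_parent_pct'].mean():.1f}%")
    print(f"table -> {OUT}/bias_experiment.tsv")


if __name__ == "__main__":
    main()
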