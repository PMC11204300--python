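"""Pseudogene / parent-gene cataloging.

Clusters GENCODE biotypes into pseudogene classes, makes binary expression
calls from median-TPM tables, computes alternative-splicing rates, and
measures parent-CDS vs pseudogene percent identity by global alignment.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .models import GeneRecord

PROCESSED = "Processed"
UNPROCESSED = "Unprocessed"
UNITARY = "Unitary"
OTHER = "Other"
NOT_PSEUDOGENE = "NotPseudogene"

#: GENCODE gene_type -> pseudogene class.  Polymorphic pseudogenes are
#: excluded (still potentially coding in some haplotypes), hence NotPseudogene.
BIOTYPE_CLASSES: Dict[str, str] = {
    "processed_pseudogene": PROCESSED,
    "transcribed_processed_pseudogene": PROCESSED,
    "translated_processed_pseudogene": PROCESSED,
    "unprocessed_pseudogene": UNPROCESSED,
    "transcribed_unprocessed_pseudogene": UNPROCESSED,
    "translated_unprocessed_pseudogene": UNPROCESSED,
    "unitary_pseudogene": UNITARY,
    "transcribed_unitary_pseudogene": UNITARY,
    "IG_V_pseudogene": UNITARY,
    "IG_C_pseudogene": UNITARY,
    "IG_J_pseudogene": UNITARY,
    "IG_pseudogene": UNITARY,
    "TR_pseudogene": UNITARY,
    "TR_J_pseudogene": UNITARY,
    "TR_V_pseudogene": UNITARY,
    "rRNA_pseudogene": OTHER,
    "pseudogene": OTHER,
}

#: Variant clustering in which the IG/TR immunoglobulin- and T-cell-receptor
#: pseudogene biotypes fall under "Other" instead of "Unitary".
BIOTYPE_CLASSES_IG_TR_OTHER: Dict[str, str] = {
    k: (OTHER if k.startswith(("IG_", "TR_")) else v) for k, v in BIOTYPE_CLASSES.items()
}


def classify_biotype(gene_type: str, mapping: Optional[Mapping[str, str]] = None) -> str:
    """Map a GENCODE gene_type string to a pseudogene class.

    Total and deterministic: anything outside the mapping (including
    polymorphic_pseudogene and all non-pseudogene biotypes) is
    ``NotPseudogene``.
    """
    mapping = BIOTYPE_CLASSES if mapping is None else mapping
    return mapping.get(gene_type, NOT_PSEUDOGENE)


def catalog_summary(
    genes: Sequence[GeneRecord],
    source: Optional[str] = "HAVANA",
    mapping: Optional[Mapping[str, str]] = None,
) -> Dict[str, int]:
    """Count pseudogenes per class (after source filtering) plus distinct
    parent genes.

    ``source`` restricts to rows annotated by that source (HAVANA by
    default); pass None to keep all rows.
    """
    counts = {PROCESSED: 0, UNPROCESSED: 0, UNITARY: 0, OTHER: 0}
    parents = set()
    n_seen = 0
    for g in genes:
        if source is not None and g.source and g.source != source:
            continue
        n_seen += 1
        cls = classify_biotype(g.gene_type, mapping)
        if cls == NOT_PSEUDOGENE:
            continue
        counts[cls] += 1
        if g.parent_id:
            parents.add(g.parent_id)
    if n_seen == 0:
        warnings.warn("catalog_summary called on an empty annotation")
    counts["total"] = sum(counts[c] for c in (PROCESSED, UNPROCESSED, UNITARY, OTHER))
    counts["parent_genes"] = len(parents)
    return counts


def load_parent_map(path: str) -> Dict[str, str]:
    """Two-column TSV (pseudogene_id, parent_id), psiCube-export compatible."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def call_expressed(tpm: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Binary expression calls from a gene x tissue median-TPM table.

    A gene counts as expressed in a tissue iff its median TPM is strictly
    greater than zero (a deliberately conservative call, since these tables
    are built from uniquely mapped reads only).  Returns the boolean matrix
    and summary fractions: expressed in >= 1 tissue, and mean +/- sd of the
    per-tissue expressed fraction.
    """
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values in input")
    flags = tpm > 0
    per_tissue = flags.mean(axis=0)
    summary = {
        "frac_expressed_any_tissue": float(flags.any(axis=1).mean()),
        "mean_frac_per_tissue": float(per_tissue.mean()),
        "sd_frac_per_tissue": float(per_tissue.std(ddof=1)) if tpm.shape[1] > 1 else 0.0,
    }
    return flags, summary


def alt_splicing_rate(
    tx_support: pd.DataFrame,
    tx_to_gene: Mapping[str, str],
    genes: Sequence[GeneRecord],
) -> Dict[str, float]:
    """Fraction of expressed pseudogenes per class that are alternatively
    spliced (more than one transcript with nonzero support).

    ``tx_support`` is a transcript x sample table; a transcript is supported
    if it has nonzero support in any sample.  Genes with zero expressed
    transcripts are excluded (not expressed), genes absent from
    ``tx_to_gene``'s image entirely are excluded with a warning.
    """
    by_class: Dict[str, GeneRecord] = {g.gene_id: g for g in genes}
    supported = (tx_support > 0).any(axis=1)
    n_tx: Dict[str, int] = {}
    for tid, ok in supported.items():
        gid = tx_to_gene.get(tid)
        if gid is None:
            continue
        n_tx.setdefault(gid, 0)
        if ok:
            n_tx[gid] += 1
    missing = [g.gene_id for g in genes if g.gene_id not in n_tx]
    if missing:
        warnings.warn(f"{len(missing)} genes have no transcripts in the support table")

    tallies: Dict[str, List[bool]] = {}
    for gid, n in n_tx.items():
        g = by_class.get(gid)
        if g is None or n == 0:
            continue
        cls = classify_biotype(g.gene_type)
        if cls == NOT_PSEUDOGENE:
            continue
        tallies.setdefault(cls, []).append(n > 1)
    return {cls: float(np.mean(v)) for cls, v in tallies.items()}


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def cds_percent_identity(parent_cds: str, pseudo_seq: str) -> float:
    """Percent identity of a parent-gene CDS against a pseudogene sequence.

    Needleman-Wunsch global alignment (match +1, mismatch -1, gap open -2,
    gap extend -0.5); identity is the number of identical aligned columns as
    a percentage of the parent CDS length, so gaps in the pseudogene lower
    the score while the denominator stays fixed.
    """
    parent_cds = parent_cds.upper()
    pseudo_seq = pseudo_seq.upper()
    for name, s in (("parent_cds", parent_cds), ("pseudo_seq", pseudo_seq)):
        if not s:
            raise ValueError(f"{name} is empty")
        if set(s) - set("ACGTN"):
            raise ValueError(f"{name} contains non-ACGTN characters")
    aln = _aligner().align(parent_cds, pseudo_seq)[0]
    a, b = aln[0], aln[1]
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * identical / len(parent_cds)
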