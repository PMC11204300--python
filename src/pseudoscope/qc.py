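"""Long-read isoform QC and full-length-read quantification.

The post-classification QC stage for targeted long-read data: remove
intrapriming artifacts (A-rich genomic window downstream of the transcript
3' end), RT-switching artifacts (direct-repeat junctions), and off-target
transcripts; then normalize full-length read counts within each sample and
retain isoforms by expression thresholds.

Normalization, for transcript T of a gene in sample i with M transcripts and
N samples:

    NFLR_Ti = 100 * FLR_Ti / sum_T FLR_Ti      (percent of the sample total)
    NFLR_T  = (1/N) * sum_i NFLR_Ti            (mean across samples)

Retention requires NFLR_Ti >= 0.1 in at least 80% of samples and
NFLR_T >= 0.3; all thresholds are inclusive and the sample fraction is
compared as an exact rational.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import Interval, TranscriptModel, revcomp

REASON_INTRAPRIMING = "intrapriming"
REASON_RT_SWITCH = "rt_switch"
REASON_WRONG_GENE = "wrong_gene"
REASON_LOW_EXPRESSION = "low_expression"
REASON_LOW_SUPPORT = "low_support"


def perc_a_downstream(
    genome: str, tts: int, strand: str, window: int = 20
) -> float:
    """Percent of A's (transcript-strand sense) in the genomic window
    strictly downstream of the transcript termination site.

    For a plus-strand transcript the window is the ``window`` bases after
    the TTS read directly; for minus strand it is the ``window`` bases
    before the TTS on the reference, where a sense A appears as a T.  A
    window truncated by the contig edge shrinks the denominator.
    """
    if not 0 <= tts < len(genome):
        raise ValueError(f"TTS {tts} outside contig of length {len(genome)}")
    if strand == "+":
        lo, hi = tts + 1, tts + 1 + window
    else:
        lo, hi = tts - window, tts
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(genome))
    if (clipped_lo, clipped_hi) != (lo, hi):
        warnings.warn("downstream window truncated at contig edge")
    seq = genome[clipped_lo:clipped_hi].upper()
    if not seq:
        return 0.0
    target = "A" if strand == "+" else "T"
    return 100.0 * seq.count(target) / len(seq)


def rts_flag(
    genome: str, intron: Interval, strand: str, repeat_len: int = 8
) -> bool:
    """Direct-repeat signature of reverse-transcriptase template switching.

    True iff the ``repeat_len`` exonic bases ending at the donor site are
    identical to the ``repeat_len`` intronic bases ending at the acceptor
    site, both read on the transcript strand.  Such repeats let the RT jump
    templates and fabricate the junction.
    """
    s, e = intron
    if not (0 <= s < e <= len(genome)):
        raise ValueError(f"invalid intron coordinates {intron}")
    if strand == "+":
        exon_end = genome[max(0, s - repeat_len):s]
        intron_end = genome[max(0, e - repeat_len):e]
    else:
        exon_end = revcomp(genome[e:e + repeat_len])
        intron_end = revcomp(genome[s:s + repeat_len])
    if len(exon_end) < repeat_len or len(intron_end) < repeat_len:
        return False
    return exon_end.upper() == intron_end.upper()


# ---------------------------------------------------------------------------
# artifact filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-transcript filter decisions with every applicable reason recorded
    (reasons are not short-circuited)."""

    table: pd.DataFrame  # index transcript_id; columns retained, reasons, attrs

    def retained(self) -> List[str]:
        return list(self.table.index[self.table["retained"]])

    def removed(self) -> List[str]:
        return list(self.table.index[~self.table["retained"]])

    def reasons(self, transcript_id: str) -> List[str]:
        r = self.table.loc[transcript_id, "reasons"]
        return r.split(",") if r else []

    def add_reason(self, transcript_id: str, reason: str) -> None:
        cur = self.reasons(transcript_id)
        if reason not in cur:
            cur.append(reason)
        self.table.loc[transcript_id, "reasons"] = ",".join(cur)
        self.table.loc[transcript_id, "retained"] = False


def apply_artifact_filters(
    transcripts: Sequence[TranscriptModel],
    genome: str,
    target_gene: str,
    qc_attributes: Optional[pd.DataFrame] = None,
    max_perc_a: float = 80.0,
    repeat_len: int = 8,
) -> FilterReport:
    """Remove intrapriming, RT-switch and off-target transcripts.

    A transcript is removed when its downstream-of-TTS A content is
    *strictly* greater than ``max_perc_a``, when any of its junctions bears
    the direct-repeat RT-switch signature, or when it is assigned to a gene
    other than ``target_gene``.  ``qc_attributes`` may carry precomputed
    columns (perc_A_downstream_TTS, RTS_stage, associated_gene, as emitted
    by the upstream classifier) which are used in lieu of recomputation.
    """
    rows = []
    for tx in transcripts:
        tid = tx.transcript_id
        if qc_attributes is not None and tid in qc_attributes.index:
            attrs = qc_attributes.loc[tid]
            perc_a = float(attrs.get("perc_A_downstream_TTS", np.nan))
            if np.isnan(perc_a):
                perc_a = perc_a_downstream(genome, tx.tts, tx.strand)
            rts_any = bool(attrs.get("RTS_stage", False))
            gene = str(attrs.get("associated_gene", tx.gene_id))
        else:
            perc_a = perc_a_downstream(genome, tx.tts, tx.strand)
            rts_any = any(
                rts_flag(genome, intron, tx.strand, repeat_len) for intron in tx.introns
            )
            gene = tx.gene_id
        reasons = []
        if perc_a > max_perc_a:
            reasons.append(REASON_INTRAPRIMING)
        if rts_any:
            reasons.append(REASON_RT_SWITCH)
        if gene != target_gene:
            reasons.append(REASON_WRONG_GENE)
        rows.append(
            {
                "transcript_id": tid,
                "retained": not reasons,
                "reasons": ",".join(reasons),
                "perc_A_downstream_TTS": perc_a,
                "RTS_stage": rts_any,
                "associated_gene": gene,
            }
        )
    table = pd.DataFrame(rows).set_index("transcript_id")
    return FilterReport(table)


# ---------------------------------------------------------------------------
# normalization & retention
# ---------------------------------------------------------------------------

def nflr_normalize(flr: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-sample percentage normalization of a transcript x sample
    full-length-read matrix.

    Returns (NFLR matrix, NFLR_T row means).  Every retained sample column
    must have a positive total; an all-zero column is an error naming the
    sample.
    """
    if (flr.values < 0).any():
        raise ValueError("negative full-length-read counts")
    totals = flr.sum(axis=0)
    dead = list(totals.index[totals == 0])
    if dead:
        raise ValueError(f"sample(s) with zero total full-length reads: {dead}")
    nflr = 100.0 * flr / totals
    nflr_t = nflr.mean(axis=1)
    nflr_t.name = "NFLR_T"
    return nflr, nflr_t


def _frac(x: float) -> Fraction:
    """Exact rational from a threshold given as float or string (0.8 -> 4/5)."""
    return Fraction(str(x))


def retain_by_expression(
    nflr: pd.DataFrame,
    nflr_t: Optional[pd.Series] = None,
    min_per_sample: float = 0.1,
    min_sample_frac: float = 0.8,
    min_mean: float = 0.3,
    mean_criterion: str = "across_samples",
) -> Tuple[List[str], pd.DataFrame]:
    """Expression-based retention of normalized isoforms.

    A transcript is retained iff NFLR_Ti >= ``min_per_sample`` in at least
    ``min_sample_frac`` of samples (exact rational comparison, inclusive)
    and, under the default ``across_samples`` criterion, its mean NFLR_T >=
    ``min_mean``.  The ``per_sample`` variant instead requires NFLR_Ti >=
    ``min_mean`` in at least ``min_sample_frac`` of samples.
    """
    if nflr_t is None:
        nflr_t = nflr.mean(axis=1)
    n = nflr.shape[1]
    need = _frac(min_sample_frac)
    rows = []
    for tid in nflr.index:
        vals = nflr.loc[tid]
        n_pass = int((vals >= min_per_sample).sum())
        frac_ok = Fraction(n_pass, n) >= need
        if mean_criterion == "across_samples":
            mean_ok = bool(nflr_t.loc[tid] >= min_mean)
        elif mean_criterion == "per_sample":
            n_pass_mean = int((vals >= min_mean).sum())
            mean_ok = Fraction(n_pass_mean, n) >= need
        else:
            raise ValueError(f"unknown mean_criterion {mean_criterion!r}")
        rows.append(
            {
                "transcript_id": tid,
                "n_samples_passing": n_pass,
                "NFLR_T": float(nflr_t.loc[tid]),
                "retained": bool(frac_ok and mean_ok),
            }
        )
    report = pd.DataFrame(rows).set_index("transcript_id")
    return list(report.index[report["retained"]]), report


def run_isoform_qc(
    transcripts: Sequence[TranscriptModel],
    genome: str,
    flr: pd.DataFrame,
    target_gene: str,
    qc_attributes: Optional[pd.DataFrame] = None,
    min_total_flr: int = 2,
    min_per_sample: float = 0.1,
    min_sample_frac: float = 0.8,
    min_mean: float = 0.3,
    mean_criterion: str = "across_samples",
) -> Tuple[pd.DataFrame, pd.Series, FilterReport]:
    """Full QC stage in its fixed order: artifact filters, then per-sample
    normalization over the surviving transcripts, then expression-based
    retention.  The order matters — normalizing before removing artifacts
    would deflate every genuine isoform's share.

    ``min_total_flr`` is an optional collapse-support pre-filter (a
    transcript needs that many full-length reads summed over samples).
    Returns the NFLR matrix restricted to retained transcripts, their
    NFLR_T, and the merged filter report.
    """
    by_id = {tx.transcript_id: tx for tx in transcripts}
    missing = [t for t in flr.index if t not in by_id]
    if missing:
        warnings.warn(f"{len(missing)} count rows lack transcript models; dropped")
        flr = flr.drop(index=missing)
    report = apply_artifact_filters(
        [by_id[t] for t in flr.index], genome, target_gene, qc_attributes
    )
    if min_total_flr > 0:
        for tid in flr.index:
            if flr.loc[tid].sum() < min_total_flr:
                report.add_reason(tid, REASON_LOW_SUPPORT)
    kept = [t for t in flr.index if t in report.retained()]
    if not kept:
        raise ValueError(f"no transcripts of {target_gene} survive artifact filtering")
    nflr, nflr_t = nflr_normalize(flr.loc[kept])
    retained, exp_report = retain_by_expression(
        nflr, nflr_t, min_per_sample, min_sample_frac, min_mean, mean_criterion
    )
    for tid in nflr.index:
        if tid not in retained:
            report.add_reason(tid, REASON_LOW_EXPRESSION)
    return nflr.loc[retained], nflr_t.loc[retained], report
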