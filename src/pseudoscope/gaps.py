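"""Genome-scale annotation-incompleteness survey.

Compares a group of parent genes against other protein-coding genes using
two modes of evidence that the annotation misses real transcription:

* long-read mode — the proportion of transcripts per gene carrying a novel
  splice site inside the predicted CDS that yields a novel ORF;
* short-read mode — novel splice-junction usage: a gene is flagged when at
  least one unannotated junction shows split-read support in >= 5% of the
  tissue's samples.

For a tissue T the group proportion is P_Tj = j / x, with j the number of
flagged genes in the group and x the group size; groups are compared with a
two-sided Wilcoxon rank-sum test across tissues.

Junction QC mirrors standard split-read database criteria: implied introns
shorter than 25 bp are discarded, as are junctions overlapping a blacklist.
Junction coordinates are 0-based half-open over the intron (donor = first
intronic base, acceptor = last intronic base).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneRecord, Interval, TranscriptModel

MIN_INTRON_BP = 25

JunctionKey = Tuple[str, int, int, str]  # contig, intron start, intron end, strand

ANNOTATED = "annotated"
NOVEL_DONOR = "novel_donor"
NOVEL_ACCEPTOR = "novel_acceptor"
NOVEL_BOTH = "novel_both"
NOVEL_PAIRING = "novel_pairing"
NOVEL_LABELS = {NOVEL_DONOR, NOVEL_ACCEPTOR, NOVEL_BOTH, NOVEL_PAIRING}


def _check_junction_index(junctions: pd.DataFrame) -> None:
    for contig, start, end, strand in junctions.index:
        if end <= start:
            raise ValueError(f"malformed junction {(contig, start, end, strand)}")
        if strand not in "+-":
            raise ValueError(f"bad junction strand {strand!r}")


def qc_junctions(
    junctions: pd.DataFrame,
    blacklist: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_intron: int = MIN_INTRON_BP,
) -> pd.DataFrame:
    """Drop junctions with implied intron length < ``min_intron`` bp and,
    when a blacklist is given, junctions overlapping any blacklist interval.

    ``junctions`` is indexed by (contig, start, end, strand) with one count
    column per sample.
    """
    _check_junction_index(junctions)
    keep = []
    for key in junctions.index:
        contig, start, end, strand = key
        if end - start < min_intron:
            continue
        if blacklist and any(
            c == contig and start < b and a < end for c, a, b in blacklist
        ):
            continue
        keep.append(key)
    return junctions.loc[keep]


def read_blacklist_bed(path: str) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# junction novelty
# ---------------------------------------------------------------------------

@dataclass
class NoveltyResult:
    labels: pd.Series  # junction -> label
    gene_of: pd.Series  # junction -> gene_id
    n_unassigned: int  # junctions overlapping no gene (discarded)
    n_ambiguous: int  # junctions spanning two genes (discarded)


def annotate_junction_novelty(
    junctions: pd.DataFrame,
    reference: Sequence[TranscriptModel],
    gene_spans: Optional[Mapping[str, Tuple[str, Interval]]] = None,
) -> NoveltyResult:
    """Label each junction against the reference splice sites of its gene.

    A junction is assigned to the single gene whose span contains both of
    its sites; junctions contained in no gene, or in more than one, are
    discarded (counted in the result).  Labels: annotated (the exact intron
    exists in a reference transcript), novel_donor / novel_acceptor /
    novel_both (site-level novelty on the transcript strand), novel_pairing
    (both sites known but never paired).
    """
    _check_junction_index(junctions)
    if gene_spans is None:
        gene_spans = {}
        for tx in reference:
            contig, (lo, hi) = gene_spans.get(tx.gene_id, (tx.contig, tx.span))
            lo, hi = min(lo, tx.span[0]), max(hi, tx.span[1])
            gene_spans[tx.gene_id] = (tx.contig, (lo, hi))

    known_pairs: Dict[str, Set[Tuple[int, int]]] = {}
    known_donors: Dict[str, Set[int]] = {}
    known_acceptors: Dict[str, Set[int]] = {}
    for tx in reference:
        kp = known_pairs.setdefault(tx.gene_id, set())
        kd = known_donors.setdefault(tx.gene_id, set())
        ka = known_acceptors.setdefault(tx.gene_id, set())
        for intron in tx.introns:
            kp.add(intron)
        kd.update(tx.donors)
        ka.update(tx.acceptors)

    labels, gene_of = {}, {}
    n_unassigned = n_ambiguous = 0
    for key in junctions.index:
        contig, start, end, strand = key
        hosts = [
            gid
            for gid, (gcontig, (lo, hi)) in gene_spans.items()
            if gcontig == contig and lo <= start and end <= hi
        ]
        if not hosts:
            n_unassigned += 1
            continue
        if len(hosts) > 1:
            n_ambiguous += 1
            continue
        gid = hosts[0]
        if (start, end) in known_pairs.get(gid, set()):
            labels[key] = ANNOTATED
        else:
            # donor/acceptor positions on the transcript strand
            donor = start if strand == "+" else end - 1
            acceptor = end - 1 if strand == "+" else start
            d_known = donor in known_donors.get(gid, set())
            a_known = acceptor in known_acceptors.get(gid, set())
            if d_known and a_known:
                labels[key] = NOVEL_PAIRING
            elif not d_known and not a_known:
                labels[key] = NOVEL_BOTH
            elif not d_known:
                labels[key] = NOVEL_DONOR
            else:
                labels[key] = NOVEL_ACCEPTOR
        gene_of[key] = gid
    return NoveltyResult(
        labels=pd.Series(labels, dtype=object),
        gene_of=pd.Series(gene_of, dtype=object),
        n_unassigned=n_unassigned,
        n_ambiguous=n_ambiguous,
    )


def flag_genes_by_junction_support(
    junctions: pd.DataFrame,
    novelty: NoveltyResult,
    min_sample_frac: float = 0.05,
) -> Set[str]:
    """Genes with >= 1 novel junction used in >= ``min_sample_frac`` of the
    tissue's samples (nonzero count; inclusive exact rational comparison)."""
    need = Fraction(str(min_sample_frac))
    n_samples = junctions.shape[1]
    flagged: Set[str] = set()
    for key, label in novelty.labels.items():
        if label not in NOVEL_LABELS:
            continue
        n_used = int((junctions.loc[[key]].iloc[0] > 0).sum())
        if Fraction(n_used, n_samples) >= need:
            flagged.add(novelty.gene_of[key])
    return flagged


# ---------------------------------------------------------------------------
# long-read mode: novel-ORF transcript proportions
# ---------------------------------------------------------------------------

def novel_orf_transcript_rate(
    transcripts: Sequence[TranscriptModel],
    calls: pd.DataFrame,  # classify.calls_to_frame output (needs novel ORF info)
    orfs: Mapping[str, object],
    reference: Sequence[TranscriptModel],
) -> Tuple[Dict[str, float], List[str]]:
    """Per gene, the fraction of transcripts with at least one novel splice
    site located inside the predicted CDS and a novel predicted ORF.

    Genes with no coding transcripts are excluded and reported separately.
    """
    ref_donors: Dict[str, Set[int]] = {}
    ref_acceptors: Dict[str, Set[int]] = {}
    for tx in reference:
        ref_donors.setdefault(tx.gene_id, set()).update(tx.donors)
        ref_acceptors.setdefault(tx.gene_id, set()).update(tx.acceptors)

    per_gene_total: Dict[str, int] = {}
    per_gene_hit: Dict[str, int] = {}
    coding_seen: Dict[str, bool] = {}
    for tx in transcripts:
        gid = tx.gene_id
        per_gene_total[gid] = per_gene_total.get(gid, 0) + 1
        orf = orfs.get(tx.transcript_id)
        coding_seen[gid] = coding_seen.get(gid, False) or orf is not None
        if orf is None or not getattr(orf, "novel_orf", False):
            continue
        cds_blocks = tx.project_tx_interval(orf.start, orf.stop)
        cds_lo, cds_hi = cds_blocks[0][0], cds_blocks[-1][1]
        novel_in_cds = False
        for site in list(tx.donors) + list(tx.acceptors):
            known = site in ref_donors.get(gid, set()) or site in ref_acceptors.get(gid, set())
            if not known and cds_lo <= site < cds_hi:
                novel_in_cds = True
                break
        if novel_in_cds:
            per_gene_hit[gid] = per_gene_hit.get(gid, 0) + 1
    excluded = [g for g, c in coding_seen.items() if not c]
    rates = {
        g: per_gene_hit.get(g, 0) / n
        for g, n in per_gene_total.items()
        if coding_seen.get(g, False)
    }
    return rates, excluded


# ---------------------------------------------------------------------------
# group proportions and the rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass
class IncompletenessResult:
    tissue: str
    group: str
    j: int
    x: int

    @property
    def proportion(self) -> float:
        return self.j / self.x


def group_proportion(
    flagged: Set[str], group: Iterable[str], tissue: str = "", group_name: str = ""
) -> IncompletenessResult:
    """P_Tj = j / x: flagged genes within the group over the group size."""
    group = set(group)
    if not group:
        raise ValueError("empty gene group")
    j = len(flagged & group)
    return IncompletenessResult(tissue=tissue, group=group_name, j=j, x=len(group))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 20
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration of rank assignments when n_a + n_b <=
    ``exact_max_n`` and the pooled data are tie-free; otherwise the normal
    approximation with midranks, tie correction and continuity correction.
    Returns (U for sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and a.size + b.size <= exact_max_n:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_exact_enumeration(a: Sequence[float], b: Sequence[float]) -> float:
    """Independent brute-force two-sided p: enumerate every assignment of
    pooled ranks to group a and count rank sums at least as extreme (by
    distance from the mean rank sum) as observed.  Tie-free data only."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    ranks = stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    n = pooled.size
    mean = a.size * (n + 1) / 2.0
    obs = abs(ra - mean)
    hits = total = 0
    for idx in combinations(range(n), a.size):
        s = sum(ranks[list(idx)])
        total += 1
        if abs(s - mean) >= obs - 1e-12:
            hits += 1
    return hits / total
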