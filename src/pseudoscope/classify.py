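"""Structural categorization of long-read isoforms against a reference
annotation, ORF/NMD prediction, the 7-way final category, and CAGE-based
TSS support.

Structural classes follow the standard long-read taxonomy:

* FSM  — full splice match: junction chain identical to a reference isoform;
* ISM  — incomplete splice match: the chain is a 3'-anchored contiguous
  sub-chain of a reference isoform (fewer 5' exons);
* NIC  — novel in catalog: every donor and acceptor is individually known
  for the gene, but the chain (or a donor-acceptor pairing) is new;
* NNC  — novel not in catalog: at least one splice site is absent from the
  reference gene.

The final 7-way category is a pure function of structural class, coding
status, NMD status and terminal-end agreement; "known" in that scheme keys
off full-splice-match status only.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import Seq

from .models import (
    CategoryCall,
    Interval,
    OrfPrediction,
    TranscriptModel,
)

END_TOLERANCE_BP = 50


# ---------------------------------------------------------------------------
# structural classification
# ---------------------------------------------------------------------------

def _end_status(query: TranscriptModel, ref: TranscriptModel, tol: int) -> str:
    d5 = abs(query.tss - ref.tss)
    d3 = abs(query.tts - ref.tts)
    if d5 <= tol and d3 <= tol:
        return "complete_match"
    if d5 > tol and d3 > tol:
        return "alt5+alt3"
    return "alt5" if d5 > tol else "alt3"


def _is_3prime_subchain(
    query_chain: Sequence[Interval], ref_chain: Sequence[Interval]
) -> bool:
    """True iff the query junction chain equals the 3'-terminal contiguous
    stretch of the reference chain (a 5'-truncated isoform)."""
    nq, nr = len(query_chain), len(ref_chain)
    if nq == 0 or nq >= nr:
        return False
    return tuple(query_chain) == tuple(ref_chain[nr - nq:])


def structural_category(
    query: TranscriptModel,
    reference: Sequence[TranscriptModel],
    end_tolerance: int = END_TOLERANCE_BP,
) -> Tuple[str, Optional[str], str]:
    """Classify one query isoform against reference transcripts.

    Returns (structural class, matched reference transcript id or None,
    end status).  The reference set is restricted to transcripts on the
    query's contig; a strand mismatch against an overlapping reference gene
    is an error (targeted data are stranded).
    """
    same_contig = [r for r in reference if r.contig == query.contig]
    overlapping = [
        r for r in same_contig
        if r.span[0] < query.span[1] and query.span[0] < r.span[1]
    ]
    for r in overlapping:
        if r.strand != query.strand:
            raise ValueError(
                f"strand mismatch: query {query.transcript_id} ({query.strand}) vs "
                f"reference {r.transcript_id} ({r.strand})"
            )
    candidates = [r for r in same_contig if r.strand == query.strand]
    q_chain = query.junction_chain

    # mono-exonic queries: contained in a mono-exonic reference => FSM of it,
    # otherwise NIC for the region (no junctions exist, so never NNC)
    if not q_chain:
        for r in candidates:
            if not r.junction_chain and r.span[0] <= query.span[0] and query.span[1] <= r.span[1]:
                return "FSM", r.transcript_id, _end_status(query, r, end_tolerance)
        return "NIC", None, "n/a"

    for r in candidates:
        if r.junction_chain == q_chain:
            return "FSM", r.transcript_id, _end_status(query, r, end_tolerance)
    ism_hits = [r for r in candidates if _is_3prime_subchain(q_chain, r.junction_chain)]
    if ism_hits:
        # longest containing chain wins ties deterministically
        best = max(ism_hits, key=lambda r: (len(r.junction_chain), r.transcript_id))
        return "ISM", best.transcript_id, "n/a"

    # site-level novelty against the overlapping gene's reference sites
    gene_refs = [r for r in candidates if r.span[0] < query.span[1] and query.span[0] < r.span[1]]
    known_donors: Set[int] = set()
    known_acceptors: Set[int] = set()
    for r in gene_refs:
        known_donors.update(r.donors)
        known_acceptors.update(r.acceptors)
    all_known = all(d in known_donors for d in query.donors) and all(
        a in known_acceptors for a in query.acceptors
    )
    return ("NIC" if all_known else "NNC"), None, "n/a"


# ---------------------------------------------------------------------------
# ORF and NMD prediction
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def predict_orf(tx_sequence: str, min_orf_len: int = 50) -> Optional[OrfPrediction]:
    """Longest ATG-initiated ORF in the spliced (sense) sequence.

    The ORF must terminate at an in-frame stop codon; an ATG running off the
    transcript end without a stop is treated as incomplete and the
    transcript noncoding.  Length ties break to the 5'-most start.  Returns
    None when no ORF reaches ``min_orf_len`` amino acids (stop excluded).
    """
    seq = tx_sequence.upper()
    best: Optional[Tuple[int, int]] = None  # (start, stop_end)
    n = len(seq)
    # earliest in-frame stop per frame, scanned once
    for frame in range(3):
        starts: List[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOPS:
                for s in starts:
                    length = (i + 3 - s) // 3 - 1  # aa, stop excluded
                    if length >= min_orf_len:
                        if best is None or length > (best[1] - best[0]) // 3 - 1 or (
                            length == (best[1] - best[0]) // 3 - 1 and s < best[0]
                        ):
                            best = (s, i + 3)
                starts = []
            i += 3
    if best is None:
        return None
    s, e = best
    protein = str(Seq(seq[s:e - 3]).translate())
    return OrfPrediction(start=s, stop=e, protein=protein)


def nmd_flag(orf: OrfPrediction, tx: TranscriptModel, rule_nt: int = 50) -> bool:
    """Nonsense-mediated-decay call by the 50-nt rule.

    True iff the stop codon ends at least ``rule_nt`` nucleotides upstream
    of the last exon-exon junction (transcript coordinates, inclusive).
    Mono-exonic transcripts are never NMD.
    """
    junctions = tx.junction_tx_positions()
    if not junctions:
        return False
    last_junction = junctions[-1]
    return last_junction - orf.stop >= rule_nt


def novel_orf_flag(
    orf: OrfPrediction, reference_proteome: Iterable[str]
) -> bool:
    """True iff the predicted protein is not an exact member of the
    reference protein set.  A pure truncation of a reference protein counts
    as novel under this exact-match rule (flagged per call so a caller can
    narrow the definition)."""
    return orf.protein not in set(reference_proteome)


def reference_proteome(
    reference: Sequence[TranscriptModel], genome: str
) -> Set[str]:
    """Protein sequences translated from the reference transcripts' CDS."""
    prots = set()
    for tx in reference:
        if not tx.cds:
            continue
        s = "".join(genome[a:b] for a, b in tx.cds)
        if tx.strand == "-":
            s = str(Seq(s).reverse_complement())
        prot = str(Seq(s).translate()).rstrip("*")
        prots.add(prot)
    return prots


# ---------------------------------------------------------------------------
# final 7-way category
# ---------------------------------------------------------------------------

def assign_category(
    structural: str, coding: bool, nmd: bool, end_status: str
) -> str:
    """The 7-way final category; total over all input combinations.

    "Known" means full splice match; coding-known splits further on whether
    the terminal ends also match the reference transcript.
    """
    known = structural == "FSM"
    if not coding:
        return "noncoding_known" if known else "noncoding_novel"
    if nmd:
        return "nmd_known" if known else "nmd_novel"
    if not known:
        return "coding_novel"
    if end_status == "complete_match":
        return "coding_known_complete"
    return "coding_known_alt_ends"


def classify_transcripts(
    queries: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    genome: str,
    min_orf_len: int = 50,
    nmd_rule_nt: int = 50,
    end_tolerance: int = END_TOLERANCE_BP,
) -> Tuple[List[CategoryCall], Dict[str, Optional[OrfPrediction]]]:
    """Run the full per-transcript classification: structural class, ORF,
    NMD, novelty of the predicted protein, final category."""
    ref_prots = reference_proteome(reference, genome)
    calls: List[CategoryCall] = []
    orfs: Dict[str, Optional[OrfPrediction]] = {}
    for q in queries:
        structural, matched, ends = structural_category(q, reference, end_tolerance)
        orf = predict_orf(q.spliced_sequence(genome), min_orf_len)
        coding = orf is not None
        nmd = nmd_flag(orf, q, nmd_rule_nt) if orf else False
        if orf:
            orf.nmd = nmd
            orf.novel_orf = novel_orf_flag(orf, ref_prots)
        orfs[q.transcript_id] = orf
        calls.append(
            CategoryCall(
                transcript_id=q.transcript_id,
                structural=structural,
                matched_reference=matched,
                end_status=ends if structural == "FSM" else "n/a",
                coding=coding,
                nmd=nmd,
                final=assign_category(structural, coding, nmd, ends if structural == "FSM" else "n/a"),
            )
        )
    return calls, orfs


def calls_to_frame(calls: Sequence[CategoryCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "structural": c.structural,
            "matched_reference": c.matched_reference or "",
            "end_status": c.end_status,
            "coding": c.coding,
            "nmd": c.nmd,
            "final": c.final,
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("transcript_id").sort_index()


# ---------------------------------------------------------------------------
# CAGE-based TSS support
# ---------------------------------------------------------------------------

def cage_support(
    tss: int,
    peaks: Sequence[Interval],
    max_dist: int = 50,
) -> Tuple[bool, float]:
    """Distance from a TSS to the nearest CAGE peak (0 when inside a peak),
    and whether it falls within ``max_dist`` bp (inclusive).

    Peaks are 0-based half-open intervals on the TSS's contig; strand
    filtering, if desired, happens before the call.  An empty peak set gives
    (False, inf).
    """
    if not peaks:
        return False, float("inf")
    best = float("inf")
    for a, b in peaks:
        if a <= tss < b:
            return True, 0.0
        gap = a - tss if tss < a else tss - (b - 1)
        best = min(best, gap)
    return best <= max_dist, float(best)


def read_cage_bed(path: str) -> Dict[Tuple[str, str], List[Interval]]:
    """Read CAGE peaks from BED (0-based half-open) keyed by (contig, strand);
    strand '.' entries are returned under both strands."""
    peaks: Dict[Tuple[str, str], List[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) > 5 else "."
            strands = ["+", "-"] if strand == "." else [strand]
            for s in strands:
                peaks.setdefault((contig, s), []).append((start, end))
    for v in peaks.values():
        v.sort()
    return peaks
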