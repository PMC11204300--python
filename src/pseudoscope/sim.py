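"""Synthetic parent/pseudogene locus simulator.

Generates a two-locus genome (a multi-exon parent gene and a pseudogene copy
at configurable per-base identity), a reference annotation covering only the
"known" transcripts, a richer set of true transcripts (novel splice site,
novel TSS, intrapriming and RT-switch artifacts), per-sample full-length-read
count matrices, and short paired-end alignment records whose multimapping
degree follows from the planted sequence identity.

The regime the defaults emulate is a GBA1/GBAP1-like pair: ~96% identity,
both genes on the minus strand, the parent roughly fourfold more expressed
than the pseudogene, and a pseudogene transcript that additionally carries a
short stretch of unique (non-homologous) 3' sequence from its integration
site.

Determinism contract: one seed drives everything; per-stage and per-sample
generators are derived as ``default_rng([seed, stream, index])`` so that
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import AlignedRead, GeneRecord, Interval, TranscriptModel, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

PARENT_GENE = "PARENT"
PSEUDO_GENE = "PSEUDO"

# RNG stream ids (second word of the seed sequence)
_STREAM_GENOME = 0
_STREAM_FLR = 1
_STREAM_READS = 2
_STREAM_JUNC = 3


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Parameters of one simulated parent/pseudogene experiment.

    ``identity`` is the target per-base identity of the pseudogene copy
    (0.96 reproduces the high-similarity regime of interest).
    ``gene_ratio`` splits each library between the two genes (4:1 parent to
    pseudogene by default); ``true_abundances`` splits each gene's share
    among its transcripts and must sum to 1 per gene.
    """

    identity: float = 0.96
    pseudogene_class: str = "processed"  # or "unprocessed"
    n_exons: int = 8
    exon_len_range: Tuple[int, int] = (120, 180)
    intron_len_range: Tuple[int, int] = (250, 400)
    gene_ratio: Dict[str, float] = field(
        default_factory=lambda: {PARENT_GENE: 0.8, PSEUDO_GENE: 0.2}
    )
    true_abundances: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            PARENT_GENE: {
                "PARENT.T1": 0.60,
                "PARENT.T2": 0.15,
                "PARENT.N1": 0.15,
                "PARENT.N2": 0.10,
            },
            PSEUDO_GENE: {"PSEUDO.T1": 1.0},
        }
    )
    n_samples: int = 5
    library_sizes: Optional[Dict[str, int]] = None  # default: 10k reads/sample
    artifact_rates: Dict[str, float] = field(
        default_factory=lambda: {"intrapriming": 0.05, "rt_switch": 0.05}
    )
    short_read: Dict[str, int] = field(
        default_factory=lambda: {
            "read_len": 100,
            "n_pairs": 2000,
            "max_mismatch": 4,
            "fragment_len": 260,
        }
    )
    strand: str = "-"
    spacer_bp: int = 10_000
    flank_bp: int = 1_000
    pseudo_tail_len: int = 250
    contig: str = "chrSim"
    seed: int = 0

    # ------------------------------------------------------------------
    def samples(self) -> List[str]:
        if self.library_sizes:
            return list(self.library_sizes)
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def library_size(self, sample: str) -> int:
        if self.library_sizes:
            return int(self.library_sizes[sample])
        return 10_000

    def validate(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ConfigurationError(f"identity must be in [0,1], got {self.identity}")
        if self.pseudogene_class not in ("processed", "unprocessed"):
            raise ConfigurationError(f"unknown pseudogene_class {self.pseudogene_class!r}")
        if self.n_exons < 4:
            raise ConfigurationError("n_exons must be >= 4 (transcript menu needs internal exons)")
        lo, hi = self.exon_len_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"infeasible exon_len_range {self.exon_len_range}")
        if lo < 60:
            raise ConfigurationError("exon_len_range minimum must be >= 60")
        ilo, ihi = self.intron_len_range
        if not (0 < ilo <= ihi):
            raise ConfigurationError(f"infeasible intron_len_range {self.intron_len_range}")
        if ilo < 30:
            raise ConfigurationError("intron_len_range minimum must be >= 30")
        if self.strand not in "+-":
            raise ConfigurationError(f"bad strand {self.strand!r}")
        if self.spacer_bp < 10_000:
            raise ConfigurationError("loci must be placed >= 10 kb apart")
        if abs(sum(self.gene_ratio.values()) - 1.0) > 1e-9:
            raise ConfigurationError("gene_ratio must sum to 1")
        for gid, ab in self.true_abundances.items():
            total = sum(ab.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"abundances for {gid} sum to {total}, expected 1")
            if any(v < 0 for v in ab.values()):
                raise ConfigurationError(f"negative abundance for {gid}")
        rates = self.artifact_rates
        ip = rates.get("intrapriming", 0.0)
        rt = rates.get("rt_switch", 0.0)
        if ip < 0 or rt < 0 or ip + rt >= 1:
            raise ConfigurationError("artifact rates must be >= 0 and sum to < 1")
        if self.n_samples < 1:
            raise ConfigurationError("need at least one sample")


@dataclass
class SimTruth:
    """Ground truth of one simulation run.

    ``annotation`` holds the known transcripts only (what an annotation-aware
    tool would see); ``true_transcripts`` includes novel isoforms and artifact
    transcripts, keyed by ``artifact_labels`` as clean / intrapriming /
    rt_switch.  ``true_nh`` is filled by the short-read simulator with the
    true number of valid placements per (read, mate).
    """

    contig: str
    genome: str
    annotation: List[TranscriptModel]
    genes: List[GeneRecord]
    true_transcripts: List[TranscriptModel]
    true_proportions: Dict[str, float]
    artifact_labels: Dict[str, str]
    true_nh: Dict[Tuple[str, int], int] = field(default_factory=dict)
    config: Optional[SimConfig] = None

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for tx in self.true_transcripts:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)

    @property
    def parent_span(self) -> Interval:
        return next(g.span for g in self.genes if g.gene_id == PARENT_GENE)

    @property
    def pseudo_span(self) -> Interval:
        return next(g.span for g in self.genes if g.gene_id == PSEUDO_GENE)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_copy(seq: str, identity: float, seed: int) -> str:
    """Substitute each base independently with probability ``1 - identity``.

    Substitutions go to a uniformly chosen *different* base; length is
    preserved and no indels are introduced, so the realised identity is
    exactly Binomial(len, 1 - identity) distributed.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0,1], got {identity}")
    rng = np.random.default_rng([seed, 97])
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < (1.0 - identity)
    if hit.any():
        idx = {b: i for i, b in enumerate(_BASES)}
        cur = np.array([idx.get(b, 0) for b in arr[hit]])
        shift = rng.integers(1, 4, size=cur.size)
        arr[hit] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def _plant_orf(sense: List[str], start: int, stop_end: int) -> None:
    """Force an open reading frame into a sense-strand sequence in place.

    ATG at ``start``, TAA ending at ``stop_end`` (half-open), and every
    internal in-frame stop codon broken by a middle-base substitution.
    """
    assert (stop_end - start) % 3 == 0
    sense[start:start + 3] = list("ATG")
    sense[stop_end - 3:stop_end] = list("TAA")
    for p in range(start + 3, stop_end - 3, 3):
        if "".join(sense[p:p + 3]) in _STOPS:
            sense[p + 1] = "C"


def build_locus_pair(cfg: SimConfig) -> SimTruth:
    """Construct the genome, annotation and true transcript set.

    The parent gene carries four true isoforms: T1 (canonical, annotated,
    coding), T2 (exon-skipping, annotated), N1 (novel donor site, novel),
    N2 (novel 5' TSS via an extended first exon, novel).  Two artifact
    transcripts are planted with their sequence signatures written into the
    genome: an intraprimed truncation whose TTS sits just upstream of an
    A-rich window, and an RT-switch isoform whose novel junction is flanked
    by an 8-bp direct repeat.  The pseudogene copy is derived from T1
    (processed: spliced sequence; unprocessed: full genomic span) mutated to
    the configured identity.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _STREAM_GENOME])
    strand = cfg.strand
    n = cfg.n_exons

    # exon lengths in transcript (5'->3') order; the 3'-terminal exon is kept
    # long enough to host the UTR features (stop codon, A-run, RT junction)
    lo, hi = cfg.exon_len_range
    lens_tx = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    lens_tx[-1] = max(lens_tx[-1], 240)
    ilo, ihi = cfg.intron_len_range
    intron_lens = [int(rng.integers(ilo, ihi + 1)) for _ in range(n - 1)]

    lens_genomic = lens_tx if strand == "+" else lens_tx[::-1]
    parent_start = cfg.flank_bp
    exons: List[Interval] = []
    pos = parent_start
    for i, ln in enumerate(lens_genomic):
        exons.append((pos, pos + ln))
        pos += ln
        if i < n - 1:
            pos += intron_lens[i]
    parent_end = pos
    parent_len = parent_end - parent_start

    parent_seq = list(_random_seq(rng, parent_len))

    def t1_model() -> TranscriptModel:
        return TranscriptModel("PARENT.T1", PARENT_GENE, cfg.contig, strand, tuple(exons))

    t1 = t1_model()
    t1_len = t1.tx_length
    last_exon_tx_start = t1_len - lens_tx[-1]

    # work on the sense-strand spliced sequence, then write back to the genome
    def read_sense() -> List[str]:
        genome_like = "".join(parent_seq)
        s = "".join(
            genome_like[a - parent_start:b - parent_start] for a, b in exons
        )
        return list(s if strand == "+" else revcomp(s))

    def write_sense(sense: List[str]) -> None:
        s = "".join(sense)
        g = s if strand == "+" else revcomp(s)
        off = 0
        for a, b in exons:
            parent_seq[a - parent_start:b - parent_start] = list(g[off:off + (b - a)])
            off += b - a

    sense = read_sense()

    # ORF: starts 60 nt in, stop codon ends 21 nt into the terminal exon so
    # the annotated transcript is comfortably non-NMD
    orf_start = 60
    stop_end = last_exon_tx_start + 21
    stop_end = orf_start + ((stop_end - orf_start) // 3) * 3
    _plant_orf(sense, orf_start, stop_end)

    # intrapriming signature: an A-rich window (18/20 A) in the 3' UTR; the
    # artifact transcript terminates immediately upstream of it
    ip_tts = last_exon_tx_start + 45
    window = list("A" * 20)
    window[7], window[15] = "C", "C"
    sense[ip_tts + 1:ip_tts + 21] = window

    # RT-switch signature: a 60-bp "intron" in the 3' UTR whose acceptor-side
    # last 8 intronic bases duplicate the 8 exonic bases ending at the donor
    rts_u = last_exon_tx_start + 90
    rts_del = 60
    sense[rts_u + rts_del - 8:rts_u + rts_del] = sense[rts_u - 8:rts_u]

    write_sense(sense)
    t1_sense = "".join(sense)

    # CDS blocks of T1 from the planted ORF
    t1 = t1.with_cds(t1.project_tx_interval(orf_start, stop_end))

    # T2: skip the second transcript exon (annotated alternative isoform)
    tx_order = list(range(n)) if strand == "+" else list(range(n - 1, -1, -1))
    skip_genomic_idx = tx_order[1]
    t2_exons = tuple(e for i, e in enumerate(exons) if i != skip_genomic_idx)
    t2 = TranscriptModel("PARENT.T2", PARENT_GENE, cfg.contig, strand, t2_exons)

    # N1: novel donor — extend the donor side of one internal junction 6 bp
    # into the intron (an unannotated splice site)
    jn = max(1, n - 3) - 1  # transcript-order junction index
    donor_exon_gidx = tx_order[jn]
    n1_exons = list(exons)
    a, b = n1_exons[donor_exon_gidx]
    if strand == "+":
        n1_exons[donor_exon_gidx] = (a, b + 6)
    else:
        n1_exons[donor_exon_gidx] = (a - 6, b)
    n1 = TranscriptModel("PARENT.N1", PARENT_GENE, cfg.contig, strand, tuple(n1_exons))

    # N2: novel TSS — first transcript exon extended 120 bp upstream
    n2_exons = list(exons)
    first_gidx = tx_order[0]
    a, b = n2_exons[first_gidx]
    if strand == "+":
        n2_exons[first_gidx] = (a - 120, b)
    else:
        n2_exons[first_gidx] = (a, b + 120)
    n2 = TranscriptModel("PARENT.N2", PARENT_GENE, cfg.contig, strand, tuple(n2_exons))

    # artifact transcripts (long-read artifacts; sequences are T1-derived)
    art_ip = TranscriptModel(
        "PARENT.ART_IP", PARENT_GENE, cfg.contig, strand,
        t1.project_tx_interval(0, ip_tts + 1),
    )
    art_rts_blocks = t1.project_tx_interval(0, rts_u) + t1.project_tx_interval(
        rts_u + rts_del, t1_len
    )
    art_rts = TranscriptModel(
        "PARENT.ART_RTS", PARENT_GENE, cfg.contig, strand, art_rts_blocks
    )

    # pseudogene copy
    if cfg.pseudogene_class == "processed":
        mutated = mutate_copy(t1_sense, cfg.identity, cfg.seed)
        tail = _random_seq(rng, cfg.pseudo_tail_len)
        ptx_sense = mutated + tail
        pseudo_seq = ptx_sense if strand == "+" else revcomp(ptx_sense)
        pseudo_len = len(pseudo_seq)
        gene_type = "processed_pseudogene"
    else:
        parent_genomic = "".join(parent_seq)
        pseudo_seq = mutate_copy(parent_genomic, cfg.identity, cfg.seed)
        pseudo_len = len(pseudo_seq)
        gene_type = "unprocessed_pseudogene"

    spacer = _random_seq(rng, cfg.spacer_bp)
    flank_l = _random_seq(rng, cfg.flank_bp)
    flank_r = _random_seq(rng, cfg.flank_bp)
    pseudo_start = parent_end + cfg.spacer_bp
    genome = (
        flank_l
        + "".join(parent_seq)
        + spacer
        + pseudo_seq
        + flank_r
    )

    if cfg.pseudogene_class == "processed":
        p_exons: Tuple[Interval, ...] = ((pseudo_start, pseudo_start + pseudo_len),)
    else:
        shift = pseudo_start - parent_start
        p_exons = tuple((a + shift, b + shift) for a, b in exons)
    ptx = TranscriptModel("PSEUDO.T1", PSEUDO_GENE, cfg.contig, strand, p_exons)

    genes = [
        GeneRecord(
            gene_id=PARENT_GENE, gene_type="protein_coding", source="HAVANA",
            contig=cfg.contig, strand=strand, span=(parent_start, parent_end),
        ),
        GeneRecord(
            gene_id=PSEUDO_GENE, gene_type=gene_type, source="HAVANA",
            pseudo_class="Processed" if gene_type.startswith("processed") else "Unprocessed",
            parent_id=PARENT_GENE, contig=cfg.contig, strand=strand,
            span=(pseudo_start, pseudo_start + pseudo_len),
        ),
    ]

    annotation = [t1, t2, ptx]
    true_transcripts = [t1, t2, n1, n2, ptx, art_ip, art_rts]

    proportions: Dict[str, float] = {}
    for gid, ab in cfg.true_abundances.items():
        w = cfg.gene_ratio.get(gid, 0.0)
        for tid, frac in ab.items():
            proportions[tid] = w * frac
    known_ids = {tx.transcript_id for tx in true_transcripts}
    unknown = set(proportions) - known_ids
    if unknown:
        raise ConfigurationError(f"abundances refer to unknown transcripts: {sorted(unknown)}")

    labels = {tx.transcript_id: "clean" for tx in true_transcripts}
    labels["PARENT.ART_IP"] = "intrapriming"
    labels["PARENT.ART_RTS"] = "rt_switch"

    return SimTruth(
        contig=cfg.contig,
        genome=genome,
        annotation=annotation,
        genes=genes,
        true_transcripts=true_transcripts,
        true_proportions=proportions,
        artifact_labels=labels,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# full-length-read counts
# ---------------------------------------------------------------------------

def simulate_flr_counts(truth: SimTruth, cfg: Optional[SimConfig] = None) -> pd.DataFrame:
    """Draw the transcript x sample full-length-read matrix.

    Counts are multinomial per sample at the sample's library size, so
    per-sample totals are exact.  A fraction ``artifact_rates.intrapriming``
    (resp. ``rt_switch``) of each parent-gene read mass is reassigned to the
    planted artifact transcripts.
    """
    cfg = cfg or truth.config
    assert cfg is not None
    cfg.validate()
    ip = cfg.artifact_rates.get("intrapriming", 0.0)
    rt = cfg.artifact_rates.get("rt_switch", 0.0)

    tids: List[str] = []
    probs: List[float] = []
    for tid, p in sorted(truth.true_proportions.items()):
        gene = truth.transcript(tid).gene_id
        scale = (1.0 - ip - rt) if gene == PARENT_GENE else 1.0
        tids.append(tid)
        probs.append(p * scale)
    w_parent = cfg.gene_ratio.get(PARENT_GENE, 0.0)
    for art_id, rate in (("PARENT.ART_IP", ip), ("PARENT.ART_RTS", rt)):
        tids.append(art_id)
        probs.append(w_parent * rate)
    pvec = np.asarray(probs)
    pvec = pvec / pvec.sum()

    samples = cfg.samples()
    data = {}
    for i, sample in enumerate(samples):
        srng = np.random.default_rng([cfg.seed, _STREAM_FLR, i])
        data[sample] = srng.multinomial(cfg.library_size(sample), pvec)
    flr = pd.DataFrame(data, index=tids)
    flr.index.name = "transcript_id"
    return flr


# ---------------------------------------------------------------------------
# short-read alignment simulation
# ---------------------------------------------------------------------------

def merge_overlapping_placements(
    items: Sequence[Tuple[int, str, str, int, int]]
) -> List[Tuple[int, str, str, int]]:
    """Collapse placements with overlapping reference footprints to one
    alignment per genomic window.

    ``items`` are (start, cigar, strand, n_mismatch, contiguous_flag); the
    cluster representative minimises (mismatches, contiguous-before-spliced
    penalty, start).  Returns (start, cigar, strand, n_mismatch), sorted.
    """
    from .multimap import reference_width

    spans = sorted(
        (s, s + reference_width(c), c, st, mm, spl) for s, c, st, mm, spl in items
    )
    merged: List[Tuple[int, str, str, int]] = []
    cluster: List[Tuple[int, int, str, str, int, int]] = []
    cluster_end = -1

    def flush() -> None:
        if cluster:
            best = min(cluster, key=lambda x: (x[4], x[5], x[0], x[2]))
            merged.append((best[0], best[2], best[3], best[4]))

    for it in spans:
        if cluster and it[0] >= cluster_end:
            flush()
            cluster = []
            cluster_end = -1
        cluster.append(it)
        cluster_end = max(cluster_end, it[1])
    flush()
    return sorted(merged)


class _PlacementIndex:
    """Exhaustive mismatch-bounded placement search over a genome plus a set
    of annotated spliced transcript sequences (emulating an annotation-guided
    splice-aware aligner).

    Seeding uses the pigeonhole principle: a read with at most ``m``
    mismatches must contain one of ``m + 1`` disjoint exact seed chunks, so
    the chunk-index lookup plus full verification finds *all* placements with
    <= m mismatches — identical to a brute-force scan, just faster.
    """

    def __init__(self, truth: SimTruth, read_len: int, max_mismatch: int):
        self.read_len = read_len
        self.max_mismatch = max_mismatch
        self.k = max(8, read_len // (max_mismatch + 1))
        if self.k * (max_mismatch + 1) > read_len:
            self.k = read_len // (max_mismatch + 1)
        if self.k < 4:
            raise ConfigurationError("read_len too short for the mismatch cap")
        self.refs: Dict[str, np.ndarray] = {}
        self.transcripts: Dict[str, TranscriptModel] = {}
        self._add_ref("genome", truth.genome)
        for tx in truth.annotation:
            self._add_ref(tx.transcript_id, tx.spliced_sequence(truth.genome))
            self.transcripts[tx.transcript_id] = tx
        self.contig = truth.contig

    def _add_ref(self, name: str, seq: str) -> None:
        self.refs[name] = np.frombuffer(seq.encode(), dtype=np.uint8)
        if not hasattr(self, "_index"):
            self._index: Dict[bytes, List[Tuple[str, int]]] = {}
        arr = seq.encode()
        k = self.k
        for i in range(len(arr) - k + 1):
            self._index.setdefault(arr[i:i + k], []).append((name, i))

    def _candidates(self, q: bytes) -> Dict[Tuple[str, int], None]:
        out: Dict[Tuple[str, int], None] = {}
        k, m = self.k, self.max_mismatch
        for j in range(m + 1):
            chunk = q[j * k:(j + 1) * k]
            for name, pos in self._index.get(chunk, ()):  # pragma: no branch
                start = pos - j * k
                if start >= 0:
                    out[(name, start)] = None
        return out

    def _verify(self, q_arr: np.ndarray, name: str, start: int) -> Optional[int]:
        ref = self.refs[name]
        end = start + q_arr.size
        if end > ref.size:
            return None
        mm = int(np.count_nonzero(ref[start:end] != q_arr))
        return mm if mm <= self.max_mismatch else None

    def _genomic_placement(
        self, name: str, start: int, length: int, query_is_sense: bool
    ) -> Tuple[int, str, str]:
        """Project a reference-local hit to (genomic start, CIGAR, strand)."""
        if name == "genome":
            return start, f"{length}M", "+" if query_is_sense else "-"
        tx = self.transcripts[name]
        blocks = tx.project_tx_interval(start, start + length)
        cigar_parts = []
        for i, (a, b) in enumerate(blocks):
            if i:
                gap = a - blocks[i - 1][1]
                cigar_parts.append(f"{gap}N")
            cigar_parts.append(f"{b - a}M")
        strand = tx.strand if query_is_sense else ("-" if tx.strand == "+" else "+")
        return blocks[0][0], "".join(cigar_parts), strand

    def placements(self, seq: str) -> List[Tuple[int, str, str, int]]:
        """Distinct genomic placements of ``seq`` with <= max_mismatch
        mismatches, as (start, cigar, strand, n_mismatch).

        Placements whose reference footprints overlap are merged into one
        (a single alignment per genomic window), preferring fewer mismatches
        and, on ties, a spliced placement over a contiguous one — the way an
        annotation-aware aligner's splice-junction bonus breaks such ties.
        """
        found: Dict[Tuple[int, str, str], Tuple[int, int]] = {}
        for query, is_sense in ((seq, True), (revcomp(seq), False)):
            q = query.encode()
            q_arr = np.frombuffer(q, dtype=np.uint8)
            for name, start in self._candidates(q):
                mm = self._verify(q_arr, name, start)
                if mm is None:
                    continue
                key = self._genomic_placement(name, start, len(seq), is_sense)
                spliced = 0 if "N" in key[1] else 1
                if key not in found or (mm, spliced) < found[key]:
                    found[key] = (mm, spliced)
        return merge_overlapping_placements(
            [(s, c, st, mm, spl) for (s, c, st), (mm, spl) in found.items()]
        )


def simulate_short_read_alignments(
    truth: SimTruth, cfg: Optional[SimConfig] = None
) -> List[AlignedRead]:
    """Sample paired-end reads from the expressed (clean) transcripts and
    place them exhaustively on the two-locus genome.

    Placement search runs against the genome *plus the annotated transcript
    sequences* — spliced alignments are only available across annotated
    junctions, exactly as with an annotation-guided short-read aligner, so
    reads crossing unannotated junctions go unplaced.  NH is the number of
    distinct genomic placements; every distinct placement is emitted.  The
    true NH of each mate (0 for unplaceable reads) is recorded in
    ``truth.true_nh``.
    """
    cfg = cfg or truth.config
    assert cfg is not None
    cfg.validate()
    sr = cfg.short_read
    read_len = int(sr["read_len"])
    n_pairs = int(sr["n_pairs"])
    max_mm = int(sr.get("max_mismatch", 4))
    frag_len = int(sr.get("fragment_len", max(2 * read_len + 50, read_len)))

    rng = np.random.default_rng([cfg.seed, _STREAM_READS])
    clean = [
        tid for tid, p in sorted(truth.true_proportions.items())
        if p > 0 and truth.artifact_labels.get(tid, "clean") == "clean"
    ]
    probs = np.array([truth.true_proportions[t] for t in clean])
    probs = probs / probs.sum()
    seqs = {t: truth.transcript(t).spliced_sequence(truth.genome) for t in clean}
    for t, s in seqs.items():
        if read_len > len(s):
            raise ConfigurationError(f"read_len {read_len} exceeds transcript {t} length")

    index = _PlacementIndex(truth, read_len, max_mm)
    counts = rng.multinomial(n_pairs, probs)
    reads: List[AlignedRead] = []
    pair_idx = 0
    for tid, n_tx in zip(clean, counts):
        s = seqs[tid]
        frag = min(frag_len, len(s))
        # fragment starts are uniform over the transcript; fragments running
        # off the 3' end are truncated (fragmentation does not respect the
        # nominal insert size), so first mates sample the whole transcript.
        # Library convention: mate 1 reads the transcript sense strand.
        starts = rng.integers(0, len(s) - read_len + 1, size=n_tx)
        for st in starts:
            name = f"r{pair_idx:06d}"
            pair_idx += 1
            frag_eff = min(frag, len(s) - st)
            mate1 = s[st:st + read_len]
            mate2 = revcomp(s[st + frag_eff - read_len:st + frag_eff])
            for mate_no, seq in ((1, mate1), (2, mate2)):
                placements = index.placements(seq)
                truth.true_nh[(name, mate_no)] = len(placements)
                nh = len(placements)
                for gstart, cigar, strand, _mm in placements:
                    reads.append(
                        AlignedRead(
                            read_name=name,
                            contig=truth.contig,
                            start=int(gstart),
                            cigar=cigar,
                            nh=nh,
                            strand=strand,
                            is_first_mate=(mate_no == 1),
                            is_paired=True,
                            sequence=seq,
                        )
                    )
    return reads


# ---------------------------------------------------------------------------
# junction-level counts (for the annotation-incompleteness survey)
# ---------------------------------------------------------------------------

def simulate_junction_counts(truth: SimTruth, cfg: Optional[SimConfig] = None) -> pd.DataFrame:
    """Per-sample split-read support for every junction of every expressed
    true transcript (the short-read view a junction database would hold).

    Rows are junctions keyed by (contig, start, end, strand) with start/end
    delimiting the intron, 0-based half-open; one column per sample.
    Expected support is proportional to transcript abundance.
    """
    cfg = cfg or truth.config
    assert cfg is not None
    junctions: Dict[Tuple[str, int, int, str], float] = {}
    for tx in truth.true_transcripts:
        p = truth.true_proportions.get(tx.transcript_id, 0.0)
        if p <= 0:
            continue
        for (a, b) in tx.introns:
            key = (tx.contig, a, b, tx.strand)
            junctions[key] = junctions.get(key, 0.0) + p
    keys = sorted(junctions)
    samples = cfg.samples()
    data = {}
    for i, sample in enumerate(samples):
        srng = np.random.default_rng([cfg.seed, _STREAM_JUNC, i])
        depth = cfg.library_size(sample) / 10.0
        lam = np.array([junctions[k] for k in keys]) * depth
        data[sample] = srng.poisson(lam)
    df = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(keys, names=["contig", "start", "end", "strand"]))
    return df
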