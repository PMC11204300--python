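"""Core in-memory types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; converters to the
1-based inclusive GTF convention live in :mod:`pseudoscope.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


Interval = Tuple[int, int]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one isoform on a genome.

    Exons are 0-based half-open intervals sorted by genomic start and
    non-overlapping.  The junction chain (the ordered introns between
    consecutive exons) is the unit of structural comparison: two transcripts
    with the same chain are splice-identical regardless of terminal-exon
    boundaries.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    exons: Tuple[Interval, ...]
    cds: Tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"empty exon ({a},{b}) in {self.transcript_id}")
        for (_, b), (a2, _) in zip(exons, exons[1:]):
            if a2 < b:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted((int(a), int(b)) for a, b in self.cds)))
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    # -- genomic geometry ---------------------------------------------------
    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Genomic introns, ascending; empty for mono-exonic transcripts."""
        return tuple((e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:]))

    @property
    def junction_chain(self) -> Tuple[Interval, ...]:
        """Introns ordered 5'->3' along the transcript."""
        ints = self.introns
        return ints if self.strand == "+" else ints[::-1]

    @property
    def donors(self) -> Tuple[int, ...]:
        """Donor positions, one per intron: first intronic base (0-based) on
        the transcript strand."""
        if self.strand == "+":
            return tuple(s for s, _ in self.junction_chain)
        return tuple(e - 1 for _, e in self.junction_chain)

    @property
    def acceptors(self) -> Tuple[int, ...]:
        """Acceptor positions, one per intron: last intronic base (0-based)."""
        if self.strand == "+":
            return tuple(e - 1 for _, e in self.junction_chain)
        return tuple(s for s, _ in self.junction_chain)

    @property
    def tx_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def tss(self) -> int:
        """Genomic position (0-based) of the transcript's first base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def tts(self) -> int:
        """Genomic position (0-based) of the transcript's last base."""
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]

    # -- sequence & coordinate projection -----------------------------------
    def spliced_sequence(self, genome: str) -> str:
        """mRNA-sense sequence obtained by concatenating exons and, for minus
        strand, reverse-complementing."""
        s = "".join(genome[a:b] for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)

    def tx_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate (0-based, 5'->3') to its genomic base."""
        if not 0 <= pos < self.tx_length:
            raise IndexError(pos)
        if self.strand == "-":
            pos = self.tx_length - 1 - pos
        for a, b in self.exons:
            if pos < b - a:
                return a + pos
            pos -= b - a
        raise AssertionError("unreachable")

    def project_tx_interval(self, start: int, end: int) -> Tuple[Interval, ...]:
        """Project a transcript-coordinate interval [start, end) onto genomic
        blocks (ascending, half-open), splitting at introns."""
        if not 0 <= start < end <= self.tx_length:
            raise IndexError((start, end))
        if self.strand == "-":
            start, end = self.tx_length - end, self.tx_length - start
        blocks = []
        off = 0
        for a, b in self.exons:
            length = b - a
            lo, hi = max(start, off), min(end, off + length)
            if lo < hi:
                blocks.append((a + lo - off, a + hi - off))
            off += length
        return tuple(blocks)

    def junction_tx_positions(self) -> Tuple[int, ...]:
        """Transcript coordinates of each junction: the index of the first
        base of the downstream exon, in 5'->3' order."""
        lens = [b - a for a, b in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        out, acc = [], 0
        for ln in lens[:-1]:
            acc += ln
            out.append(acc)
        return tuple(out)

    def with_cds(self, cds: Sequence[Interval]) -> "TranscriptModel":
        return replace(self, cds=tuple(cds))


@dataclass
class AlignedRead:
    """One alignment record: the subset of SAM a locus-level multimapping
    analysis needs (NH tag included)."""

    read_name: str
    contig: str
    start: int  # 0-based leftmost reference position
    cigar: str
    nh: int
    strand: str  # "+" or "-"
    is_first_mate: bool = True
    is_paired: bool = True
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.nh < 1:
            raise ValueError("NH must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class GeneRecord:
    """A gene row from a GENCODE-style annotation with its pseudogene class."""

    gene_id: str
    gene_type: str
    source: str = ""
    pseudo_class: str = "NotPseudogene"
    parent_id: Optional[str] = None
    contig: Optional[str] = None
    strand: Optional[str] = None
    span: Optional[Interval] = None


@dataclass
class OrfPrediction:
    """Longest-ORF call on a spliced transcript sequence.

    ``start``/``stop`` are transcript coordinates: ``start`` points at the A
    of the initiator ATG, ``stop`` one past the last base of the stop codon
    (half-open), so ``stop - start`` is a multiple of 3.
    """

    start: int
    stop: int
    protein: str
    nmd: bool = False
    novel_orf: bool = False
    has_stop: bool = True

    @property
    def length_aa(self) -> int:
        return len(self.protein)


STRUCTURAL_CLASSES = ("FSM", "ISM", "NIC", "NNC")
END_STATUSES = ("complete_match", "alt5", "alt3", "alt5+alt3", "n/a")
FINAL_CATEGORIES = (
    "coding_known_complete",
    "coding_known_alt_ends",
    "coding_novel",
    "nmd_known",
    "nmd_novel",
    "noncoding_known",
    "noncoding_novel",
)


@dataclass
class CategoryCall:
    """Structural class plus coding/NMD status and the final 7-way category."""

    transcript_id: str
    structural: str
    matched_reference: Optional[str]
    end_status: str
    coding: bool
    nmd: bool
    final: str
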