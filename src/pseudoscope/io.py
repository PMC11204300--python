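"""Readers and writers for the standard formats the pipeline touches.

GTF is read through gffutils (GENCODE attribute dialect) and written
1-based inclusive; SAM goes through pysam; FASTA through Biopython.
Internal coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedRead, GeneRecord, TranscriptModel


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path: str, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(pairs: Sequence[Tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(
    path: str,
    transcripts: Sequence[TranscriptModel],
    genes: Optional[Sequence[GeneRecord]] = None,
    source: str = "HAVANA",
    gene_types: Optional[Dict[str, str]] = None,
) -> None:
    """Emit gene/transcript/exon/CDS rows, 1-based inclusive, stable-sorted.

    ``gene_types`` maps gene_id -> gene_type attribute; genes without an
    explicit GeneRecord are synthesised from their transcripts' extent.
    """
    gene_types = dict(gene_types or {})
    gene_rows: Dict[str, GeneRecord] = {}
    for g in genes or []:
        gene_rows[g.gene_id] = g
        if g.gene_type:
            gene_types.setdefault(g.gene_id, g.gene_type)
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gid, txs in by_gene.items():
        if gid not in gene_rows:
            lo = min(t.span[0] for t in txs)
            hi = max(t.span[1] for t in txs)
            gene_rows[gid] = GeneRecord(
                gene_id=gid,
                gene_type=gene_types.get(gid, "protein_coding"),
                contig=txs[0].contig,
                strand=txs[0].strand,
                span=(lo, hi),
            )

    lines: List[str] = []
    for gid in sorted(gene_rows):
        g = gene_rows[gid]
        gtype = gene_types.get(gid, g.gene_type or "protein_coding")
        attrs = [("gene_id", gid), ("gene_type", gtype)]
        if g.span is not None:
            lines.append(
                "\t".join(
                    [
                        g.contig or "?",
                        source,
                        "gene",
                        str(g.span[0] + 1),
                        str(g.span[1]),
                        ".",
                        g.strand or ".",
                        ".",
                        _gtf_attributes(attrs),
                    ]
                )
            )
        for tx in sorted(by_gene.get(gid, []), key=lambda t: t.transcript_id):
            tattrs = [
                ("gene_id", gid),
                ("transcript_id", tx.transcript_id),
                ("gene_type", gtype),
            ]
            lines.append(
                "\t".join(
                    [
                        tx.contig,
                        source,
                        "transcript",
                        str(tx.span[0] + 1),
                        str(tx.span[1]),
                        ".",
                        tx.strand,
                        ".",
                        _gtf_attributes(tattrs),
                    ]
                )
            )
            for a, b in tx.exons:
                lines.append(
                    "\t".join(
                        [tx.contig, source, "exon", str(a + 1), str(b), ".", tx.strand, ".", _gtf_attributes(tattrs)]
                    )
                )
            for a, b in tx.cds:
                lines.append(
                    "\t".join(
                        [tx.contig, source, "CDS", str(a + 1), str(b), ".", tx.strand, "0", _gtf_attributes(tattrs)]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gtf(path: str) -> Tuple[List[TranscriptModel], List[GeneRecord]]:
    """Load transcripts (with exons/CDS) and gene records from a GTF file."""
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneRecord] = []
    for g in db.features_of_type("gene"):
        genes.append(
            GeneRecord(
                gene_id=g.attributes.get("gene_id", ["?"])[0],
                gene_type=g.attributes.get("gene_type", [""])[0],
                source=g.source,
                contig=g.seqid,
                strand=g.strand,
                span=(g.start - 1, g.end),
            )
        )
    transcripts: List[TranscriptModel] = []
    for t in db.features_of_type("transcript"):
        tid = t.attributes.get("transcript_id", ["?"])[0]
        exons = tuple(
            (e.start - 1, e.end) for e in db.children(t, featuretype="exon", order_by="start")
        )
        cds = tuple(
            (c.start - 1, c.end) for c in db.children(t, featuretype="CDS", order_by="start")
        )
        if not exons:
            continue
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=t.attributes.get("gene_id", ["?"])[0],
                contig=t.seqid,
                strand=t.strand,
                exons=exons,
                cds=cds,
            )
        )
    return transcripts, genes


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(path: str, reads: Iterable[AlignedRead], contigs: Dict[str, int]) -> None:
    """Write alignment records as SAM text with @SQ header lines and NH tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_name
            a.reference_name = r.contig
            a.reference_start = r.start
            a.cigarstring = r.cigar
            a.mapping_quality = 255 if r.nh == 1 else 0
            flag = 0
            if r.is_paired:
                flag |= 0x1 | 0x2
                flag |= 0x40 if r.is_first_mate else 0x80
                # mate strand is opposite for a proper pair
                flag |= 0x20 if r.strand == "+" else 0x0
            if r.strand == "-":
                flag |= 0x10
            a.flag = flag
            if r.sequence is not None:
                a.query_sequence = r.sequence
            a.set_tag("NH", r.nh)
            out.write(a)


def read_sam(path: str, require_nh: bool = True) -> List[AlignedRead]:
    """Read a SAM/BAM file into AlignedRead records.

    Files lacking NH tags are rejected (the multimapping analysis is
    meaningless without the number-of-alignments tag).
    """
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if not a.has_tag("NH"):
                if require_nh:
                    raise ValueError(
                        f"{path}: alignment {a.query_name} lacks the NH tag; "
                        "re-run the aligner with NH reporting enabled"
                    )
                nh = 1
            else:
                nh = int(a.get_tag("NH"))
            reads.append(
                AlignedRead(
                    read_name=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start,
                    cigar=a.cigarstring,
                    nh=nh,
                    strand="-" if a.is_reverse else "+",
                    is_first_mate=bool(a.is_read1) or not a.is_paired,
                    is_paired=a.is_paired,
                )
            )
    return reads
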