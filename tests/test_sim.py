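"""Simulator: sequence mutation, locus construction, count and read models."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from pseudoscope import io
from pseudoscope.models import revcomp
from pseudoscope.multimap import Locus, select_locus_reads, unique_mapping_rate
from pseudoscope.qc import perc_a_downstream
from pseudoscope.sim import (
    PARENT_GENE,
    PSEUDO_GENE,
    ConfigurationError,
    SimConfig,
    build_locus_pair,
    mutate_copy,
    simulate_flr_counts,
    simulate_junction_counts,
    simulate_short_read_alignments,
)

from dataclasses import replace


# ---------------------------------------------------------------------------
# mutate_copy
# ---------------------------------------------------------------------------

def test_mutate_identity_one_is_noop():
    assert mutate_copy("ACGT", 1.0, seed=1) == "ACGT"


def test_mutate_identity_zero_substitutes_every_base():
    seq = "ACGT" * 50
    out = mutate_copy(seq, 0.0, seed=3)
    assert len(out) == len(seq)
    assert all(a != b for a, b in zip(seq, out))


def test_mutate_rate_within_binomial_interval():
    n = 10_000
    seq = "A" * n
    out = mutate_copy(seq, 0.9, seed=5)
    dist = sum(a != b for a, b in zip(seq, out))
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.1)
    assert lo <= dist <= hi


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def test_processed_copy_at_full_identity_equals_parent_exons():
    cfg = SimConfig(seed=2, identity=1.0, pseudo_tail_len=0)
    truth = build_locus_pair(cfg)
    t1 = truth.transcript("PARENT.T1")
    parent_exonic = "".join(truth.genome[a:b] for a, b in t1.exons)
    ps, pe = truth.pseudo_span
    assert truth.genome[ps:pe] == parent_exonic


def test_pseudogene_mismatches_within_binomial_interval():
    cfg = SimConfig(seed=4, identity=0.96, pseudo_tail_len=0)
    truth = build_locus_pair(cfg)
    t1_sense = truth.transcript("PARENT.T1").spliced_sequence(truth.genome)
    p_sense = truth.transcript("PSEUDO.T1").spliced_sequence(truth.genome)
    assert len(p_sense) == len(t1_sense)
    mm = sum(a != b for a, b in zip(t1_sense, p_sense))
    lo, hi = stats.binom.ppf([0.005, 0.995], len(t1_sense), 0.04)
    assert lo <= mm <= hi


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    for run in ("a", "b"):
        cfg = SimConfig(seed=9)
        truth = build_locus_pair(cfg)
        io.write_fasta({truth.contig: truth.genome}, tmp_path / f"{run}.fa")
        io.write_gtf(str(tmp_path / f"{run}.gtf"), truth.annotation, truth.genes)
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


def test_infeasible_ranges_raise():
    with pytest.raises(ConfigurationError):
        build_locus_pair(SimConfig(exon_len_range=(200, 100)))
    with pytest.raises(ConfigurationError):
        build_locus_pair(SimConfig(intron_len_range=(5, 10)))
    with pytest.raises(ConfigurationError):
        SimConfig(identity=1.5).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(true_abundances={PARENT_GENE: {"PARENT.T1": 0.5}}).validate()


def test_loci_at_least_10kb_apart(default_truth):
    assert default_truth.pseudo_span[0] - default_truth.parent_span[1] >= 10_000


def test_novel_transcripts_differ_from_every_reference(default_truth):
    refs = default_truth.annotation
    for tid in ("PARENT.N1", "PARENT.N2"):
        novel = default_truth.transcript(tid)
        for ref in refs:
            same_chain = novel.junction_chain == ref.junction_chain
            same_ends = novel.span == ref.span
            assert not (same_chain and same_ends)


def test_unprocessed_copy_keeps_intron_structure():
    cfg = SimConfig(seed=6, pseudogene_class="unprocessed")
    truth = build_locus_pair(cfg)
    ptx = truth.transcript("PSEUDO.T1")
    t1 = truth.transcript("PARENT.T1")
    assert len(ptx.exons) == len(t1.exons)
    shift = ptx.exons[0][0] - t1.exons[0][0]
    assert all(
        (a + shift, b + shift) == pe for (a, b), pe in zip(t1.exons, ptx.exons)
    )


# ---------------------------------------------------------------------------
# full-length-read counts
# ---------------------------------------------------------------------------

def test_single_transcript_gets_whole_library():
    cfg = SimConfig(
        seed=3,
        gene_ratio={PARENT_GENE: 1.0, PSEUDO_GENE: 0.0},
        true_abundances={PARENT_GENE: {"PARENT.T1": 1.0}},
        artifact_rates={"intrapriming": 0.0, "rt_switch": 0.0},
        library_sizes={"S1": 500},
    )
    flr = simulate_flr_counts(build_locus_pair(cfg), cfg)
    assert flr.loc["PARENT.T1", "S1"] == 500
    assert flr["S1"].sum() == 500


def test_two_transcript_counts_within_multinomial_interval():
    cfg = SimConfig(
        seed=8,
        gene_ratio={PARENT_GENE: 1.0, PSEUDO_GENE: 0.0},
        true_abundances={PARENT_GENE: {"PARENT.T1": 0.6, "PARENT.T2": 0.4}},
        artifact_rates={"intrapriming": 0.0, "rt_switch": 0.0},
        library_sizes={"S1": 10_000},
    )
    flr = simulate_flr_counts(build_locus_pair(cfg), cfg)
    c1 = flr.loc["PARENT.T1", "S1"]
    lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.6)
    assert lo <= c1 <= hi
    assert flr["S1"].sum() == 10_000


def test_intrapriming_reassignment_within_binomial_interval():
    cfg = SimConfig(
        seed=12,
        gene_ratio={PARENT_GENE: 1.0, PSEUDO_GENE: 0.0},
        true_abundances={PARENT_GENE: {"PARENT.T1": 1.0}},
        artifact_rates={"intrapriming": 0.1, "rt_switch": 0.0},
        library_sizes={"S1": 10_000},
    )
    flr = simulate_flr_counts(build_locus_pair(cfg), cfg)
    n_art = flr.loc["PARENT.ART_IP", "S1"]
    lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.1)
    assert lo <= n_art <= hi


def test_flr_conservation_per_sample(default_truth):
    flr = simulate_flr_counts(default_truth)
    for sample in flr.columns:
        assert flr[sample].sum() == default_truth.config.library_size(sample)


def test_planted_intrapriming_tts_is_a_rich(default_truth):
    art = default_truth.transcript("PARENT.ART_IP")
    assert perc_a_downstream(default_truth.genome, art.tts, art.strand) > 80


# ---------------------------------------------------------------------------
# short-read alignments
# ---------------------------------------------------------------------------

def _brute_force_placements(truth, seq, max_mm):
    """Independent oracle: naive sliding-window scan of the genome and of
    every annotated spliced transcript sequence, both orientations, followed
    by the one-alignment-per-overlapping-window rule."""
    raw = {}
    L = len(seq)

    def scan(ref_seq):
        ref = np.frombuffer(ref_seq.encode(), np.uint8)
        out = []
        for query in (seq, revcomp(seq)):
            q = np.frombuffer(query.encode(), np.uint8)
            for i in range(ref.size - L + 1):
                mm = int((ref[i:i + L] != q).sum())
                if mm <= max_mm:
                    out.append((i, query is seq, mm))
        return out

    for i, is_sense, mm in scan(truth.genome):
        key = (i, i + L, f"{L}M", "+" if is_sense else "-")
        raw[key] = min(raw.get(key, (99, 9)), (mm, 1))
    for tx in truth.annotation:
        s = tx.spliced_sequence(truth.genome)
        for i, is_sense, mm in scan(s):
            blocks = tx.project_tx_interval(i, i + L)
            cigar = []
            for k, (a, b) in enumerate(blocks):
                if k:
                    cigar.append(f"{a - blocks[k - 1][1]}N")
                cigar.append(f"{b - a}M")
            strand = tx.strand if is_sense else ("+" if tx.strand == "-" else "-")
            key = (blocks[0][0], blocks[-1][1], "".join(cigar), strand)
            spliced = 0 if len(blocks) > 1 else 1
            raw[key] = min(raw.get(key, (99, 9)), (mm, spliced))

    # greedy interval clustering, representative = min(mm, contiguous, start)
    spans = sorted((s, e, c, st, mm, spl) for (s, e, c, st), (mm, spl) in raw.items())
    clusters, cur, cur_end = [], [], -1
    for it in spans:
        if cur and it[0] >= cur_end:
            clusters.append(cur)
            cur, cur_end = [], -1
        cur.append(it)
        cur_end = max(cur_end, it[1])
    if cur:
        clusters.append(cur)
    out = set()
    for cl in clusters:
        best = min(cl, key=lambda x: (x[4], x[5], x[0], x[2]))
        out.add((best[0], best[2], best[3]))
    return out


def test_nh_matches_brute_force_oracle():
    cfg = SimConfig(seed=21, short_read={"read_len": 100, "n_pairs": 25,
                                         "max_mismatch": 4, "fragment_len": 260})
    truth = build_locus_pair(cfg)
    reads = simulate_short_read_alignments(truth, cfg)
    by_read = {}
    for r in reads:
        by_read.setdefault((r.read_name, r.is_first_mate), []).append(r)
    checked = 0
    for (name, first), placements in list(by_read.items())[:30]:
        seq = placements[0].sequence
        oracle = _brute_force_placements(truth, seq, 4)
        assert placements[0].nh == len(oracle)
        assert {(r.start, r.cigar, r.strand) for r in placements} == oracle
        checked += 1
    assert checked > 0


def test_low_identity_means_all_unique():
    """Constructed so every read window differs from the homologous locus
    (50% identity) and no junction ambiguity exists (mono-exonic source):
    every read must be uniquely placed."""
    cfg = SimConfig(
        seed=14,
        identity=0.5,
        gene_ratio={PARENT_GENE: 0.0, PSEUDO_GENE: 1.0},
        true_abundances={PSEUDO_GENE: {"PSEUDO.T1": 1.0}},
        short_read={"read_len": 100, "n_pairs": 300, "max_mismatch": 4,
                    "fragment_len": 260},
    )
    truth = build_locus_pair(cfg)
    reads = simulate_short_read_alignments(truth, cfg)
    assert reads
    assert all(r.nh == 1 for r in reads)


def test_full_identity_full_span_copy_leaves_no_unique_parent_reads():
    cfg = SimConfig(
        seed=15,
        identity=1.0,
        pseudo_tail_len=0,
        true_abundances={
            PARENT_GENE: {"PARENT.T1": 1.0},
            PSEUDO_GENE: {"PSEUDO.T1": 1.0},
        },
        short_read={"read_len": 100, "n_pairs": 400, "max_mismatch": 4,
                    "fragment_len": 260},
    )
    truth = build_locus_pair(cfg)
    reads = simulate_short_read_alignments(truth, cfg)
    assert all(r.nh >= 2 for r in reads)
    g = next(g for g in truth.genes if g.gene_id == PARENT_GENE)
    locus = Locus(truth.contig, g.span[0], g.span[1], g.strand)
    selected = select_locus_reads(reads, locus)
    assert unique_mapping_rate(selected) == 0.0


def test_unique_fraction_monotone_in_identity():
    """Higher parent/pseudogene identity never increases the parent gene's
    expected unique-mapping fraction (mean over seeds)."""
    means = []
    for identity in (0.80, 0.90, 0.96, 1.00):
        rates = []
        for seed in range(10):
            cfg = SimConfig(
                seed=seed, identity=identity,
                short_read={"read_len": 100, "n_pairs": 400,
                            "max_mismatch": 4, "fragment_len": 260},
            )
            truth = build_locus_pair(cfg)
            reads = simulate_short_read_alignments(truth, cfg)
            g = next(g for g in truth.genes if g.gene_id == PARENT_GENE)
            locus = Locus(truth.contig, g.span[0], g.span[1], g.strand)
            rates.append(unique_mapping_rate(select_locus_reads(reads, locus)))
        means.append(np.mean(rates))
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_sam_round_trip(tmp_path, default_truth):
    cfg = replace(default_truth.config,
                  short_read={"read_len": 100, "n_pairs": 50,
                              "max_mismatch": 4, "fragment_len": 260})
    truth = build_locus_pair(cfg)
    reads = simulate_short_read_alignments(truth, cfg)
    path = tmp_path / "aln.sam"
    io.write_sam(str(path), reads, {truth.contig: len(truth.genome)})
    back = io.read_sam(str(path))
    assert len(back) == len(reads)
    orig = sorted((r.read_name, r.start, r.cigar, r.nh, r.strand, r.is_first_mate)
                  for r in reads)
    rt = sorted((r.read_name, r.start, r.cigar, r.nh, r.strand, r.is_first_mate)
                for r in back)
    assert orig == rt


def test_junction_counts_cover_novel_junction(default_truth):
    jm = simulate_junction_counts(default_truth)
    n1 = default_truth.transcript("PARENT.N1")
    known = set()
    for tx in default_truth.annotation:
        known.update(tx.introns)
    novel = [i for i in n1.introns if i not in known]
    assert novel
    key = (default_truth.contig, novel[0][0], novel[0][1], n1.strand)
    assert key in jm.index
    assert (jm.loc[[key]].iloc[0] > 0).all()
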