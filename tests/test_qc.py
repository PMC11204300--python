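"""Isoform QC: intrapriming/RT-switch detection, NFLR math, retention."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pseudoscope.models import TranscriptModel, revcomp
from pseudoscope.qc import (
    REASON_INTRAPRIMING,
    REASON_RT_SWITCH,
    REASON_WRONG_GENE,
    apply_artifact_filters,
    nflr_normalize,
    perc_a_downstream,
    retain_by_expression,
    rts_flag,
    run_isoform_qc,
)
from pseudoscope.sim import PARENT_GENE, SimConfig, build_locus_pair, simulate_flr_counts


# ---------------------------------------------------------------------------
# perc_a_downstream
# ---------------------------------------------------------------------------

def test_perc_a_all_a_window():
    genome = "C" * 10 + "A" * 20 + "C" * 10
    assert perc_a_downstream(genome, tts=9, strand="+") == pytest.approx(100.0)


def test_perc_a_17_of_20():
    genome = "C" * 10 + "A" * 17 + "GGG" + "C" * 10
    assert perc_a_downstream(genome, tts=9, strand="+") == pytest.approx(85.0)


def test_perc_a_minus_strand_counts_reference_t():
    # minus-strand transcript ending at position 30; reference upstream
    # window all T => all sense A
    genome = "C" * 10 + "T" * 20 + "G" * 10
    assert perc_a_downstream(genome, tts=30, strand="-") == pytest.approx(100.0)


def test_perc_a_window_truncated_at_edge():
    genome = "A" * 10
    with pytest.warns(UserWarning):
        pct = perc_a_downstream(genome, tts=5, strand="+")
    assert pct == pytest.approx(100.0)  # 4 of 4 available bases


def test_perc_a_tts_out_of_range():
    with pytest.raises(ValueError):
        perc_a_downstream("ACGT", 10, "+")


# ---------------------------------------------------------------------------
# rts_flag
# ---------------------------------------------------------------------------

def _planted_rts_genome(repeat="ACGTACGT"):
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    g = list("".join(bases[rng.integers(0, 4, 300)]))
    # exon [0,100), intron [100, 200), exon [200, 300) on + strand
    g[100 - 8:100] = list(repeat)  # exon end at donor
    g[200 - 8:200] = list(repeat)  # intron end at acceptor
    return "".join(g)


def test_rts_flag_detects_planted_repeat():
    genome = _planted_rts_genome()
    assert rts_flag(genome, (100, 200), "+")


def test_rts_flag_false_on_random_junction():
    rng = np.random.default_rng(10)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    # explicit check that the two 8-mers differ, then the flag must be False
    assert genome[92:100] != genome[192:200]
    assert not rts_flag(genome, (100, 200), "+")


def test_rts_flag_requires_full_repeat_length():
    genome = _planted_rts_genome()
    g = list(genome)
    g[92] = "T" if g[92] != "T" else "G"  # break first repeat base: 7-mer left
    assert not rts_flag("".join(g), (100, 200), "+")


def test_rts_flag_minus_strand():
    # mirror-image planting for a minus-strand transcript
    rng = np.random.default_rng(11)
    g = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]))
    rep = "ACGTACGT"
    # transcript-strand exon-end 8-mer = revcomp(genome[e:e+8])
    g[200:208] = list(revcomp(rep))
    g[100:108] = list(revcomp(rep))
    assert rts_flag("".join(g), (100, 200), "-")


# ---------------------------------------------------------------------------
# artifact filters
# ---------------------------------------------------------------------------

def _mono_tx(tid, gene, start, end, strand="+", contig="c"):
    return TranscriptModel(tid, gene, contig, strand, ((start, end),))


def test_filter_boundary_strict_inequality():
    # 16/20 A = 80.0 exactly -> retained; 17/20 = 85.0 -> removed
    genome = ("G" * 100) + ("A" * 16 + "CCCC") + ("G" * 30) + ("A" * 17 + "CCC") + "G" * 50
    tx80 = _mono_tx("t80", "G1", 50, 100)    # window = 16A + 4C
    tx85 = _mono_tx("t85", "G1", 80, 120)    # window = [120,140) = A*17+CCC? recompute
    genome = "G" * 100 + "A" * 16 + "CCCC" + "A" * 17 + "CCC" + "G" * 60
    tx80 = _mono_tx("t80", "G1", 50, 100)    # downstream [100,120): 16A4C = 80.0
    tx85 = _mono_tx("t85", "G1", 50, 120)    # downstream [120,140): 17A3C = 85.0
    report = apply_artifact_filters([tx80, tx85], genome, "G1")
    assert report.table.loc["t80", "retained"]
    assert not report.table.loc["t85", "retained"]
    assert report.reasons("t85") == [REASON_INTRAPRIMING]


def test_filter_records_all_reasons_not_short_circuited():
    genome = "G" * 100 + "A" * 18 + "CC" + "G" * 80
    tx = _mono_tx("bad", "OTHER_GENE", 50, 100)
    report = apply_artifact_filters([tx], genome, "G1")
    assert set(report.reasons("bad")) == {REASON_INTRAPRIMING, REASON_WRONG_GENE}


def test_filter_uses_precomputed_attributes():
    genome = "G" * 200
    tx = _mono_tx("t", "G1", 50, 100)
    attrs = pd.DataFrame(
        {"perc_A_downstream_TTS": [90.0], "RTS_stage": [True],
         "associated_gene": ["G1"]},
        index=["t"],
    )
    report = apply_artifact_filters([tx], genome, "G1", qc_attributes=attrs)
    assert set(report.reasons("t")) == {REASON_INTRAPRIMING, REASON_RT_SWITCH}


def test_simulated_artifacts_removed_clean_kept():
    """Planted intrapriming/RT-switch transcripts are removed with the right
    reasons; no clean transcript with a real expression share is removed,
    across seeds."""
    for seed in range(5):
        cfg = SimConfig(seed=100 + seed)
        truth = build_locus_pair(cfg)
        parent_tx = [t for t in truth.true_transcripts if t.gene_id == PARENT_GENE]
        report = apply_artifact_filters(parent_tx, truth.genome, PARENT_GENE)
        assert REASON_INTRAPRIMING in report.reasons("PARENT.ART_IP")
        assert REASON_RT_SWITCH in report.reasons("PARENT.ART_RTS")
        clean_ids = [
            t.transcript_id for t in parent_tx
            if truth.artifact_labels[t.transcript_id] == "clean"
        ]
        for tid in clean_ids:
            assert report.table.loc[tid, "retained"], (seed, tid, report.reasons(tid))


# ---------------------------------------------------------------------------
# NFLR normalization
# ---------------------------------------------------------------------------

def test_nflr_single_transcript_is_100_everywhere():
    flr = pd.DataFrame({"S1": [7], "S2": [3]}, index=["t"])
    nflr, nflr_t = nflr_normalize(flr)
    assert (nflr.values == 100.0).all()
    assert nflr_t["t"] == pytest.approx(100.0)


def test_nflr_column_arithmetic():
    flr = pd.DataFrame({"S1": [2, 3, 5]}, index=list("abc"))
    nflr, _ = nflr_normalize(flr)
    assert list(nflr["S1"]) == pytest.approx([20.0, 30.0, 50.0])


def test_nflr_mean_across_samples():
    flr = pd.DataFrame({"S1": [1, 0], "S2": [0, 1]}, index=["a", "b"])
    nflr, nflr_t = nflr_normalize(flr)
    assert nflr_t["a"] == pytest.approx(50.0)
    assert nflr_t["b"] == pytest.approx(50.0)


def test_nflr_zero_column_names_sample():
    flr = pd.DataFrame({"S1": [1, 1], "BAD": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="BAD"):
        nflr_normalize(flr)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=6),
        min_size=2,
        max_size=8,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_nflr_columns_conserve_100(rows):
    flr = pd.DataFrame(rows)
    if (flr.sum(axis=0) == 0).any():
        return
    nflr, _ = nflr_normalize(flr)
    assert np.allclose(nflr.sum(axis=0), 100.0, atol=1e-6)


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def test_retention_sample_fraction_rule():
    # 2/3 samples passing 0.1 < 80% -> removed
    nflr = pd.DataFrame([[0.05, 0.2, 0.5]], index=["t"])
    kept, _ = retain_by_expression(nflr)
    assert kept == []


def test_retention_mean_rule():
    # all samples pass 0.1 but mean 0.1 < 0.3 -> removed
    nflr = pd.DataFrame({f"S{i}": [0.1] for i in range(5)}, index=["t"])
    kept, _ = retain_by_expression(nflr)
    assert kept == []


def test_retention_inclusive_boundaries():
    # exactly 0.3 everywhere: passes both (inclusive >=)
    nflr = pd.DataFrame({f"S{i}": [0.3] for i in range(4)}, index=["t"])
    kept, _ = retain_by_expression(nflr)
    assert kept == ["t"]
    # 3/4 = 0.75 < 0.8 -> removed
    nflr2 = pd.DataFrame(
        {"S0": [0.3], "S1": [0.3], "S2": [0.3], "S3": [0.05]}, index=["t"]
    )
    kept2, _ = retain_by_expression(nflr2)
    assert kept2 == []


def test_retention_exact_rational_sample_fraction():
    # 4/5 samples passing equals 80% exactly -> retained (no float rounding)
    nflr = pd.DataFrame(
        {f"S{i}": [1.0] for i in range(4)} | {"S4": [0.05]}, index=["t"]
    )
    kept, _ = retain_by_expression(nflr)
    assert kept == ["t"]


def test_retention_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    nflr = pd.DataFrame(rng.uniform(0, 1.0, size=(30, 5)))
    nflr.index = [f"t{i}" for i in range(30)]
    base, _ = retain_by_expression(nflr)
    for kw in (
        dict(min_per_sample=0.2),
        dict(min_sample_frac=0.9),
        dict(min_mean=0.5),
    ):
        tighter, _ = retain_by_expression(nflr, **kw)
        assert set(tighter) <= set(base)


def test_per_sample_mean_variant():
    nflr = pd.DataFrame({f"S{i}": [0.2] for i in range(5)}, index=["t"])
    kept_default, _ = retain_by_expression(nflr)
    kept_variant, _ = retain_by_expression(nflr, mean_criterion="per_sample")
    assert kept_default == []  # mean 0.2 < 0.3
    assert kept_variant == []  # 0.2 < 0.3 in every sample too
    nflr2 = pd.DataFrame({f"S{i}": [0.35] for i in range(5)}, index=["t"])
    assert retain_by_expression(nflr2, mean_criterion="per_sample")[0] == ["t"]


# ---------------------------------------------------------------------------
# pipeline order and parameter recovery
# ---------------------------------------------------------------------------

def test_filter_before_normalize_order_is_pinned():
    """Artifact transcripts must be excluded before percentage
    normalization: with a large artifact the clean shares differ between the
    two orders, and run_isoform_qc must produce the filter-first numbers."""
    genome = "G" * 100 + "A" * 18 + "CC" + "G" * 200
    clean_a = _mono_tx("a", "G1", 150, 250)
    clean_b = _mono_tx("b", "G1", 150, 260)
    artifact = _mono_tx("art", "G1", 50, 100)  # A-rich downstream window
    flr = pd.DataFrame({"S1": [60, 20, 20], "S2": [60, 20, 20]},
                       index=["a", "b", "art"])
    nflr, nflr_t, report = run_isoform_qc(
        [clean_a, clean_b, artifact], genome, flr, "G1", min_total_flr=0
    )
    assert "art" in report.removed()
    # filter-first: a = 100*60/80 = 75; normalize-first would keep a at 60
    assert nflr_t["a"] == pytest.approx(75.0)
    assert nflr_t["b"] == pytest.approx(25.0)


def test_recovery_on_artifact_free_simulation(clean_cfg, clean_truth):
    """With >= 5k reads/sample and no artifacts, every transcript with true
    share >= 1% lands inside the Monte-Carlo 99% interval of its NFLR_T."""
    flr = simulate_flr_counts(clean_truth, clean_cfg)
    parent_ids = [t.transcript_id for t in clean_truth.true_transcripts
                  if t.gene_id == PARENT_GENE and
                  clean_truth.true_proportions.get(t.transcript_id, 0) > 0]
    nflr, nflr_t = nflr_normalize(flr.loc[parent_ids])
    shares = {tid: clean_truth.config.true_abundances[PARENT_GENE][tid]
              for tid in parent_ids}
    n_samples = clean_cfg.n_samples
    lib = 10_000
    w_parent = clean_cfg.gene_ratio[PARENT_GENE]
    rng = np.random.default_rng(2024)
    probs = np.array([shares[t] for t in parent_ids])
    # independent Monte-Carlo oracle for the distribution of mean shares
    sims = np.zeros((2000, len(parent_ids)))
    for k in range(2000):
        per_sample = np.zeros((n_samples, len(parent_ids)))
        for i in range(n_samples):
            n_gene = rng.binomial(lib, w_parent)
            c = rng.multinomial(n_gene, probs)
            per_sample[i] = 100.0 * c / c.sum()
        sims[k] = per_sample.mean(axis=0)
    lo = np.percentile(sims, 0.5, axis=0)
    hi = np.percentile(sims, 99.5, axis=0)
    for j, tid in enumerate(parent_ids):
        if shares[tid] >= 0.01:
            assert lo[j] <= nflr_t[tid] <= hi[j], (tid, nflr_t[tid], lo[j], hi[j])
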