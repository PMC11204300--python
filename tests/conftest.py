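"""Shared fixtures: small simulated locus pairs and a toy annotation."""

from __future__ import annotations

import numpy as np
import pytest

from pseudoscope.models import TranscriptModel
from pseudoscope.sim import SimConfig, build_locus_pair


@pytest.fixture(scope="session")
def default_truth():
    """One default-configuration locus pair (96% identity, artifacts planted)."""
    return build_locus_pair(SimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cfg():
    """Artifact-free configuration for recovery tests."""
    return SimConfig(
        seed=7,
        artifact_rates={"intrapriming": 0.0, "rt_switch": 0.0},
    )


@pytest.fixture(scope="session")
def clean_truth(clean_cfg):
    return build_locus_pair(clean_cfg)


@pytest.fixture(scope="session")
def toy_reference():
    """Five-transcript single-gene annotation on a toy plus-strand contig.

    Exon grid (0-based half-open) over a ~3 kb region; transcripts share a
    pool of splice sites so that known-site recombinations are possible.
    """
    e = {
        1: (100, 250),
        2: (400, 520),
        3: (700, 820),
        4: (1000, 1150),
        5: (1400, 1520),
        6: (1700, 1850),
    }
    mk = lambda tid, exons: TranscriptModel(tid, "TOY", "chrT", "+", exons)
    return [
        mk("TOY.R1", (e[1], e[2], e[3], e[4], e[5], e[6])),
        mk("TOY.R2", (e[1], e[3], e[4], e[5], e[6])),      # skips exon 2
        mk("TOY.R3", (e[2], e[3], e[4], e[6])),            # alt start, skips 5
        mk("TOY.R4", (e[1], e[2], (700, 840), e[4], e[5], e[6])),  # alt donor on 3
        mk("TOY.R5", ((90, 250), e[2], e[3], e[4], e[5], (1700, 1900))),  # alt ends
    ]


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(123)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
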