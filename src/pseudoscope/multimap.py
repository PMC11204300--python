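"""Short-read multimapping at a parent/pseudogene locus pair.

Implements the read-selection rules (paired first-mate reads on the locus
strand, fully contained in the locus), the unique-mapping percentage, the
cross-locus multimapper share, the parent/pseudogene log2 ratio convention,
and the statistics used to compare short-read against long-read
quantification (Shapiro-Wilk normality and the Grubbs single-outlier test).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .models import AlignedRead

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")

#: default cap on reported alignments; reads mapping to more places than
#: this are treated as unalignable and dropped (half the usual ENCODE
#: long-RNA cap of 20).
DEFAULT_NH_CAP = 10


def reference_width(cigar: str) -> int:
    """Reference-consumed width of an alignment: the summed lengths of the
    CIGAR operations that consume the reference (M, D, N, =, X)."""
    if not cigar:
        raise ValueError("empty CIGAR")
    pos = 0
    width = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_CONSUMING:
            width += int(m.group(1))
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return width


@dataclass(frozen=True)
class Locus:
    """A genomic region with a strand, e.g. a gene span."""

    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str

    @classmethod
    def parse(cls, text: str) -> "Locus":
        """Parse ``contig:start-end:strand`` (1-based inclusive start)."""
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+):([+-])", text)
        if not m:
            raise ValueError(f"cannot parse locus {text!r}")
        return cls(m.group(1), int(m.group(2)) - 1, int(m.group(3)), m.group(4))


def select_locus_reads(
    reads: Iterable[AlignedRead],
    locus: Locus,
    nh_cap: Optional[int] = DEFAULT_NH_CAP,
) -> List[AlignedRead]:
    """Reads usable for locus-level quantification: paired, first-mate, on
    the locus strand, with the full reference footprint
    ``[start, start + reference_width)`` inside the locus.

    Reads whose NH exceeds ``nh_cap`` are dropped up front (pass None to
    disable the cap).
    """
    out = []
    for r in reads:
        if not (r.is_paired and r.is_first_mate):
            continue
        if r.contig != locus.contig or r.strand != locus.strand:
            continue
        if nh_cap is not None and r.nh > nh_cap:
            continue
        if r.start >= locus.start and r.start + reference_width(r.cigar) <= locus.end:
            out.append(r)
    return out


class EmptyInputError(ValueError):
    """A rate or share was requested on an empty read set."""


def _unique_names(reads: Sequence[AlignedRead]) -> Set[str]:
    return {r.read_name for r in reads}


def unique_mapping_rate(reads: Sequence[AlignedRead]) -> float:
    """Percentage of reads that mapped uniquely: 100 * unique /
    (unique + multimapped), counting distinct read names."""
    names = _unique_names(reads)
    if not names:
        raise EmptyInputError("no reads selected at this locus")
    uniq = {r.read_name for r in reads if r.nh == 1}
    return 100.0 * len(uniq) / len(names)


def multimappers(reads: Sequence[AlignedRead]) -> List[AlignedRead]:
    return [r for r in reads if r.nh > 1]


def cross_locus_share(
    multi_a: Sequence[AlignedRead], multi_b: Sequence[AlignedRead]
) -> float:
    """Of the reads multimapping at locus A, the percentage whose read name
    is also found among the multimappers of locus B."""
    names_a = _unique_names(multi_a)
    if not names_a:
        raise EmptyInputError("no multimapped reads at the query locus")
    names_b = _unique_names(multi_b)
    return 100.0 * len(names_a & names_b) / len(names_a)


def log2_ratio(parent_expr: float, pseudo_expr: float) -> float:
    """log2(parent / pseudogene); the parent gene is always the numerator."""
    if parent_expr <= 0 or pseudo_expr <= 0:
        raise ValueError(
            f"log2_ratio requires positive expression values, got "
            f"({parent_expr}, {pseudo_expr})"
        )
    return math.log2(parent_expr / pseudo_expr)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class OutlierTestResult:
    g_statistic: float
    p_value: float
    candidate_is_outlier: bool
    n: int


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value: G_crit = ((n-1)/sqrt(n)) *
    sqrt(t^2 / (n - 2 + t^2)) with t the upper alpha/(2n) Student-t quantile
    on n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def _grubbs_p_value(g: float, n: int) -> float:
    """Two-sided p for the maximum normalized residual, by inverting the
    critical-value relation: p = 2n * P(T_{n-2} > t(G)).  G values at or
    beyond the distribution's support bound give p = 0."""
    bound = (n - 1) / math.sqrt(n)
    if g <= 0:
        return 1.0
    if g >= bound:
        return 0.0
    u = (g * g * n) / ((n - 1) ** 2)
    t = math.sqrt((n - 2) * u / (1.0 - u))
    return float(min(1.0, 2.0 * n * stats.t.sf(t, n - 2)))


def grubbs_single_outlier(
    background: Sequence[float], candidate: float, alpha: float = 0.05
) -> OutlierTestResult:
    """Grubbs' (maximum normalized residual) test for a single outlier.

    The candidate value is pooled with the background; G = max |x_i - mean| /
    sd (sample sd, n - 1 denominator).  The candidate is called an outlier
    only when the test rejects *and* the maximal residual belongs to the
    candidate itself.
    """
    x = np.asarray(list(background) + [candidate], dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need |background| + 1 >= 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Grubbs test undefined on constant data")
    resid = np.abs(x - x.mean()) / sd
    g = float(resid.max())
    p = _grubbs_p_value(g, n)
    candidate_is_max = int(np.argmax(resid)) == n - 1
    return OutlierTestResult(
        g_statistic=g,
        p_value=p,
        candidate_is_outlier=bool(p < alpha and candidate_is_max),
        n=n,
    )


def shapiro_wilk(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation, via scipy)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)
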