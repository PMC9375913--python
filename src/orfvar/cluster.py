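"""Binomial test for variant clustering in the overlap of two coding regions.

Under the null model every nucleotide of the union of two coding regions is
equally likely to be hit and variants are independent, so the number of
variants falling in the intersection among n variants in the union is
X ~ B(n, p) with p = |intersection| / |union| (lengths in nt).  Enrichment
is assessed with the z-score of the observed count against the binomial
mean and standard deviation; z > 2.58 (one-sided, P < 0.01 under the normal
approximation) is called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .model import ORFModel, Transcript, Variant

Z_THRESHOLD = 2.58

Interval = tuple[int, int]


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if s > e:
            raise ValueError(f"bad interval ({s}, {e})")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _total_length(intervals: list[Interval]) -> int:
    return sum(e - s + 1 for s, e in _merge(intervals))


def _intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out = []
    for s1, e1 in _merge(a):
        for s2, e2 in _merge(b):
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return out


def overlap_probability(seq1: list[Interval], seq2: list[Interval]) -> float:
    """p = |seq1 ∩ seq2| / |seq1 ∪ seq2| over 1-based closed intervals."""
    if not seq1 or not seq2:
        raise ValueError("both interval sets must be nonempty")
    inter = _total_length(_intersect(seq1, seq2))
    union = _total_length(list(seq1) + list(seq2))
    return inter / union


@dataclass(frozen=True)
class OverlapTest:
    """Result of the binomial clustering test.

    n: variants in the union of the two coding regions; k: variants in the
    intersection; p: per-variant probability of the intersection; z-score
    of k against mean n*p and sd sqrt(n*p*(1-p)); p_value is the one-sided
    normal tail.
    """

    n: int
    k: int
    p: float
    mean: float
    sd: float
    z: float
    p_value: float
    threshold: float = Z_THRESHOLD

    @property
    def significant(self) -> bool:
        return self.z > self.threshold

    @property
    def observed_fraction(self) -> float:
        return self.k / self.n


def binomial_cluster_test(n: int, k: int, p: float,
                          threshold: float = Z_THRESHOLD) -> OverlapTest:
    """z-score of k hits among n trials against B(n, p).

    ``p`` may come from :func:`overlap_probability` or be supplied directly
    (e.g. a published overlap fraction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < p < 1:
        raise ValueError("z undefined for p in {0, 1} (sd = 0)")
    mean = n * p
    sd = math.sqrt(n * p * (1 - p))
    z = (k - mean) / sd
    return OverlapTest(n=n, k=k, p=p, mean=mean, sd=sd, z=z,
                       p_value=float(norm.sf(z)), threshold=threshold)


def count_overlap_variants(variants: list[Variant], orf_a: ORFModel,
                           orf_b: ORFModel, tx: Transcript) -> tuple[int, int]:
    """(n, k): variants in the union / intersection of two ORF spans.

    Positions are compared in transcript space, so the two ORFs must be
    hosted by the same transcript.
    """
    if orf_a.transcript_accession != orf_b.transcript_accession:
        raise ValueError("ORFs must share a transcript")
    a = (orf_a.cds_t_start, orf_a.cds_t_end)
    b = (orf_b.cds_t_start, orf_b.cds_t_end)
    n = k = 0
    for v in variants:
        t = tx.genomic_to_transcript(v.pos)
        if not isinstance(t, int):
            continue
        in_a = a[0] <= t <= a[1]
        in_b = b[0] <= t <= b[1]
        if in_a or in_b:
            n += 1
        if in_a and in_b:
            k += 1
    return n, k
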