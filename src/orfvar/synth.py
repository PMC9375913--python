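"""Synthetic annotation bundles: the HEY2 dual-coding fixture and a
random-gene simulator.

The HEY2 fixture re-creates, on a synthetic chromosome-6 window, the
published dual-coding locus: a two-exon plus-strand transcript carrying the
canonical HEY2 CDS (337 aa + stop, ending at 6:125,759,802) and an
alternative ORF in a shifted frame (genomic 6:125,759,396-125,759,827,
432 nt).  Reference bases at positions constrained by the known variant
consequences are pinned (e.g. CGA arginine codons where C>T yields a stop,
CAA at the alternative ORF's codon 106); every other base is drawn from a
seeded RNG and repaired so that neither ORF contains a premature stop.

The simulator builds small random genes with a canonical ORF plus an
alternative ORF in one of several layouts, on either strand, and returns a
truth table of expected (effect, impact) per variant x ORF computed by the
full-retranslation oracle rather than the engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd

from .model import (
    AnnotationBundle,
    GenomeReference,
    GenomicInterval,
    ORFModel,
    Transcript,
    Variant,
    revcomp,
)
from .oracle import classify_by_retranslation

_STOPS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# HEY2 fixture geometry (all 1-based inclusive)
# ---------------------------------------------------------------------------

HEY2_CHROM = "6"
HEY2_GENE = "HEY2"
HEY2_TX = "ENST00000368364"
HEY2_CANONICAL = "Q9UBP5"
HEY2_ALT = "IP_145210"

# exon 1 carries transcript positions 1-499, exon 2 positions 500-1400;
# the exon-2 offset (g = t + 125,758,591) is fixed by the published anchors:
# canonical CDS end t1211 <-> g125,759,802 and the alternative ORF
# t805-1236 <-> g125,759,396-125,759,827.
HEY2_EXON1 = (125_749_580, 125_750_078)
HEY2_EXON2 = (125_759_091, 125_759_991)
HEY2_TX_LEN = 1400
HEY2_CAN_T = (198, 1211)        # 1014 nt = 337 aa + stop
HEY2_ALT_T = (805, 1236)        # 432 nt = 143 aa + stop
HEY2_WINDOW = (125_749_080, 125_760_491)

#: the five published variants: four stop-gain/missense rows plus the
#: 3'UTR-vs-missense example 4 nt past the canonical stop codon
HEY2_VARIANTS = (
    ("6", 125_759_167, "C", "T"),
    ("6", 125_759_503, "C", "T"),
    ("6", 125_759_711, "C", "T"),
    ("6", 125_759_780, "G", "T"),
    ("6", 125_759_806, "T", "G"),
)


def _hey2_t2g(t: int) -> int:
    if t <= 499:
        return t + HEY2_EXON1[0] - 1
    return t + 125_758_591


def _hey2_pins() -> dict[int, str]:
    """Transcript-space pinned bases implied by the published consequences."""
    pins: dict[int, str] = {}

    def pin(t_start: int, bases: str) -> None:
        for i, b in enumerate(bases):
            t = t_start + i
            if pins.get(t, b) != b:
                raise AssertionError(f"conflicting pin at t{t}")
            pins[t] = b

    pin(198, "ATG")      # canonical start
    pin(576, "CGA")      # R127: C>T -> TGA (stop)
    pin(912, "CGA")      # R239: C>T -> TGA (stop)
    pin(1119, "TCA")     # S308: C>T at offset 2 -> TTA (Leu)
    pin(1120, "CAA")     # alt codon 106: C>T -> TAA (stop); fixes t1122=A
    pin(1188, "GGG")     # G331: G>T at offset 2 -> GTG (Val)
    pin(1189, "GGA")     # alt codon 129: G>T -> TGA (stop); fixes t1191=A
    pin(1209, "TGA")     # canonical stop, genomic 125,759,800-125,759,802
    pin(805, "ATG")      # alternative start
    pin(1213, "TTT")     # alt codon 137: T>G at offset 3 -> TTG (Leu)
    pin(1234, "TAA")     # alternative stop
    return pins


def _repair_sequence(rng: random.Random, length: int, pins: dict[int, str],
                     orf_spans: list[tuple[int, int]]) -> list[str]:
    """Random transcript sequence honouring pins, with no premature stop in
    any listed ORF span (spans are transcript coords incl. stop codon)."""
    seq = [pins.get(t) or rng.choice("ACGT") for t in range(1, length + 1)]
    for _ in range(500):
        dirty = False
        for cs, ce in orf_spans:
            n = (ce - cs + 1) // 3
            for i in range(n - 1):          # internal codons only
                t1 = cs + 3 * i
                codon = "".join(seq[t1 - 1:t1 + 2])
                if codon in _STOPS:
                    free = [t for t in (t1, t1 + 1, t1 + 2) if t not in pins]
                    if not free:
                        raise AssertionError(
                            f"stop codon fully pinned at t{t1}")
                    for t in free:
                        seq[t - 1] = rng.choice("ACGT")
                    dirty = True
        if not dirty:
            return seq
    raise AssertionError("could not purge premature stops")


def build_fixture_hey2(seed: int = 2022) -> tuple[AnnotationBundle, list[Variant]]:
    """The dual-coding HEY2 locus on a synthetic chromosome-6 window.

    Returns the annotation bundle plus the five published variants.  Bases
    not constrained by a published consequence are drawn from ``seed``.
    """
    rng = random.Random(seed)
    pins = _hey2_pins()
    tseq = _repair_sequence(rng, HEY2_TX_LEN, pins,
                            [HEY2_CAN_T, HEY2_ALT_T])

    win_lo, win_hi = HEY2_WINDOW
    genome = [rng.choice("ACGT") for _ in range(win_hi - win_lo + 1)]
    for t in range(1, HEY2_TX_LEN + 1):
        genome[_hey2_t2g(t) - win_lo] = tseq[t - 1]
    reference = GenomeReference.from_dict(
        {HEY2_CHROM: "".join(genome)}, offsets={HEY2_CHROM: win_lo})

    tx = Transcript(
        accession=HEY2_TX, gene=HEY2_GENE, chrom=HEY2_CHROM, strand="+",
        exons=(GenomicInterval(HEY2_CHROM, *HEY2_EXON1, "+"),
               GenomicInterval(HEY2_CHROM, *HEY2_EXON2, "+")))
    orfs = [
        ORFModel(HEY2_CANONICAL, HEY2_TX, *HEY2_CAN_T, category="canonical"),
        ORFModel(HEY2_ALT, HEY2_TX, *HEY2_ALT_T, category="alternative"),
    ]
    bundle = AnnotationBundle(reference, [tx], orfs)

    # internal consistency: protein lengths and variant REF bases
    can_prot = bundle.translate_orf(orfs[0])
    alt_prot = bundle.translate_orf(orfs[1])
    if not (len(can_prot) == 338 and can_prot.endswith("*")
            and can_prot.count("*") == 1):
        raise AssertionError("canonical ORF must encode 337 aa + stop")
    if not (len(alt_prot) == 144 and alt_prot.endswith("*")
            and alt_prot.count("*") == 1):
        raise AssertionError("alternative ORF must encode 143 aa + stop")
    variants = []
    for chrom, pos, ref, alt in HEY2_VARIANTS:
        if reference.base(chrom, pos) != ref:
            raise AssertionError(f"fixture REF mismatch at {chrom}:{pos}")
        variants.append(Variant.normalized(chrom, pos, ref, alt))
    return bundle, variants


# ---------------------------------------------------------------------------
# random gene simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Layout of a simulated dual-coding gene.

    orf_layout: where the alternative ORF sits relative to the canonical
        CDS — "nested" (inside, shifted frame), "overlap3" (shifted frame,
        running past the canonical stop), "upstream" (in the 5'UTR) or
        "downstream" (in the 3'UTR).
    """

    n_exons: int = 2
    orf_layout: str = "nested"
    n_variants: int = 8
    strand: str = "+"

    def __post_init__(self):
        if not 1 <= self.n_exons <= 4:
            raise ValueError("n_exons must be in 1..4")
        if self.orf_layout not in ("nested", "overlap3", "upstream",
                                   "downstream"):
            raise ValueError(f"unknown orf_layout {self.orf_layout!r}")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


def _alt_span(rng: random.Random, layout: str, utr5: int, n_codons: int,
              utr3: int) -> tuple[int, int]:
    """Transcript-space (start, end) of the alternative ORF."""
    cds_start = utr5 + 1
    cds_end = utr5 + 3 * n_codons
    L = cds_end + utr3
    if layout == "nested":
        a = rng.randint(6, n_codons - 10)
        k = rng.randint(2, n_codons - a - 4)
        start = cds_start + 3 * k + rng.choice((1, 2))
    elif layout == "overlap3":
        ov = rng.randint(4, 12)
        a = ov + rng.randint(3, max(3, (utr3 - 12) // 3))
        # +2/+3 keeps the alternative ORF out of the canonical frame
        start = cds_end - 3 * ov + rng.choice((2, 3))
    elif layout == "upstream":
        a = rng.randint(4, (utr5 - 6) // 3)
        start = rng.randint(1, utr5 - 3 * a)
    else:  # downstream
        a = rng.randint(4, (utr3 - 6) // 3)
        start = rng.randint(cds_end + 1, L - 3 * a - 1)
    end = start + 3 * a - 1
    if not (1 <= start < end <= L - 1):
        raise ValueError("infeasible alternative-ORF layout")
    return start, end


def simulate_gene(seed: int, params: SimParams = SimParams()
                  ) -> tuple[AnnotationBundle, list[Variant], pd.DataFrame]:
    """Deterministic random gene + variants + oracle truth table.

    The truth table has one row per (variant x ORF) with the effect and
    impact expected from full-CDS retranslation; it is computed by
    :func:`orfvar.oracle.classify_by_retranslation`, not by the engine.
    """
    rng = random.Random(seed)
    utr5 = rng.randint(50, 90)
    n_codons = rng.randint(40, 80)
    utr3 = rng.randint(60, 120)
    cds_start, cds_end = utr5 + 1, utr5 + 3 * n_codons
    L = cds_end + utr3

    for attempt in range(50):
        try:
            alt_start, alt_end = _alt_span(rng, params.orf_layout, utr5,
                                           n_codons, utr3)
            pins: dict[int, str] = {}

            def pin(t0: int, bases: str) -> None:
                for i, b in enumerate(bases):
                    if pins.get(t0 + i, b) != b:
                        raise ValueError("pin conflict")
                    pins[t0 + i] = b

            pin(cds_start, "ATG")
            pin(cds_end - 2, rng.choice(_STOPS))
            pin(alt_start, "ATG")
            pin(alt_end - 2, rng.choice(_STOPS))
            tseq = _repair_sequence(rng, L, pins,
                                    [(cds_start, cds_end),
                                     (alt_start, alt_end)])
            break
        except (ValueError, AssertionError):
            continue
    else:
        raise ValueError("could not realise the requested ORF layout")

    # exon layout: split the transcript at random junctions
    if params.n_exons == 1:
        tlens = [L]
    else:
        cuts = sorted(rng.sample(range(20, L - 20), params.n_exons - 1))
        bounds = [0] + cuts + [L]
        tlens = [b - a for a, b in zip(bounds, bounds[1:])]
    glens = tlens if params.strand == "+" else list(reversed(tlens))
    cur = 1001
    intervals = []
    for ln in glens:
        intervals.append((cur, cur + ln - 1))
        cur += ln + rng.randint(40, 90)
    exon_ivs = intervals if params.strand == "+" else list(reversed(intervals))

    chrom = "sim1"
    win_hi = intervals[-1][1] + 300
    genome = [rng.choice("ACGT") for _ in range(win_hi)]
    tx = Transcript(
        accession="SIMT1", gene="SIMG1", chrom=chrom, strand=params.strand,
        exons=tuple(GenomicInterval(chrom, s, e, params.strand)
                    for s, e in exon_ivs))
    for t in range(1, L + 1):
        g = tx.transcript_to_genomic(t)
        b = tseq[t - 1]
        genome[g - 1] = b if params.strand == "+" else revcomp(b)
    reference = GenomeReference.from_dict({chrom: "".join(genome)})

    orfs = [
        ORFModel("SIMP_CANON", "SIMT1", cds_start, cds_end,
                 category="canonical"),
        ORFModel("SIMP_ALT", "SIMT1", alt_start, alt_end,
                 category="alternative"),
    ]
    bundle = AnnotationBundle(reference, [tx], orfs)
    for orf in orfs:
        prot = bundle.translate_orf(orf)
        assert prot.endswith("*") and prot.count("*") == 1, \
            f"simulated ORF {orf.protein_accession} has a premature stop"

    variants = _draw_variants(rng, params.n_variants, bundle, tx, orfs[0])
    rows = []
    for v in variants:
        for orf in orfs:
            effect, impact = classify_by_retranslation(
                v, tx, orf, reference)
            rows.append({"variant": v.name, "vclass": v.vclass,
                         "protein_accession": orf.protein_accession,
                         "orf_category": orf.category,
                         "effect": effect.value, "impact_code": impact})
    truth = pd.DataFrame(
        rows, columns=["variant", "vclass", "protein_accession",
                       "orf_category", "effect", "impact_code"])
    return bundle, variants, truth


def _draw_variants(rng: random.Random, n: int, bundle: AnnotationBundle,
                   tx: Transcript, canon: ORFModel) -> list[Variant]:
    ref = bundle.reference
    chrom = tx.chrom
    span = tx.span
    win_lo, win_hi = ref.window(chrom)
    lo = max(win_lo + 2, span.start - 150)
    hi = min(win_hi - 2, span.end + 150)
    cs, ce = canon.cds_t_start, canon.cds_t_end

    def same_exon(ts: list[int]) -> bool:
        return len({tx.exon_index_of(t) for t in ts}) == 1

    out: list[Variant] = []
    while len(out) < n:
        kind = rng.choices(("SNV", "MNP", "DEL", "INS"),
                           weights=(0.6, 0.15, 0.15, 0.1))[0]
        if kind == "SNV":
            g = rng.randint(lo, hi)
            rb = ref.base(chrom, g)
            ab = rng.choice([b for b in "ACGT" if b != rb])
            out.append(Variant.normalized(chrom, g, rb, ab))
        elif kind == "MNP":
            e = rng.choice(tx.exons)
            ln = rng.randint(2, 3)
            if e.length < ln + 2:
                continue
            g = rng.randint(e.start, e.end - ln + 1)
            rb = ref.fetch(chrom, g, g + ln - 1)
            ab = "".join(rng.choice("ACGT") for _ in range(ln))
            if ab == rb:
                continue
            try:
                out.append(Variant.normalized(chrom, g, rb, ab))
            except ValueError:
                continue
        elif kind == "DEL":
            dl = rng.randint(1, 4)
            if ce - 3 - dl <= cs + 3:
                continue
            t0 = rng.randint(cs + 3, ce - 3 - dl)
            ts = list(range(t0, t0 + dl))
            if not same_exon(ts):
                continue
            gs = [tx.transcript_to_genomic(t) for t in ts]
            gmin = min(gs)
            anchor = gmin - 1
            if anchor < win_lo:
                continue
            rb = ref.fetch(chrom, anchor, anchor + dl)
            out.append(Variant.normalized(chrom, anchor, rb, rb[0]))
        else:  # INS
            t0 = rng.randint(cs + 3, ce - 6)
            if not same_exon([t0, t0 + 1]):
                continue
            anchor = min(tx.transcript_to_genomic(t0),
                         tx.transcript_to_genomic(t0 + 1))
            rb = ref.base(chrom, anchor)
            ins = "".join(rng.choice("ACGT")
                          for _ in range(rng.randint(1, 3)))
            out.append(Variant.normalized(chrom, anchor, rb, rb + ins))
    return out
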