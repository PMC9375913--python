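"""Brute-force consequence oracle used to validate the engine.

Instead of codon arithmetic, this module applies a variant to the spliced
transcript sequence, re-translates the entire coding span and derives the
effect from a whole-protein diff.  It shares the published classification
conventions (splice windows, severity order, anchor choices) with the
engine but none of its coordinate machinery, so agreement between the two
is a meaningful check.

Intentionally slow and simple; used by the synthetic-gene truth tables and
the property tests.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .effects import IMPACT_OF, AnnotationConfig, EffectTerm, severity_rank
from .model import GenomeReference, ORFModel, Transcript, Variant, revcomp


def _tx_sequence(tx: Transcript, reference: GenomeReference) -> str:
    parts = []
    for e in tx.exons:
        s = reference.fetch(tx.chrom, e.start, e.end)
        parts.append(s if tx.strand == "+" else revcomp(s))
    return "".join(parts)


def _tmap(tx: Transcript, pos: int):
    """Own genomic->transcript mapping: int, or a tagged tuple."""
    span_lo = min(e.start for e in tx.exons)
    span_hi = max(e.end for e in tx.exons)
    if pos < span_lo:
        d = span_lo - pos
        return ("up", d) if tx.strand == "+" else ("down", d)
    if pos > span_hi:
        d = pos - span_hi
        return ("down", d) if tx.strand == "+" else ("up", d)
    acc = 0
    for e in tx.exons:
        if e.start <= pos <= e.end:
            within = pos - e.start + 1 if tx.strand == "+" else e.end - pos + 1
            return acc + within
        acc += e.length
    # intron: locate flanking exons in transcript order
    for i in range(len(tx.exons) - 1):
        a, b = tx.exons[i], tx.exons[i + 1]
        if tx.strand == "+":
            if a.end < pos < b.start:
                return ("intron", pos - a.end, b.start - pos)
        else:
            if b.end < pos < a.start:
                return ("intron", a.start - pos, pos - b.end)
    raise AssertionError("position classified nowhere")


def _translate_to_stop(s: str) -> str:
    prot = []
    for i in range(0, len(s) - 2, 3):
        aa = str(Seq(s[i:i + 3]).translate())
        prot.append(aa)
        if aa == "*":
            break
    return "".join(prot)


def _region_term(tx: Transcript, orf: ORFModel, pos: int,
                 cfg: AnnotationConfig) -> EffectTerm:
    tag = _tmap(tx, pos)
    if isinstance(tag, tuple):
        kind = tag[0]
        if kind == "up":
            return EffectTerm.upstream_gene_variant
        if kind == "down":
            return EffectTerm.downstream_gene_variant
        _, dd, da = tag
        if dd <= cfg.splice_site_window:
            return EffectTerm.splice_donor_variant
        if da <= cfg.splice_site_window:
            return EffectTerm.splice_acceptor_variant
        lo, hi = cfg.splice_region_intron
        if lo <= min(dd, da) <= hi:
            return EffectTerm.splice_region_variant
        return EffectTerm.intron_variant
    if tag < orf.cds_t_start:
        return EffectTerm.five_prime_UTR_variant
    if tag > orf.cds_t_end:
        return EffectTerm.three_prime_UTR_variant
    raise AssertionError("coding position passed to region fallback")


def classify_by_retranslation(v: Variant, tx: Transcript, orf: ORFModel,
                              reference: GenomeReference,
                              cfg: AnnotationConfig = AnnotationConfig()
                              ) -> tuple[EffectTerm, int]:
    """Expected (effect, impact code) for one variant against one ORF."""
    seq = _tx_sequence(tx, reference)
    n = orf.n_codons
    cs, ce = orf.cds_t_start, orf.cds_t_end

    if v.vclass in ("SNV", "MNP"):
        subs: dict[int, str] = {}
        in_cds: list[int] = []
        for g in v.changed_positions():
            t = _tmap(tx, g)
            if isinstance(t, int):
                off = g - v.pos
                base = v.alt[off]
                subs[t] = base if tx.strand == "+" else revcomp(base)
                if cs <= t <= ce:
                    in_cds.append(t)
        if not in_cds:
            term = _region_term(tx, orf, v.changed_positions()[0], cfg)
            return term, int(IMPACT_OF[term])
        mut = list(seq)
        for t, b in subs.items():
            mut[t - 1] = b
        mut_seq = "".join(mut)
        ref_prot = _translate_to_stop(seq[cs - 1:])
        mut_prot = _translate_to_stop(mut_seq[cs - 1:])
        candidates: list[EffectTerm] = []
        first_changed = any(cs <= t <= cs + 2 for t in in_cds)
        if first_changed and mut_seq[cs - 1:cs + 2] != "ATG":
            candidates.append(EffectTerm.start_lost)
        i_ref = n - 1                      # 0-based stop position
        i_mut = len(mut_prot) - 1 if mut_prot.endswith("*") else None
        if i_mut is not None and i_mut < i_ref:
            candidates.append(EffectTerm.stop_gained)
        elif i_mut is None or i_mut > i_ref:
            candidates.append(EffectTerm.stop_lost)
        elif mut_prot == ref_prot:
            stop_span = range(ce - 2, ce + 1)
            candidates.append(
                EffectTerm.stop_retained_variant
                if all(t in stop_span for t in in_cds)
                else EffectTerm.synonymous_variant)
        else:
            candidates.append(EffectTerm.missense_variant)
        term = min(candidates, key=severity_rank)
        return term, int(IMPACT_OF[term])

    # --- indels ---------------------------------------------------------
    if v.vclass == "DEL":
        gdel = v.changed_positions()
        tdel = [_tmap(tx, g) for g in gdel]
        if not all(isinstance(t, int) for t in tdel):
            term = _region_term(tx, orf, gdel[0], cfg)
            return term, int(IMPACT_OF[term])
        tdel_set = set(tdel)
        if not any(cs <= t <= ce for t in tdel_set):
            tag = _tmap(tx, gdel[0])
            term = (EffectTerm.five_prime_UTR_variant if tag < cs
                    else EffectTerm.three_prime_UTR_variant)
            return term, int(IMPACT_OF[term])
        delta = -len(tdel_set)
        if any(cs <= t <= cs + 2 for t in tdel_set):
            term = EffectTerm.start_lost
            return term, int(IMPACT_OF[term])
        if delta % 3 != 0:
            term = EffectTerm.frameshift_variant
            return term, int(IMPACT_OF[term])
        if any(ce - 2 <= t <= ce for t in tdel_set):
            term = EffectTerm.stop_lost
            return term, int(IMPACT_OF[term])
        mut = [b for i, b in enumerate(seq, start=1) if i not in tdel_set]
        mut_prot = _translate_to_stop("".join(mut)[cs - 1:])
        expected = n - 1 + delta // 3
        i_mut = len(mut_prot) - 1 if mut_prot.endswith("*") else None
        if i_mut is not None and i_mut < expected:
            term = EffectTerm.stop_gained
        elif i_mut is None or i_mut > expected:
            term = EffectTerm.stop_lost
        else:
            term = EffectTerm.inframe_deletion
        return term, int(IMPACT_OF[term])

    # insertion
    left = _tmap(tx, v.pos)
    right = _tmap(tx, v.pos + 1)
    if not (isinstance(left, int) and isinstance(right, int)
            and abs(left - right) == 1):
        term = (EffectTerm.splice_region_variant if isinstance(left, int)
                else _region_term(tx, orf, v.pos, cfg))
        return term, int(IMPACT_OF[term])
    t_after = left if tx.strand == "+" else right
    inserted = v.alt[len(v.ref):]
    if tx.strand == "-":
        inserted = revcomp(inserted)
    if not (cs <= t_after < ce):
        term = (EffectTerm.five_prime_UTR_variant if t_after < cs
                else EffectTerm.three_prime_UTR_variant)
        return term, int(IMPACT_OF[term])
    delta = len(inserted)
    mut_seq = seq[:t_after] + inserted + seq[t_after:]
    if delta % 3 != 0:
        term = EffectTerm.frameshift_variant
        return term, int(IMPACT_OF[term])
    mut_prot = _translate_to_stop(mut_seq[cs - 1:])
    if mut_seq[cs - 1:cs + 2] != "ATG":
        term = EffectTerm.start_lost
        return term, int(IMPACT_OF[term])
    expected = n - 1 + delta // 3
    i_mut = len(mut_prot) - 1 if mut_prot.endswith("*") else None
    if i_mut is not None and i_mut < expected:
        term = EffectTerm.stop_gained
    elif i_mut is None or i_mut > expected:
        term = EffectTerm.stop_lost
    else:
        term = EffectTerm.inframe_insertion
    return term, int(IMPACT_OF[term])
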