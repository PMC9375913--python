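"""Per-ORF consequence classification of genomic variants.

Every variant is classified independently against every ORF of every
transcript it lands on or near.  A position that is 3'UTR for the canonical
ORF can therefore be a missense codon of an alternative ORF hosted by the
same transcript, in a different reading frame; the two calls do not
constrain each other.

Effect terms follow Sequence Ontology naming and the conventional 4-level
impact scheme (modifier=0 < low=1 < moderate=2 < high=3).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .model import (
    AnnotationBundle,
    DownstreamTag,
    IntronTag,
    ORFModel,
    Transcript,
    UpstreamTag,
    Variant,
    codon_transcript_range,
    revcomp,
    transcript_to_codon,
)


class EffectTerm(str, enum.Enum):
    stop_gained = "stop_gained"
    stop_lost = "stop_lost"
    start_lost = "start_lost"
    frameshift_variant = "frameshift_variant"
    splice_acceptor_variant = "splice_acceptor_variant"
    splice_donor_variant = "splice_donor_variant"
    missense_variant = "missense_variant"
    inframe_insertion = "inframe_insertion"
    inframe_deletion = "inframe_deletion"
    splice_region_variant = "splice_region_variant"
    synonymous_variant = "synonymous_variant"
    stop_retained_variant = "stop_retained_variant"
    five_prime_UTR_variant = "five_prime_UTR_variant"
    three_prime_UTR_variant = "three_prime_UTR_variant"
    upstream_gene_variant = "upstream_gene_variant"
    downstream_gene_variant = "downstream_gene_variant"
    intron_variant = "intron_variant"
    intergenic_variant = "intergenic_variant"


#: most-severe-first order, used for tie-breaking and MNP aggregation
SEVERITY_ORDER: tuple[EffectTerm, ...] = tuple(EffectTerm)
_SEVERITY_RANK = {t: i for i, t in enumerate(SEVERITY_ORDER)}


def severity_rank(term: EffectTerm) -> int:
    """Lower rank = more severe."""
    return _SEVERITY_RANK[term]


class Impact(enum.IntEnum):
    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


IMPACT_OF: dict[EffectTerm, Impact] = {
    EffectTerm.stop_gained: Impact.HIGH,
    EffectTerm.stop_lost: Impact.HIGH,
    EffectTerm.start_lost: Impact.HIGH,
    EffectTerm.frameshift_variant: Impact.HIGH,
    EffectTerm.splice_acceptor_variant: Impact.HIGH,
    EffectTerm.splice_donor_variant: Impact.HIGH,
    EffectTerm.missense_variant: Impact.MODERATE,
    EffectTerm.inframe_insertion: Impact.MODERATE,
    EffectTerm.inframe_deletion: Impact.MODERATE,
    EffectTerm.splice_region_variant: Impact.LOW,
    EffectTerm.synonymous_variant: Impact.LOW,
    EffectTerm.stop_retained_variant: Impact.LOW,
    EffectTerm.five_prime_UTR_variant: Impact.MODIFIER,
    EffectTerm.three_prime_UTR_variant: Impact.MODIFIER,
    EffectTerm.upstream_gene_variant: Impact.MODIFIER,
    EffectTerm.downstream_gene_variant: Impact.MODIFIER,
    EffectTerm.intron_variant: Impact.MODIFIER,
    EffectTerm.intergenic_variant: Impact.MODIFIER,
}

FEATURE_ID_SEP = "@"


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable geometry of the annotator.

    flank: up/downstream window (bp) within which a variant is still
        attributed to a transcript.
    splice_site_window: intronic bases at each intron end called
        donor/acceptor (high impact).
    splice_region_intron: intronic distance range (inclusive) called
        splice_region (low impact).
    splice_region_exon: exonic bases adjacent to a junction that pick up a
        secondary splice_region term.
    """

    flank: int = 5000
    splice_site_window: int = 2
    splice_region_intron: tuple[int, int] = (3, 8)
    splice_region_exon: int = 3


@dataclass
class EffectRecord:
    """One (variant x transcript x ORF) consequence call."""

    variant: Variant
    gene: str
    transcript_accession: str
    protein_accession: str
    effect: EffectTerm
    impact: Impact
    secondary: tuple[EffectTerm, ...] = ()
    cdna_change: str = ""
    protein_change: str = ""
    protein_change_short: str = ""
    orf_category: str = ""
    codon_index: int | None = None
    warnings: tuple[str, ...] = ()

    @property
    def feature_id(self) -> str:
        if not self.transcript_accession and not self.protein_accession:
            return ""
        return (f"{self.transcript_accession}{FEATURE_ID_SEP}"
                f"{self.protein_accession}")

    @property
    def effect_string(self) -> str:
        terms = [self.effect.value] + [t.value for t in self.secondary]
        return "&".join(terms)


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _aa3(a: str) -> str:
    return "Ter" if a == "*" else seq3(a)


def _protein_notation(aa_ref: str, idx: int, aa_alt: str,
                      term: EffectTerm) -> tuple[str, str]:
    """(HGVS 3-letter, 1-letter shorthand) for a substitution-type change."""
    if term == EffectTerm.start_lost:
        return "p.Met1?", "M1?"
    if term in (EffectTerm.synonymous_variant, EffectTerm.stop_retained_variant):
        return f"p.{_aa3(aa_ref)}{idx}=", f"{aa_ref}{idx}="
    return (f"p.{_aa3(aa_ref)}{idx}{_aa3(aa_alt)}",
            f"{aa_ref}{idx}{aa_alt}")


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionCall:
    """Non-coding classification of one position relative to one ORF."""

    effect: EffectTerm
    secondary: tuple[EffectTerm, ...] = ()
    is_cds: bool = False
    tpos: int | None = None


def classify_region(pos: int, tx: Transcript, orf: ORFModel,
                    cfg: AnnotationConfig = AnnotationConfig()) -> RegionCall:
    """Classify a single genomic position relative to one ORF.

    Exonic positions 5' of the ORF are 5'UTR *for that ORF* even when they
    sit inside another ORF's coding region.  Splice terms come from the
    transcript's junction geometry and are reported for every ORF of the
    transcript.
    """
    tag = tx.genomic_to_transcript(pos)
    if isinstance(tag, UpstreamTag):
        return RegionCall(EffectTerm.upstream_gene_variant)
    if isinstance(tag, DownstreamTag):
        return RegionCall(EffectTerm.downstream_gene_variant)
    if isinstance(tag, IntronTag):
        w = cfg.splice_site_window
        lo, hi = cfg.splice_region_intron
        if tag.dist_donor <= w:
            return RegionCall(EffectTerm.splice_donor_variant,
                              (EffectTerm.intron_variant,))
        if tag.dist_acceptor <= w:
            return RegionCall(EffectTerm.splice_acceptor_variant,
                              (EffectTerm.intron_variant,))
        if lo <= min(tag.dist_donor, tag.dist_acceptor) <= hi:
            return RegionCall(EffectTerm.splice_region_variant,
                              (EffectTerm.intron_variant,))
        return RegionCall(EffectTerm.intron_variant)
    # exonic
    tpos = tag
    secondary: tuple[EffectTerm, ...] = ()
    jd = tx.exonic_junction_distance(tpos)
    if jd is not None and jd <= cfg.splice_region_exon:
        secondary = (EffectTerm.splice_region_variant,)
    if tpos < orf.cds_t_start:
        return RegionCall(EffectTerm.five_prime_UTR_variant, secondary, tpos=tpos)
    if tpos > orf.cds_t_end:
        return RegionCall(EffectTerm.three_prime_UTR_variant, secondary, tpos=tpos)
    return RegionCall(EffectTerm.synonymous_variant, secondary,
                      is_cds=True, tpos=tpos)


# ---------------------------------------------------------------------------
# coding classifiers
# ---------------------------------------------------------------------------

def _strand_base(base: str, strand: str) -> str:
    return base if strand == "+" else revcomp(base)


def classify_snv(v: Variant, tx: Transcript, orf: ORFModel,
                 bundle: AnnotationBundle,
                 tpos: int) -> tuple[EffectTerm, str, str, str, int, list[str]]:
    """Classify an SNV landing inside the ORF's coding span.

    Returns (term, hgvs_c, hgvs_p, shorthand, codon_index, warnings).
    """
    warnings: list[str] = []
    cds_pos, codon_idx, offset = transcript_to_codon(tpos, orf)
    ref_codon = bundle.codon_sequence(orf, codon_idx)
    ref_base = _strand_base(v.ref, tx.strand)
    alt_base = _strand_base(v.alt, tx.strand)
    if ref_codon[offset - 1] != ref_base:
        warnings.append(
            f"{v.name}: VCF REF {v.ref} disagrees with reference codon "
            f"{ref_codon} at {orf.protein_accession} codon {codon_idx} "
            f"offset {offset}; using genome sequence")
    mut_codon = ref_codon[:offset - 1] + alt_base + ref_codon[offset:]
    aa_ref, aa_alt = _aa(ref_codon), _aa(mut_codon)
    if codon_idx == 1 and mut_codon != "ATG":
        term = EffectTerm.start_lost
    elif aa_ref != "*" and aa_alt == "*":
        term = EffectTerm.stop_gained
    elif aa_ref == "*" and aa_alt != "*":
        term = EffectTerm.stop_lost
    elif aa_ref == "*" and aa_alt == "*":
        term = EffectTerm.stop_retained_variant
    elif aa_ref == aa_alt:
        term = EffectTerm.synonymous_variant
    else:
        term = EffectTerm.missense_variant
    hgvs_c = f"c.{cds_pos}{ref_base}>{alt_base}"
    hgvs_p, short = _protein_notation(aa_ref, codon_idx, aa_alt, term)
    return term, hgvs_c, hgvs_p, short, codon_idx, warnings


def classify_mnp(v: Variant, tx: Transcript, orf: ORFModel,
                 bundle: AnnotationBundle,
                 changed_tpos: list[tuple[int, str, str]],
                 ) -> tuple[EffectTerm, str, str, str, int, list[str]]:
    """Classify an MNP from its in-CDS changed bases.

    ``changed_tpos`` holds (tpos, genomic ref base, genomic alt base) for
    every changed position inside the ORF.  All affected codons are
    re-translated and the most severe per-codon term is reported.
    """
    warnings: list[str] = []
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    cds_span: list[int] = []
    for tpos, rb, ab in changed_tpos:
        cds_pos, codon_idx, offset = transcript_to_codon(tpos, orf)
        by_codon.setdefault(codon_idx, []).append(
            (offset, _strand_base(rb, tx.strand), _strand_base(ab, tx.strand)))
        cds_span.append(cds_pos)
    calls: list[tuple[int, EffectTerm, int, str, str]] = []
    for codon_idx in sorted(by_codon):
        ref_codon = bundle.codon_sequence(orf, codon_idx)
        mut = list(ref_codon)
        for offset, rb, ab in by_codon[codon_idx]:
            if ref_codon[offset - 1] != rb:
                warnings.append(
                    f"{v.name}: REF disagrees with reference codon at "
                    f"{orf.protein_accession} codon {codon_idx}")
            mut[offset - 1] = ab
        mut_codon = "".join(mut)
        aa_ref, aa_alt = _aa(ref_codon), _aa(mut_codon)
        if codon_idx == 1 and mut_codon != "ATG":
            term = EffectTerm.start_lost
        elif aa_ref != "*" and aa_alt == "*":
            term = EffectTerm.stop_gained
        elif aa_ref == "*" and aa_alt != "*":
            term = EffectTerm.stop_lost
        elif aa_ref == "*" and aa_alt == "*":
            term = EffectTerm.stop_retained_variant
        elif aa_ref == aa_alt:
            term = EffectTerm.synonymous_variant
        else:
            term = EffectTerm.missense_variant
        calls.append((severity_rank(term), term, codon_idx, aa_ref, aa_alt))
    calls.sort()
    _, term, codon_idx, aa_ref, aa_alt = calls[0]
    hgvs_p, short = _protein_notation(aa_ref, codon_idx, aa_alt, term)
    lo, hi = min(cds_span), max(cds_span)
    ref_cs = _strand_base(v.ref, tx.strand)
    alt_cs = _strand_base(v.alt, tx.strand)
    hgvs_c = (f"c.{lo}_{hi}delins{alt_cs}" if lo != hi
              else f"c.{lo}{ref_cs}>{alt_cs}")
    return term, hgvs_c, hgvs_p, short, codon_idx, warnings


def _transcript_edit(v: Variant, tx: Transcript) -> tuple[int, str, str] | None:
    """Indel as a coding-strand transcript edit.

    Returns (t_after, deleted_seq, inserted_seq) where the change happens
    immediately after transcript position ``t_after`` (deleted bases are
    t_after+1..t_after+len(deleted)).  None when the changed span is not a
    contiguous run inside a single exon.
    """
    if v.vclass == "DEL":
        gpos = v.changed_positions()
        tmap = [tx.genomic_to_transcript(g) for g in gpos]
        if not all(isinstance(t, int) for t in tmap):
            return None
        ts = sorted(tmap)
        if ts != list(range(ts[0], ts[0] + len(ts))):
            return None
        deleted = v.ref[len(v.alt):]
        if tx.strand == "-":
            deleted = revcomp(deleted)
        return ts[0] - 1, deleted, ""
    # insertion between v.pos and v.pos+1
    left = tx.genomic_to_transcript(v.pos)
    right = tx.genomic_to_transcript(v.pos + 1)
    if not (isinstance(left, int) and isinstance(right, int)):
        return None
    if abs(left - right) != 1:
        return None
    inserted = v.alt[len(v.ref):]
    t_after = left if tx.strand == "+" else right
    if tx.strand == "-":
        inserted = revcomp(inserted)
    return t_after, "", inserted


def classify_indel(v: Variant, tx: Transcript, orf: ORFModel,
                   bundle: AnnotationBundle,
                   cfg: AnnotationConfig,
                   ) -> tuple[EffectTerm, str, str, str, int | None, list[str]]:
    """Classify an insertion or deletion that touches the ORF's coding span.

    Frame-preserving indels are re-translated so that an in-frame change
    creating an early stop is reported as stop_gained rather than a bare
    inframe term.
    """
    warnings: list[str] = []
    edit = _transcript_edit(v, tx)
    if edit is None:
        # spans an exon boundary: report the most severe per-base call
        calls = [classify_region(g, tx, orf, cfg)
                 for g in (v.changed_positions() or [v.pos])]
        calls.sort(key=lambda c: severity_rank(c.effect))
        best = calls[0]
        term = best.effect
        if best.is_cds:
            delta = len(v.alt) - len(v.ref)
            term = (EffectTerm.frameshift_variant if delta % 3
                    else (EffectTerm.inframe_insertion if delta > 0
                          else EffectTerm.inframe_deletion))
        warnings.append(f"{v.name}: indel spans an exon boundary on "
                        f"{tx.accession}; classified as {term.value}")
        return term, "", "", "", None, warnings

    t_after, deleted, inserted = edit
    delta = len(inserted) - len(deleted)
    del_span = range(t_after + 1, t_after + 1 + len(deleted))
    first_cds_t = (min(t for t in del_span if orf.contains_tpos(t))
                   if deleted else t_after + 1)
    cds_pos, codon_idx, _ = transcript_to_codon(
        min(max(first_cds_t, orf.cds_t_start), orf.cds_t_end), orf)

    start_t1, _, start_t3 = codon_transcript_range(orf, 1)
    stop_t1, _, stop_t3 = codon_transcript_range(orf, orf.n_codons)
    if deleted and any(start_t1 <= t <= start_t3 for t in del_span):
        term = EffectTerm.start_lost
        hgvs_p, short = "p.Met1?", "M1?"
    elif delta % 3 != 0:
        term = EffectTerm.frameshift_variant
        tx_seq = tx.spliced_sequence(bundle.reference)
        aa_ref = _aa(tx_seq[orf.cds_t_start + 3 * (codon_idx - 1) - 1:
                            orf.cds_t_start + 3 * codon_idx - 1])
        hgvs_p, short = f"p.{_aa3(aa_ref)}{codon_idx}fs", f"{aa_ref}{codon_idx}fs"
    elif deleted and any(stop_t1 <= t <= stop_t3 for t in del_span):
        term = EffectTerm.stop_lost
        hgvs_p, short = f"p.Ter{orf.n_codons}del", f"*{orf.n_codons}del"
    else:
        tx_seq = tx.spliced_sequence(bundle.reference)
        mut_seq = (tx_seq[:t_after] + inserted
                   + tx_seq[t_after + len(deleted):])
        mut_cds = mut_seq[orf.cds_t_start - 1: orf.cds_t_end + delta]
        mut_prot = str(Seq(mut_cds).translate())
        if not mut_cds.startswith("ATG"):
            term = EffectTerm.start_lost
            hgvs_p, short = "p.Met1?", "M1?"
        elif "*" in mut_prot[:-1]:
            term = EffectTerm.stop_gained
            i = mut_prot.index("*") + 1
            hgvs_p, short = f"p.{i}Ter", f"{i}*"
        elif not mut_prot.endswith("*"):
            term = EffectTerm.stop_lost
            hgvs_p, short = f"p.Ter{orf.n_codons}?", f"*{orf.n_codons}?"
        else:
            term = (EffectTerm.inframe_insertion if delta > 0
                    else EffectTerm.inframe_deletion)
            n = abs(delta) // 3
            kind = "ins" if delta > 0 else "del"
            hgvs_p = f"p.{codon_idx}{kind}{n}aa"
            short = f"{codon_idx}{kind}{n}aa"
    if deleted:
        hgvs_c = (f"c.{cds_pos}del" if len(deleted) == 1
                  else f"c.{cds_pos}_{cds_pos + len(deleted) - 1}del")
    else:
        hgvs_c = f"c.{cds_pos - 1}_{cds_pos}ins{inserted}"
    return term, hgvs_c, hgvs_p, short, codon_idx, warnings


# ---------------------------------------------------------------------------
# per-variant annotation
# ---------------------------------------------------------------------------

def _indel_touches_cds(v: Variant, tx: Transcript, orf: ORFModel) -> bool:
    if v.vclass == "DEL":
        for g in v.changed_positions():
            t = tx.genomic_to_transcript(g)
            if isinstance(t, int) and orf.contains_tpos(t):
                return True
        return False
    edit = _transcript_edit(v, tx)
    if edit is None:
        return False
    t_after, _, _ = edit
    return orf.cds_t_start <= t_after < orf.cds_t_end


def _annotate_against_orf(v: Variant, tx: Transcript, orf: ORFModel,
                          bundle: AnnotationBundle,
                          cfg: AnnotationConfig) -> EffectRecord:
    base = dict(variant=v, gene=tx.gene, transcript_accession=tx.accession,
                protein_accession=orf.protein_accession,
                orf_category=orf.category)

    changed = v.changed_positions()
    anchor = changed[0] if (changed and v.vclass != "INS") else v.pos
    region = classify_region(anchor, tx, orf, cfg)

    if v.vclass == "SNV":
        if region.is_cds:
            term, c, p, short, idx, warn = classify_snv(v, tx, orf, bundle,
                                                        region.tpos)
            return EffectRecord(effect=term, impact=IMPACT_OF[term],
                                secondary=region.secondary, cdna_change=c,
                                protein_change=p, protein_change_short=short,
                                codon_index=idx, warnings=tuple(warn), **base)
        return _region_record(v, tx, orf, region, base)

    if v.vclass == "MNP":
        changed = []
        for i, g in enumerate(v.changed_positions()):
            t = tx.genomic_to_transcript(g)
            if isinstance(t, int) and orf.contains_tpos(t):
                off = g - v.pos
                changed.append((t, v.ref[off], v.alt[off]))
        if changed:
            term, c, p, short, idx, warn = classify_mnp(v, tx, orf, bundle,
                                                        changed)
            return EffectRecord(effect=term, impact=IMPACT_OF[term],
                                secondary=region.secondary, cdna_change=c,
                                protein_change=p, protein_change_short=short,
                                codon_index=idx, warnings=tuple(warn), **base)
        return _region_record(v, tx, orf, region, base)

    # indel
    if v.vclass == "INS":
        edit = _transcript_edit(v, tx)
        if edit is not None:
            t_after, _, _ = edit
            if orf.cds_t_start <= t_after < orf.cds_t_end:
                term, c, p, short, idx, warn = classify_indel(
                    v, tx, orf, bundle, cfg)
                return EffectRecord(effect=term, impact=IMPACT_OF[term],
                                    secondary=region.secondary, cdna_change=c,
                                    protein_change=p,
                                    protein_change_short=short,
                                    codon_index=idx, warnings=tuple(warn),
                                    **base)
            term = (EffectTerm.five_prime_UTR_variant
                    if t_after < orf.cds_t_start
                    else EffectTerm.three_prime_UTR_variant)
            return EffectRecord(effect=term, impact=IMPACT_OF[term],
                                secondary=region.secondary, **base)
        if region.tpos is not None:
            # insertion at an exon/intron boundary: splicing is at risk
            return EffectRecord(
                effect=EffectTerm.splice_region_variant,
                impact=IMPACT_OF[EffectTerm.splice_region_variant],
                warnings=(f"{v.name}: insertion at an exon boundary of "
                          f"{tx.accession}",),
                **base)
        return _region_record(v, tx, orf, region, base)

    if _indel_touches_cds(v, tx, orf):
        term, c, p, short, idx, warn = classify_indel(v, tx, orf, bundle, cfg)
        return EffectRecord(effect=term, impact=IMPACT_OF[term],
                            secondary=region.secondary, cdna_change=c,
                            protein_change=p, protein_change_short=short,
                            codon_index=idx, warnings=tuple(warn), **base)
    return _region_record(v, tx, orf, region, base)


def _region_record(v: Variant, tx: Transcript, orf: ORFModel,
                   region: RegionCall, base: dict) -> EffectRecord:
    term = region.effect
    if region.is_cds and term == EffectTerm.synonymous_variant:
        # reached only by an insertion anchored on the last CDS base whose
        # inserted bases fall after the stop codon
        term = EffectTerm.three_prime_UTR_variant
    hgvs_c = ""
    if region.tpos is not None and v.vclass == "SNV":
        rb = _strand_base(v.ref, tx.strand)
        ab = _strand_base(v.alt, tx.strand)
        if region.tpos < orf.cds_t_start:
            hgvs_c = f"c.-{orf.cds_t_start - region.tpos}{rb}>{ab}"
        elif region.tpos > orf.cds_t_end:
            hgvs_c = f"c.*{region.tpos - orf.cds_t_end}{rb}>{ab}"
    return EffectRecord(effect=term, impact=IMPACT_OF[term],
                        secondary=region.secondary, cdna_change=hgvs_c,
                        **base)


def annotate_variant(v: Variant, bundle: AnnotationBundle,
                     cfg: AnnotationConfig = AnnotationConfig()
                     ) -> list[EffectRecord]:
    """All (transcript x ORF) consequence records for one variant.

    Transcripts are looked up within ``cfg.flank`` of the variant; a
    variant hitting no transcript yields a single intergenic record, so
    every variant produces at least one record.  Canonical-ORF records come
    before alternative ones, then severity, then accession.
    """
    records: list[EffectRecord] = []
    for tx in bundle.transcripts_near(v.chrom, v.pos, cfg.flank):
        for orf in sorted(bundle.orfs_by_transcript[tx.accession],
                          key=lambda o: (o.category != "canonical",
                                         o.protein_accession)):
            if not orf.frame_ok:
                continue
            records.append(_annotate_against_orf(v, tx, orf, bundle, cfg))
    if not records:
        return [EffectRecord(variant=v, gene="", transcript_accession="",
                             protein_accession="",
                             effect=EffectTerm.intergenic_variant,
                             impact=Impact.MODIFIER)]
    records.sort(key=lambda r: (r.orf_category != "canonical",
                                severity_rank(r.effect),
                                r.transcript_accession,
                                r.protein_accession))
    return records


def annotate_variants(variants: list[Variant], bundle: AnnotationBundle,
                      cfg: AnnotationConfig = AnnotationConfig()
                      ) -> tuple[list[EffectRecord], list[str]]:
    """Annotate a batch; returns (records, accumulated warnings)."""
    records: list[EffectRecord] = []
    warnings: list[str] = []
    for v in variants:
        recs = annotate_variant(v, bundle, cfg)
        records.extend(recs)
        for r in recs:
            warnings.extend(r.warnings)
    return records, warnings
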