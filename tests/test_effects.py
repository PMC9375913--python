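"""Consequence engine: per-ORF effect calls, splice geometry, coding
classifiers and cross-ORF independence."""

import pytest

from orfvar import (
    AnnotationConfig,
    GenomeReference,
    GenomicInterval,
    ORFModel,
    Transcript,
    Variant,
    AnnotationBundle,
    annotate_variant,
    annotate_variants,
    classify_region,
)
from orfvar.effects import IMPACT_OF, EffectTerm, Impact
from orfvar.model import revcomp
from orfvar.synth import SimParams, simulate_gene

# single-exon toy gene: 10 nt 5'UTR + 10 codons + 20 nt 3'UTR at g101-160
_CODONS = "ATG AAA CCC GGG TTT TCA CGA TAT GAA TAA".replace(" ", "")
_TOY_SEQ = ("G" * 100) + ("G" * 10) + _CODONS + ("C" * 20) + ("G" * 100)


def _toy_bundle(strand="+"):
    if strand == "+":
        seq, exon = _TOY_SEQ, (101, 160)
    else:
        seq = revcomp(_TOY_SEQ)          # mirror: 101+160 == len+1 == 261
        exon = (101, 160)
    ref = GenomeReference.from_dict({"t": seq})
    tx = Transcript(accession="TX", gene="TOY", chrom="t", strand=strand,
                    exons=(GenomicInterval("t", *exon, strand),))
    orf = ORFModel("PROT", "TX", 11, 40, category="canonical")
    return AnnotationBundle(ref, [tx], [orf])


def _one(v, bundle, **cfg):
    recs = annotate_variant(v, bundle, AnnotationConfig(**cfg)
                            if cfg else AnnotationConfig())
    assert len(recs) == 1
    return recs[0]


class TestSnvClassification:
    @pytest.mark.parametrize("pos,ref,alt,term,pshort", [
        (125, "T", "C", EffectTerm.synonymous_variant, "F5="),
        (129, "C", "T", EffectTerm.stop_gained, "R7*"),
        (138, "T", "C", EffectTerm.stop_lost, "*10Q"),
        (140, "A", "G", EffectTerm.stop_retained_variant, "*10="),
        (111, "A", "C", EffectTerm.start_lost, "M1?"),
        (121, "G", "T", EffectTerm.missense_variant, "G4V"),
    ])
    def test_codon_level_calls(self, pos, ref, alt, term, pshort):
        rec = _one(Variant.normalized("t", pos, ref, alt), _toy_bundle())
        assert rec.effect == term
        assert rec.protein_change_short == pshort

    def test_ref_mismatch_flagged_not_fatal(self):
        rec = _one(Variant.normalized("t", 125, "A", "C"), _toy_bundle())
        assert rec.warnings and "disagrees" in rec.warnings[0]

    def test_strand_mirror_gives_identical_protein_call(self):
        plus = _one(Variant.normalized("t", 129, "C", "T"), _toy_bundle("+"))
        minus = _one(Variant.normalized("t", 261 - 129, "G", "A"),
                     _toy_bundle("-"))
        assert (plus.effect, plus.protein_change) == \
            (minus.effect, minus.protein_change)


class TestMnpClassification:
    def test_most_severe_codon_wins(self):
        # F5 synonymous (TTT>TTC) + T6 missense (TCA>ACA) -> missense
        rec = _one(Variant.normalized("t", 125, "TT", "CA"), _toy_bundle())
        assert rec.effect == EffectTerm.missense_variant

    def test_two_base_change_within_codon_to_stop(self):
        # Y8 TAT -> TGA via a 2-nt substitution
        rec = _one(Variant.normalized("t", 133, "AT", "GA"), _toy_bundle())
        assert rec.effect == EffectTerm.stop_gained
        assert rec.protein_change_short == "Y8*"

    def test_all_synonymous_codons(self):
        # TTT>TTC and CGA>CGG are both silent
        rec = _one(Variant.normalized("t", 125, "TTCACGA", "CTCACGG"),
                   _toy_bundle())
        assert rec.effect == EffectTerm.synonymous_variant


class TestIndelClassification:
    def test_one_bp_insertion_is_frameshift(self):
        rec = _one(Variant.normalized("t", 120, "G", "GA"), _toy_bundle())
        assert rec.effect == EffectTerm.frameshift_variant
        assert rec.impact == Impact.HIGH

    def test_inframe_deletion_without_new_stop(self):
        rec = _one(Variant.normalized("t", 119, "CGGG", "C"), _toy_bundle())
        assert rec.effect == EffectTerm.inframe_deletion

    def test_inframe_deletion_creating_stop(self):
        # removing cds 23-25 fuses T.. + ..AA into a TAA codon
        rec = _one(Variant.normalized("t", 132, "TATG", "T"), _toy_bundle())
        assert rec.effect == EffectTerm.stop_gained

    def test_inframe_insertion(self):
        rec = _one(Variant.normalized("t", 121, "G", "GAAA"), _toy_bundle())
        assert rec.effect == EffectTerm.inframe_insertion

    def test_deletion_of_start_codon(self):
        rec = _one(Variant.normalized("t", 110, "GATG", "G"), _toy_bundle())
        assert rec.effect == EffectTerm.start_lost

    def test_deletion_of_stop_codon(self):
        rec = _one(Variant.normalized("t", 137, "ATAA", "A"), _toy_bundle())
        assert rec.effect == EffectTerm.stop_lost


class TestSpliceGeometry:
    def _bundle(self):
        ref = GenomeReference.from_dict({"c": "A" * 400})
        tx = Transcript(accession="TX", gene="G", chrom="c", strand="+",
                        exons=(GenomicInterval("c", 51, 150, "+"),
                               GenomicInterval("c", 201, 300, "+")))
        orf = ORFModel("P", "TX", 21, 80)
        return tx, orf

    @pytest.mark.parametrize("pos,term", [
        (151, EffectTerm.splice_donor_variant),
        (152, EffectTerm.splice_donor_variant),
        (153, EffectTerm.splice_region_variant),
        (158, EffectTerm.splice_region_variant),
        (170, EffectTerm.intron_variant),
        (199, EffectTerm.splice_acceptor_variant),
        (200, EffectTerm.splice_acceptor_variant),
        (195, EffectTerm.splice_region_variant),
    ])
    def test_intronic_windows(self, pos, term):
        tx, orf = self._bundle()
        assert classify_region(pos, tx, orf).effect == term

    def test_exonic_positions_near_junction_gain_secondary_term(self):
        tx, orf = self._bundle()
        call = classify_region(150, tx, orf)   # last exon-1 base, t=100
        assert call.effect == EffectTerm.three_prime_UTR_variant
        assert EffectTerm.splice_region_variant in call.secondary
        far = classify_region(120, tx, orf)
        assert EffectTerm.splice_region_variant not in far.secondary

    def test_flanking_regions(self, hey2):
        bundle, _ = hey2
        tx = bundle.transcripts["ENST00000368364"]
        orf = bundle.orfs["Q9UBP5"]
        assert classify_region(125_749_500, tx, orf).effect == \
            EffectTerm.upstream_gene_variant
        assert classify_region(125_760_100, tx, orf).effect == \
            EffectTerm.downstream_gene_variant


class TestPerOrfIndependence:
    def test_utr_for_one_orf_coding_for_another(self, hey2_records):
        by = {(r.variant.pos, r.protein_accession): r for r in hey2_records}
        # 4 nt past the canonical stop codon: modifier on the canonical
        # ORF, missense codon 137 of the alternative ORF
        canon = by[(125_759_806, "Q9UBP5")]
        alt = by[(125_759_806, "IP_145210")]
        assert canon.effect == EffectTerm.three_prime_UTR_variant
        assert canon.impact == Impact.MODIFIER
        assert alt.effect == EffectTerm.missense_variant
        assert alt.protein_change == "p.Phe137Leu"
        assert alt.impact == Impact.MODERATE

    def test_synonymous_in_one_frame_not_in_other(self, hey2_records):
        by = {(r.variant.pos, r.protein_accession): r for r in hey2_records}
        # dual-coding position: missense for the canonical frame, stop for
        # the +1-frame alternative ORF
        assert by[(125_759_711, "Q9UBP5")].effect == \
            EffectTerm.missense_variant
        assert by[(125_759_711, "IP_145210")].effect == \
            EffectTerm.stop_gained


class TestBatchInvariants:
    def test_every_variant_yields_a_record_and_mapped_impact(self):
        bundle, variants, _ = simulate_gene(5, SimParams(n_variants=12))
        records, _ = annotate_variants(variants, bundle)
        seen = {r.variant for r in records}
        assert seen == set(variants)
        for r in records:
            assert r.impact == IMPACT_OF[r.effect]

    def test_intergenic_when_no_transcript_within_flank(self, hey2):
        bundle, _ = hey2
        v = Variant.normalized("6", 125_749_100,
                               bundle.reference.base("6", 125_749_100) ,
                               "A" if bundle.reference.base("6", 125_749_100) != "A" else "C")
        recs = annotate_variant(v, bundle, AnnotationConfig(flank=100))
        assert len(recs) == 1
        assert recs[0].effect == EffectTerm.intergenic_variant

    def test_canonical_records_precede_alternative(self, hey2_records):
        by_variant = {}
        for r in hey2_records:
            by_variant.setdefault(r.variant, []).append(r)
        for recs in by_variant.values():
            cats = [r.orf_category for r in recs]
            assert cats == sorted(cats, key=lambda c: c != "canonical")
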