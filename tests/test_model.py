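"""Coordinate arithmetic, variant normalization and bundle invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfvar.model import (
    DownstreamTag,
    GenomeReference,
    GenomicInterval,
    IntronTag,
    ORFModel,
    Transcript,
    UpstreamTag,
    Variant,
    transcript_to_codon,
)


def _tx(strand="+", exons=((1, 100), (201, 300)), chrom="c"):
    return Transcript(accession="T1", gene="G1", chrom=chrom, strand=strand,
                      exons=tuple(GenomicInterval(chrom, s, e, strand)
                                  for s, e in exons))


class TestGenomicToTranscript:
    def test_first_base_of_second_exon(self):
        assert _tx().genomic_to_transcript(201) == 101

    def test_transcript_length_sums_exons(self):
        assert _tx().length == 200

    def test_intronic_position_distances(self):
        tag = _tx().genomic_to_transcript(150)
        assert tag == IntronTag(index=1, dist_donor=50, dist_acceptor=51)

    def test_minus_strand_five_prime_is_highest_coordinate(self):
        tx = _tx(strand="-", exons=((10, 19),))
        assert tx.genomic_to_transcript(19) == 1
        assert tx.genomic_to_transcript(10) == 10

    def test_minus_strand_intron_orientation(self):
        tx = _tx(strand="-")
        # transcript order: exon (201,300) first, so the intron's donor
        # side is at genomic 200 and acceptor side at genomic 101
        tag = tx.genomic_to_transcript(199)
        assert isinstance(tag, IntronTag)
        assert tag.dist_donor == 2
        assert tag.dist_acceptor == 99

    def test_flanking_tags(self):
        tx = _tx()
        assert tx.genomic_to_transcript(0) == UpstreamTag(1)
        assert tx.genomic_to_transcript(310) == DownstreamTag(10)
        tx_m = _tx(strand="-")
        assert tx_m.genomic_to_transcript(310) == UpstreamTag(10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(strand=st.sampled_from("+-"), tpos=st.integers(1, 200))
    def test_round_trip_identity(self, strand, tpos):
        tx = _tx(strand=strand)
        assert tx.genomic_to_transcript(tx.transcript_to_genomic(tpos)) == tpos

    def test_every_position_classified_exactly_once(self):
        tx = _tx()
        for pos in range(-50, 360):
            tag = tx.genomic_to_transcript(pos)
            exonic = any(e.contains(pos) for e in tx.exons)
            assert isinstance(tag, int) == exonic


class TestJunctionDistance:
    def test_exon_edges(self):
        tx = _tx()
        assert tx.exonic_junction_distance(100) == 1   # last base of exon 1
        assert tx.exonic_junction_distance(101) == 1   # first base of exon 2
        assert tx.exonic_junction_distance(97) == 4

    def test_single_exon_has_no_junction(self):
        assert _tx(exons=((1, 100),)).exonic_junction_distance(50) is None


class TestCodonArithmetic:
    def test_codon_index_and_offset(self):
        orf = ORFModel("P", "T1", 10, 21)
        assert transcript_to_codon(10, orf) == (1, 1, 1)
        assert transcript_to_codon(14, orf) == (5, 2, 2)
        assert transcript_to_codon(21, orf) == (12, 4, 3)

    def test_outside_orf_raises(self):
        with pytest.raises(ValueError):
            transcript_to_codon(9, ORFModel("P", "T1", 10, 21))

    def test_length_must_be_positive_and_ordered(self):
        with pytest.raises(ValueError):
            ORFModel("P", "T1", 21, 10)

    def test_non_divisible_span_flagged_not_rejected(self):
        orf = ORFModel("P", "T1", 10, 20)  # 11 nt
        assert not orf.frame_ok


class TestVariantNormalization:
    def test_shared_prefix_and_suffix_trimmed(self):
        v = Variant.normalized("1", 100, "CAG", "CTG")
        assert (v.pos, v.ref, v.alt, v.vclass) == (101, "A", "T", "SNV")

    def test_null_change_rejected(self):
        with pytest.raises(ValueError):
            Variant.normalized("1", 100, "AT", "AT")

    def test_classes_derived_from_allele_lengths(self):
        assert Variant.normalized("1", 5, "A", "T").vclass == "SNV"
        assert Variant.normalized("1", 5, "AT", "GC").vclass == "MNP"
        assert Variant.normalized("1", 5, "A", "ATT").vclass == "INS"
        assert Variant.normalized("1", 5, "ATT", "A").vclass == "DEL"

    def test_deletion_changed_positions_exclude_anchor(self):
        v = Variant.normalized("1", 10, "CATG", "C")
        assert v.changed_positions() == [11, 12, 13]


class TestGenomeReference:
    def test_windowed_contig_uses_true_coordinates(self):
        ref = GenomeReference.from_dict({"6": "ACGT"}, offsets={"6": 1000})
        assert ref.fetch("6", 1000, 1003) == "ACGT"
        assert ref.base("6", 1002) == "G"
        with pytest.raises(ValueError):
            ref.fetch("6", 999, 1000)


class TestHey2FixtureSelfChecks:
    def test_protein_lengths(self, hey2):
        bundle, _ = hey2
        can = bundle.translate_orf(bundle.orfs["Q9UBP5"])
        alt = bundle.translate_orf(bundle.orfs["IP_145210"])
        assert len(can) == 338 and can.endswith("*") and can.count("*") == 1
        assert len(alt) == 144 and alt.endswith("*") and alt.count("*") == 1

    def test_alternative_orf_length_432nt(self, hey2):
        bundle, _ = hey2
        assert bundle.orfs["IP_145210"].cds_length == 432

    def test_canonical_stop_occupies_printed_coordinates(self, hey2):
        bundle, _ = hey2
        tx = bundle.transcripts["ENST00000368364"]
        orf = bundle.orfs["Q9UBP5"]
        stop_g = [tx.transcript_to_genomic(t)
                  for t in range(orf.cds_t_end - 2, orf.cds_t_end + 1)]
        assert stop_g == [125_759_800, 125_759_801, 125_759_802]

    def test_codon_spanning_exon_junction_is_spliced(self, hey2):
        bundle, _ = hey2
        orf = bundle.orfs["Q9UBP5"]
        # codon 101 covers transcript 498-500, crossing the junction at 499/500
        codon = bundle.codon_sequence(orf, 101)
        tx = bundle.transcripts["ENST00000368364"]
        expected = "".join(bundle.reference.base("6",
                                                 tx.transcript_to_genomic(t))
                           for t in (498, 499, 500))
        assert codon == expected
        assert tx.exon_index_of(499) == 0 and tx.exon_index_of(500) == 1
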