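"""Genomic data model: reference sequences, transcripts, ORFs, variants.

All coordinates are 1-based inclusive, matching the convention of VCF and
GTF.  Transcript coordinates count 5'->3' on the coding strand, starting at
1 for the first transcribed base.  ORF coordinates are transcript-space and
*include* the stop codon, so a CDS of N codons spans 3*N transcript bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from Bio.Seq import Seq
from intervaltree import IntervalTree

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# intervals and region tags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Closed genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class IntronTag:
    """Position inside intron ``index`` (1-based, transcript order).

    ``dist_donor`` is the 1-based distance from the donor (5') end of the
    intron; ``dist_acceptor`` from the acceptor (3') end.  The first intronic
    base after an exon has dist_donor == 1.
    """

    index: int
    dist_donor: int
    dist_acceptor: int


@dataclass(frozen=True)
class UpstreamTag:
    """Position ``dist`` bases 5' of the transcript start (dist >= 1)."""

    dist: int


@dataclass(frozen=True)
class DownstreamTag:
    """Position ``dist`` bases 3' of the transcript end (dist >= 1)."""

    dist: int


RegionTag = Union[IntronTag, UpstreamTag, DownstreamTag]


# ---------------------------------------------------------------------------
# reference sequence access
# ---------------------------------------------------------------------------

class GenomeReference:
    """Nucleotide accessor for one or more contigs.

    Each contig stores a sequence together with the genomic coordinate of
    its first base (``offset``), so a short window of a real chromosome can
    be addressed with its true coordinates.  Plain contigs have offset 1.
    """

    def __init__(self) -> None:
        self._contigs: dict[str, tuple[int, str]] = {}

    @classmethod
    def from_dict(cls, seqs: dict[str, str],
                  offsets: dict[str, int] | None = None) -> "GenomeReference":
        ref = cls()
        for name, seq in seqs.items():
            off = (offsets or {}).get(name, 1)
            ref.add_contig(name, seq, offset=off)
        return ref

    def add_contig(self, name: str, seq: str, offset: int = 1) -> None:
        if offset < 1:
            raise ValueError("offset must be >= 1")
        self._contigs[name] = (offset, seq.upper())

    def contigs(self) -> list[str]:
        return list(self._contigs)

    def window(self, chrom: str) -> tuple[int, int]:
        """Genomic (start, end) of the stored sequence for ``chrom``."""
        off, seq = self._contigs[chrom]
        return off, off + len(seq) - 1

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the closed interval [start, end] on the + strand."""
        if chrom not in self._contigs:
            raise KeyError(f"no sequence for chromosome {chrom!r}")
        off, seq = self._contigs[chrom]
        lo, hi = start - off, end - off + 1
        if lo < 0 or hi > len(seq) or start > end:
            raise ValueError(
                f"{chrom}:{start}-{end} outside stored window "
                f"{off}-{off + len(seq) - 1}")
        return seq[lo:hi]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """A spliced transcript: ordered exons on one strand.

    Exons are stored 5'->3' in transcript order (ascending genomic
    coordinates on '+', descending on '-').
    """

    accession: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        exons = tuple(self.exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        key = (lambda e: e.start) if self.strand == "+" else (lambda e: -e.start)
        exons = tuple(sorted(exons, key=key))
        for a, b in zip(exons, exons[1:]):
            ga, gb = (a, b) if self.strand == "+" else (b, a)
            if gb.start <= ga.end:
                raise ValueError(
                    f"{self.accession}: exons overlap or touch "
                    f"({ga.start}-{ga.end} vs {gb.start}-{gb.end})")
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    # -- coordinate arithmetic ------------------------------------------

    def genomic_to_transcript(self, pos: int) -> Union[int, RegionTag]:
        """Map a genomic position to a transcript coordinate or region tag.

        Exonic positions return the 1-based transcript coordinate.  All
        other positions return an :class:`IntronTag`, :class:`UpstreamTag`
        or :class:`DownstreamTag` with 1-based distances.
        """
        span = self.span
        if pos < span.start:
            d = span.start - pos
            return UpstreamTag(d) if self.strand == "+" else DownstreamTag(d)
        if pos > span.end:
            d = pos - span.end
            return DownstreamTag(d) if self.strand == "+" else UpstreamTag(d)
        acc = 0
        for i, e in enumerate(self.exons):
            if e.contains(pos):
                within = pos - e.start + 1 if self.strand == "+" else e.end - pos + 1
                return acc + within
            acc += e.length
        return self._intron_tag(pos)

    def _intron_tag(self, pos: int) -> IntronTag:
        for i in range(len(self.exons) - 1):
            donor_exon, acceptor_exon = self.exons[i], self.exons[i + 1]
            if self.strand == "+":
                lo, hi = donor_exon.end + 1, acceptor_exon.start - 1
                if lo <= pos <= hi:
                    return IntronTag(i + 1, pos - donor_exon.end,
                                     acceptor_exon.start - pos)
            else:
                lo, hi = acceptor_exon.end + 1, donor_exon.start - 1
                if lo <= pos <= hi:
                    return IntronTag(i + 1, donor_exon.start - pos,
                                     pos - acceptor_exon.end)
        raise ValueError(f"position {pos} is not intronic in {self.accession}")

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for exonic positions."""
        if tpos < 1 or tpos > self.length:
            raise ValueError(f"transcript position {tpos} outside 1..{self.length}")
        acc = 0
        for e in self.exons:
            if tpos <= acc + e.length:
                within = tpos - acc
                return e.start + within - 1 if self.strand == "+" else e.end - within + 1
            acc += e.length
        raise AssertionError("unreachable")

    def exon_index_of(self, tpos: int) -> int:
        """0-based exon index containing transcript position ``tpos``."""
        acc = 0
        for i, e in enumerate(self.exons):
            if tpos <= acc + e.length:
                return i
            acc += e.length
        raise ValueError(f"transcript position {tpos} outside transcript")

    def exonic_junction_distance(self, tpos: int) -> int | None:
        """Distance (in nt, >=1) from exonic ``tpos`` to the nearest internal
        exon/intron junction, or None for a single-exon transcript.

        The last base of an exon adjacent to an intron has distance 1.
        """
        if len(self.exons) == 1:
            return None
        acc = 0
        best = None
        for i, e in enumerate(self.exons):
            lo, hi = acc + 1, acc + e.length
            if lo <= tpos <= hi:
                cands = []
                if i > 0:
                    cands.append(tpos - lo + 1)      # from acceptor side
                if i < len(self.exons) - 1:
                    cands.append(hi - tpos + 1)      # from donor side
                best = min(cands)
                break
            acc += e.length
        return best

    def spliced_sequence(self, reference: GenomeReference) -> str:
        """Full transcript sequence, 5'->3' on the coding strand."""
        parts = []
        for e in self.exons:
            s = reference.fetch(self.chrom, e.start, e.end)
            parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

@dataclass
class ORFModel:
    """A coding span on a transcript, stop codon included.

    ``category`` distinguishes the reference-annotation CDS ("canonical")
    from non-canonical predictions ("alternative").  ``frame_ok`` is False
    when the span length is not a multiple of 3; such ORFs are kept for
    bookkeeping but excluded from coding-consequence calls.
    """

    protein_accession: str
    transcript_accession: str
    cds_t_start: int
    cds_t_end: int
    category: str = "canonical"
    frame_ok: bool = True

    def __post_init__(self):
        if not (1 <= self.cds_t_start < self.cds_t_end):
            raise ValueError("require 1 <= cds_t_start < cds_t_end")
        if self.category not in ("canonical", "alternative"):
            raise ValueError(f"bad ORF category {self.category!r}")
        if (self.cds_t_end - self.cds_t_start + 1) % 3 != 0:
            self.frame_ok = False

    @property
    def cds_length(self) -> int:
        return self.cds_t_end - self.cds_t_start + 1

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def contains_tpos(self, tpos: int) -> bool:
        return self.cds_t_start <= tpos <= self.cds_t_end


def transcript_to_codon(tpos: int, orf: ORFModel) -> tuple[int, int, int]:
    """Locate a transcript position inside an ORF.

    Returns ``(cds_pos, codon_index, offset_in_codon)``, all 1-based:
    cds_pos counts from the first base of the start codon, codon_index is
    ceil(cds_pos/3) and offset_in_codon is 1..3.
    """
    if not orf.contains_tpos(tpos):
        raise ValueError(
            f"transcript position {tpos} outside ORF "
            f"{orf.protein_accession} ({orf.cds_t_start}-{orf.cds_t_end})")
    cds_pos = tpos - orf.cds_t_start + 1
    codon_index = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3 + 1
    return cds_pos, codon_index, offset


def codon_transcript_range(orf: ORFModel, codon_index: int) -> tuple[int, int, int]:
    """Transcript positions (t1, t2, t3) of the three bases of a codon."""
    if not (1 <= codon_index <= orf.n_codons):
        raise ValueError(f"codon index {codon_index} outside 1..{orf.n_codons}")
    t1 = orf.cds_t_start + (codon_index - 1) * 3
    return t1, t1 + 1, t1 + 2


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VCLASS = {"SNV", "MNP", "INS", "DEL"}


@dataclass(frozen=True)
class Variant:
    """A normalized genomic change.

    ``pos``/``ref``/``alt`` follow VCF conventions after minimal
    normalization: shared suffix then shared prefix are trimmed (keeping at
    least one base on each side), with ``pos`` advanced over the trimmed
    prefix.  For INS/DEL the first base is the conventional VCF anchor and
    is not itself changed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    source_key: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use anchored VCF style")
        if self.ref == self.alt:
            raise ValueError("ref == alt after normalization (null change)")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str,
                   source_key: tuple | None = None) -> "Variant":
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError("ref == alt (null change)")
        # trim shared suffix, keeping >= 1 base
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # trim shared prefix, keeping >= 1 base
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return cls(chrom, pos, ref, alt, source_key=source_key)

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def name(self) -> str:
        """"chrom_pos_ref_alt" identifier (the max-impact table key)."""
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    def changed_positions(self) -> list[int]:
        """Genomic positions whose reference base is altered.

        For SNV/MNP these are the substituted positions (only those where
        ref and alt actually differ); for DEL the deleted bases after the
        anchor; for INS the two anchor-adjacent positions are unchanged, so
        an empty list is returned and the insertion point is ``pos``.
        """
        if self.vclass in ("SNV", "MNP"):
            return [self.pos + i for i, (r, a)
                    in enumerate(zip(self.ref, self.alt)) if r != a]
        if self.vclass == "DEL":
            return list(range(self.pos + len(self.alt), self.pos + len(self.ref)))
        return []


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

class AnnotationBundle:
    """Reference + transcripts + ORFs, indexed for positional queries."""

    def __init__(self, reference: GenomeReference,
                 transcripts: Iterable[Transcript],
                 orfs: Iterable[ORFModel]) -> None:
        self.reference = reference
        self.transcripts: dict[str, Transcript] = {
            t.accession: t for t in transcripts}
        self.orfs: dict[str, ORFModel] = {}
        self.orfs_by_transcript: dict[str, list[ORFModel]] = {
            acc: [] for acc in self.transcripts}
        for orf in orfs:
            if orf.transcript_accession not in self.transcripts:
                raise KeyError(
                    f"ORF {orf.protein_accession} references unknown "
                    f"transcript {orf.transcript_accession}")
            tx = self.transcripts[orf.transcript_accession]
            if orf.cds_t_end > tx.length:
                raise ValueError(
                    f"ORF {orf.protein_accession} extends past the end of "
                    f"transcript {tx.accession} ({orf.cds_t_end} > {tx.length})")
            self.orfs[orf.protein_accession] = orf
            self.orfs_by_transcript[orf.transcript_accession].append(orf)
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts.values():
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            sp = tx.span
            tree.addi(sp.start, sp.end + 1, tx.accession)  # half-open

    def transcripts_near(self, chrom: str, pos: int,
                         flank: int = 5000) -> list[Transcript]:
        """Transcripts whose span +- flank contains ``pos``, sorted by accession."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - flank, pos + flank + 1)
        return [self.transcripts[h.data] for h in sorted(hits, key=lambda h: h.data)]

    def codon_sequence(self, orf: ORFModel, codon_index: int) -> str:
        """3-nt codon on the coding strand, spliced across junctions."""
        tx = self.transcripts[orf.transcript_accession]
        bases = []
        for t in codon_transcript_range(orf, codon_index):
            g = tx.transcript_to_genomic(t)
            b = self.reference.base(tx.chrom, g)
            bases.append(b if tx.strand == "+" else revcomp(b))
        return "".join(bases)

    def cds_sequence(self, orf: ORFModel) -> str:
        tx = self.transcripts[orf.transcript_accession]
        full = tx.spliced_sequence(self.reference)
        return full[orf.cds_t_start - 1: orf.cds_t_end]

    def translate_orf(self, orf: ORFModel) -> str:
        """Protein of the ORF including a trailing '*' for the stop."""
        return str(Seq(self.cds_sequence(orf)).translate())
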