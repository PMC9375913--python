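"""Readers and writers for the standard input formats.

Inputs: VCF v4.x (variants), GTF exon features (transcript models), a TSV
ORF table (canonical + alternative coding spans, transcript- or
genomic-space) and a FASTA reference.  FASTA headers may carry a
samtools-faidx style region suffix (``>6:125749080-125760491``), in which
case the record is treated as a window of the named chromosome with true
genomic coordinates.
"""

from __future__ import annotations

import warnings as _pywarnings
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    AnnotationBundle,
    GenomeReference,
    GenomicInterval,
    ORFModel,
    Transcript,
    Variant,
)

ORF_TABLE_COLUMNS = ["protein_accession", "transcript_accession",
                     "coord_space", "start", "end", "category"]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[list[Variant], list[str]]:
    """Parse a VCF into normalized variants.

    Multi-allelic records are split into one variant per ALT; shared
    prefix/suffix bases are trimmed (position adjusted).  Symbolic or
    breakend alleles and null changes are skipped with a warning.
    Returns (variants, warnings).
    """
    variants: list[Variant] = []
    warns: list[str] = []
    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore")  # pysam grumbles about headers
        vcf = pysam.VariantFile(str(path))
        for rec in vcf:
            for i, alt in enumerate(rec.alts or ()):
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if alt is None or any(c in alt for c in "<>[].*"):
                    warns.append(f"{rec.chrom}:{rec.pos} symbolic allele "
                                 f"{alt!r} skipped")
                    continue
                try:
                    variants.append(Variant.normalized(
                        rec.chrom, rec.pos, rec.ref, alt, source_key=key))
                except ValueError as exc:
                    warns.append(f"{rec.chrom}:{rec.pos} {rec.ref}>{alt} "
                                 f"skipped: {exc}")
    return variants, warns


def read_transcripts(path: str | Path) -> tuple[dict[str, Transcript], list[str]]:
    """Transcript models from GTF exon features (transcript_id, gene_name)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    grouped: dict[str, dict] = {}
    warns: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = (feat.attributes.get("transcript_id") or [None])[0]
        if tid is None:
            warns.append(f"exon at {feat.seqid}:{feat.start}-{feat.end} "
                         "lacks transcript_id; skipped")
            continue
        gene = (feat.attributes.get("gene_name") or [tid])[0]
        entry = grouped.setdefault(
            tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                  "exons": []})
        entry["exons"].append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand))
    transcripts = {
        tid: Transcript(accession=tid, gene=e["gene"], chrom=e["chrom"],
                        strand=e["strand"], exons=tuple(e["exons"]))
        for tid, e in grouped.items()}
    return transcripts, warns


def read_orfs(path: str | Path, transcripts: dict[str, Transcript]
              ) -> tuple[dict[str, ORFModel], list[str]]:
    """ORF table -> transcript-space ORF models.

    Genomic-space rows are converted through the transcript's exon map.
    Spans not divisible by 3 are kept but flagged (excluded from coding
    calls); rows naming unknown transcripts are skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ORF_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ORF table missing columns: {sorted(missing)}")
    orfs: dict[str, ORFModel] = {}
    warns: list[str] = []
    for row in df.itertuples(index=False):
        tx = transcripts.get(row.transcript_accession)
        if tx is None:
            warns.append(f"ORF {row.protein_accession}: unknown transcript "
                         f"{row.transcript_accession}; skipped")
            continue
        start, end = int(row.start), int(row.end)
        if row.coord_space == "genomic":
            ts = tx.genomic_to_transcript(start)
            te = tx.genomic_to_transcript(end)
            if not (isinstance(ts, int) and isinstance(te, int)):
                warns.append(f"ORF {row.protein_accession}: genomic bounds "
                             "not exonic; skipped")
                continue
            start, end = min(ts, te), max(ts, te)
        elif row.coord_space != "transcript":
            warns.append(f"ORF {row.protein_accession}: bad coord_space "
                         f"{row.coord_space!r}; skipped")
            continue
        orf = ORFModel(row.protein_accession, row.transcript_accession,
                       start, end, category=row.category)
        if not orf.frame_ok:
            warns.append(f"ORF {row.protein_accession}: span {orf.cds_length}"
                         " nt not divisible by 3; kept but excluded from"
                         " coding-consequence calls")
        orfs[row.protein_accession] = orf
    return orfs, warns


def read_fasta(path: str | Path) -> GenomeReference:
    """FASTA -> reference; ``name:start-end`` headers become offset windows."""
    ref = GenomeReference()
    for rec in SeqIO.parse(str(path), "fasta"):
        name, offset = rec.id, 1
        if ":" in rec.id:
            base, _, region = rec.id.rpartition(":")
            try:
                lo, _, hi = region.partition("-")
                offset, end = int(lo.replace(",", "")), int(hi.replace(",", ""))
            except ValueError:
                offset, end = 1, None
            else:
                if end - offset + 1 != len(rec.seq):
                    raise ValueError(
                        f"{rec.id}: region length {end - offset + 1} != "
                        f"sequence length {len(rec.seq)}")
                name = base
        ref.add_contig(name, str(rec.seq), offset=offset)
    return ref


def load_bundle(fasta: str | Path, gtf: str | Path, orf_table: str | Path
                ) -> tuple[AnnotationBundle, list[str]]:
    """Assemble an annotation bundle from the three annotation files."""
    reference = read_fasta(fasta)
    transcripts, w1 = read_transcripts(gtf)
    orfs, w2 = read_orfs(orf_table, transcripts)
    bundle = AnnotationBundle(reference, transcripts.values(), orfs.values())
    return bundle, w1 + w2


# ---------------------------------------------------------------------------
# writers (used by the simulator/fixture export and the CLI)
# ---------------------------------------------------------------------------

def write_fasta(reference: GenomeReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in reference.contigs():
            lo, hi = reference.window(chrom)
            header = chrom if lo == 1 else f"{chrom}:{lo}-{hi}"
            fh.write(f">{header}\n")
            seq = reference.fetch(chrom, lo, hi)
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_gtf(transcripts: dict[str, Transcript] | list[Transcript],
              path: str | Path) -> None:
    txs = (transcripts.values() if isinstance(transcripts, dict)
           else transcripts)
    with open(path, "w") as fh:
        for tx in txs:
            for e in sorted(tx.exons, key=lambda e: e.start):
                attrs = (f'gene_name "{tx.gene}"; '
                         f'transcript_id "{tx.accession}";')
                fh.write("\t".join([
                    tx.chrom, "orfvar", "exon", str(e.start), str(e.end),
                    ".", tx.strand, ".", attrs]) + "\n")


def write_orf_table(orfs: dict[str, ORFModel] | list[ORFModel],
                    path: str | Path) -> None:
    items = orfs.values() if isinstance(orfs, dict) else orfs
    rows = [{"protein_accession": o.protein_accession,
             "transcript_accession": o.transcript_accession,
             "coord_space": "transcript",
             "start": o.cds_t_start, "end": o.cds_t_end,
             "category": o.category} for o in items]
    pd.DataFrame(rows, columns=ORF_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def write_vcf(variants: list[Variant], reference: GenomeReference,
              path: str | Path) -> None:
    header = pysam.VariantHeader()
    for chrom in reference.contigs():
        _, hi = reference.window(chrom)
        header.contigs.add(chrom, length=hi)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            out.write(rec)
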