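"""Output tables: per-effect TSV, per-variant max-impact TSV, annotated VCF
and summary statistics.

The max-impact table applies the reporting rule for non-canonical ORFs: a
variant's alternative-ORF columns are populated only when its maximal
impact on an alternative ORF is greater than or equal to its maximal impact
on a canonical ORF.  The canonical effect is always visible in every
output.
"""

from __future__ import annotations

import json
import warnings as _pywarnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .effects import EffectRecord, Impact, severity_rank
from .model import Variant

ANN_COLUMNS = ["CHROM", "POS", "REF", "ALT", "ANN[*].EFFECT",
               "ANN[*].IMPACT", "ANN[*].HGVS_C", "ANN[*].HGVS_P",
               "ANN[*].FEATUREID", "ANN[*].GENE"]

MAX_IMPACT_COLUMNS = ["hg38_name", "in_ref", "in_alt", "ref_max_impact",
                      "alt_max_impact", "ref_transcript", "ref_protein",
                      "ref_hgvs_c", "ref_hgvs_p", "alt_transcript",
                      "alt_protein", "alt_hgvs_c", "alt_hgvs_p"]

#: effects that attribute the variant to the transcript but not to any
#: region of the ORF itself
_NON_HIT = {"intergenic_variant", "upstream_gene_variant",
            "downstream_gene_variant"}


def _group_by_variant(records: list[EffectRecord]
                      ) -> dict[Variant, list[EffectRecord]]:
    grouped: dict[Variant, list[EffectRecord]] = {}
    for r in records:
        grouped.setdefault(r.variant, []).append(r)
    return grouped


def _best(records: list[EffectRecord]) -> EffectRecord:
    return min(records, key=lambda r: (-int(r.impact), severity_rank(r.effect),
                                       r.transcript_accession,
                                       r.protein_accession))


def write_ann_one_per_line(records: list[EffectRecord],
                           path: str | Path) -> pd.DataFrame:
    """One row per effect of each variant, SnpEff-style column names."""
    rows = []
    for r in records:
        v = r.variant
        rows.append({
            "CHROM": v.chrom, "POS": v.pos, "REF": v.ref, "ALT": v.alt,
            "ANN[*].EFFECT": r.effect_string,
            "ANN[*].IMPACT": r.impact.label,
            "ANN[*].HGVS_C": r.cdna_change,
            "ANN[*].HGVS_P": r.protein_change,
            "ANN[*].FEATUREID": r.feature_id,
            "ANN[*].GENE": r.gene,
        })
    df = pd.DataFrame(rows, columns=ANN_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def max_impact_table(records: list[EffectRecord]) -> pd.DataFrame:
    """One row per variant: maximal canonical vs non-canonical impact.

    Ties among records of equal impact are broken by effect severity, then
    transcript/protein accession.  Alternative-ORF fields are suppressed
    (left empty, alt_max_impact reported as 0-boundable value) only in the
    sense that the columns stay blank when alt_max < ref_max.
    """
    rows = []
    for v, recs in _group_by_variant(records).items():
        canon = [r for r in recs if r.orf_category == "canonical"]
        alt = [r for r in recs if r.orf_category == "alternative"]
        ref_max = max((int(r.impact) for r in canon), default=0)
        alt_max = max((int(r.impact) for r in alt), default=0)
        row = {c: "" for c in MAX_IMPACT_COLUMNS}
        row.update(hg38_name=v.name,
                   in_ref=any(r.effect.value not in _NON_HIT for r in canon),
                   in_alt=any(r.effect.value not in _NON_HIT for r in alt),
                   ref_max_impact=ref_max, alt_max_impact=alt_max)
        if canon:
            b = _best(canon)
            row.update(ref_transcript=b.transcript_accession,
                       ref_protein=b.protein_accession,
                       ref_hgvs_c=b.cdna_change, ref_hgvs_p=b.protein_change)
        if alt and alt_max >= ref_max:
            b = _best(alt)
            row.update(alt_transcript=b.transcript_accession,
                       alt_protein=b.protein_accession,
                       alt_hgvs_c=b.cdna_change, alt_hgvs_p=b.protein_change)
        rows.append(row)
    return pd.DataFrame(rows, columns=MAX_IMPACT_COLUMNS)


def write_max_impact(records: list[EffectRecord], path: str | Path
                     ) -> pd.DataFrame:
    df = max_impact_table(records)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_annotated_vcf(records: list[EffectRecord], input_vcf: str | Path,
                        path: str | Path) -> None:
    """Copy the input VCF adding a SnpEff-dialect ANN INFO field.

    ANN entries are Allele|Effect|Impact|Gene|FeatureID|HGVS_c|HGVS_p,
    canonical-ORF entries first, then severity.  Records are matched to the
    input by (chrom, pos, ref, alt) of the pre-normalization alleles.
    """
    by_key: dict[tuple, list[EffectRecord]] = {}
    for r in records:
        key = r.variant.source_key or (r.variant.chrom, r.variant.pos,
                                       r.variant.ref, r.variant.alt)
        by_key.setdefault(key, []).append(r)
    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore")
        vcf_in = pysam.VariantFile(str(input_vcf))
        header = vcf_in.header.copy()
        if "ANN" not in header.info:
            header.info.add(
                "ANN", ".", "String",
                "Functional annotations: "
                "'Allele|Effect|Impact|Gene|FeatureID|HGVS_c|HGVS_p'")
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for rec in vcf_in:
                entries = []
                for alt in rec.alts or ():
                    for r in by_key.get((rec.chrom, rec.pos, rec.ref, alt),
                                        ()):
                        entries.append("|".join([
                            alt, r.effect_string, r.impact.name, r.gene,
                            r.feature_id, r.cdna_change, r.protein_change]))
                new = out.new_record(contig=rec.chrom, start=rec.start,
                                     alleles=rec.alleles, id=rec.id,
                                     qual=rec.qual)
                for k, val in rec.info.items():
                    new.info[k] = val
                if entries:
                    new.info["ANN"] = tuple(entries)
                out.write(new)


@dataclass
class ImpactSummary:
    """Variant counts per impact category (each variant counted once at its
    overall maximal impact across all ORFs)."""

    counts: dict[str, int]
    proportions: dict[str, float]
    n_variants: int

    def to_dict(self) -> dict:
        return {"n_variants": self.n_variants, "counts": self.counts,
                "proportions": self.proportions}


def variant_max_impacts(records: list[EffectRecord]
                        ) -> dict[Variant, tuple[int, int]]:
    """Per variant: (overall max impact code, canonical-only max code)."""
    out: dict[Variant, tuple[int, int]] = {}
    for v, recs in _group_by_variant(records).items():
        overall = max(int(r.impact) for r in recs)
        canon = max((int(r.impact) for r in recs
                     if r.orf_category == "canonical"), default=0)
        out[v] = (overall, canon)
    return out


def summarize(records: list[EffectRecord],
              path: str | Path | None = None) -> ImpactSummary:
    """Impact-category composition of a variant set; optional JSON output."""
    maxima = variant_max_impacts(records)
    labels = [imp.label for imp in Impact]
    counts = {lab: 0 for lab in labels}
    for overall, _ in maxima.values():
        counts[Impact(overall).label] += 1
    n = len(maxima)
    proportions = {lab: (counts[lab] / n if n else 0.0) for lab in labels}
    summary = ImpactSummary(counts=counts, proportions=proportions,
                            n_variants=n)
    if path is not None:
        Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    return summary
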