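"""Annotate the five published variants of a dual-coding locus.

Builds the HEY2-style fixture (two-exon transcript carrying the canonical
CDS and an overlapping alternative ORF in a shifted frame) and prints each
variant's consequence on both ORFs side by side.  The point: a single
variant can be a missense in one reading frame and a stop-gain in the
other, or a 3'UTR bystander for the canonical protein yet a missense
change for the alternative one.
"""

from orfvar import annotate_variants, build_fixture_hey2

bundle, variants = build_fixture_hey2()
records, _ = annotate_variants(variants, bundle)

by = {}
for r in records:
    by.setdefault(r.variant, {})[r.orf_category] = r

print(f"{'variant':<22}{'canonical (Q9UBP5)':<34}alternative (IP_145210)")
for v, recs in by.items():
    cells = []
    for cat in ("canonical", "alternative"):
        r = recs[cat]
        p = r.protein_change_short or "-"
        cells.append(f"{r.effect.value} {p} [{r.impact.label}]")
    print(f"{v.chrom}:{v.pos} {v.ref}>{v.alt:<6}{cells[0]:<34}{cells[1]}")

print("\nEach row is one genomic change; the two columns are independent "
      "reading frames.\nNote the last variant: modifier for the canonical "
      "ORF (past its stop codon) but a\nmoderate-impact missense at codon "
      "137 of the alternative ORF.")
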