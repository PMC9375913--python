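# Methods

## Data model and coordinates

All coordinates are 1-based inclusive (VCF/GTF convention). Transcript
coordinates count 5'→3' on the coding strand. An ORF is a transcript-space
span `[cds_t_start, cds_t_end]` **including the stop codon** — required so
that stop_lost and stop_retained are classifiable — whose length must be a
multiple of 3; spans that are not are kept with a `frame_ok=False` flag,
warned about, and excluded from coding-consequence calls. A transcript may
host any number of ORFs, overlapping in different frames; each carries a
`category` of `canonical` (reference-annotation CDS) or `alternative`.

Variants are minimally normalized: shared suffix then shared prefix
trimmed (keeping one base each side), position advanced over the trimmed
prefix. No left-alignment against the reference is attempted — inputs are
assumed curated. Multi-allelic records are split. The class (SNV/MNP/
INS/DEL) is derived from allele lengths; for indels the first base is the
conventional VCF anchor and is not counted as changed.

## Consequence engine

Each variant is classified independently against every ORF of every
transcript within the flank window (default 5,000 bp, a common annotator
default; the sources are silent on this). Region calls are ORF-relative:
an exonic position 5' of the ORF is `five_prime_UTR_variant` *for that
ORF* even when it lies inside another ORF's CDS. Splice terms come from
transcript-level junction geometry and apply to every ORF of the
transcript: intronic bases 1–2 from either end are donor/acceptor (high),
3–8 are `splice_region` (low), exonic bases within 3 nt of a junction gain
a secondary `splice_region` term. These windows are conventional annotator
defaults and are configurable (`AnnotationConfig`).

Coding SNVs mutate the affected codon at its computed offset
(strand-aware, spliced across junctions) and compare translations;
any non-ATG mutant codon 1 is `start_lost` (no near-cognate start
allowance). MNPs re-translate every affected codon and report the single
most severe term (fixed severity order, most → least severe:
stop_gained, stop_lost, start_lost, frameshift, splice_acceptor,
splice_donor, missense, inframe_insertion, inframe_deletion,
splice_region, synonymous, stop_retained, then the modifier terms);
remaining terms join the record as secondary terms (`&`-joined in
outputs). Indels: length change mod 3 ≠ 0 → frameshift; deletions
removing start-codon bases → start_lost, removing stop-codon bases →
stop_lost; frame-preserving edits are re-translated so an in-frame change
that creates an early stop is reported as stop_gained rather than a bare
inframe term. Indels spanning an exon boundary are classified by the most
severe applicable per-base term with a warning.

Protein changes are emitted both as 3-letter HGVS (`p.Arg127Ter`,
`p.Phe137Leu`, `p.Ser308=`) and 1-letter shorthand (`R127*`, `F137L`).
The per-ORF record identifier is `transcript@protein`; the `@` separator
is this package's choice.

Impact mapping is total and fixed: HIGH = {stop_gained, stop_lost,
start_lost, frameshift, splice_acceptor, splice_donor}; MODERATE =
{missense, inframe_insertion, inframe_deletion}; LOW = {splice_region,
synonymous, stop_retained}; MODIFIER = everything else, coded 3/2/1/0.

## Validation oracle

The engine is validated against an independent route
(`orfvar.oracle.classify_by_retranslation`): apply the variant to the full
spliced transcript sequence, re-translate the entire coding span (reading
into the 3'UTR when the stop is lost or the frame shifts) and derive the
effect from a whole-protein diff. The oracle shares the published
conventions (severity order, splice windows, anchor choices) but none of
the engine's codon arithmetic. The simulator's truth tables are produced
by this oracle, never by the engine.

## Synthetic data

**Dual-coding fixture.** A two-exon plus-strand transcript (junction at
transcript 499/500, an implementation choice — no exon boundaries are
published) on a ~11.4 kb synthetic chromosome-6 window with true genomic
coordinates. The canonical CDS occupies transcript 198–1211 (1,014 nt =
337 aa + stop, resolving the published 198–1212 span in favour of the
protein length) and ends at 6:125,759,802; the alternative ORF occupies
805–1236 (432 nt, matching its published genomic span
125,759,396–125,759,827 and resolving the published 805–1237 likewise).
Bases required by the published consequences are pinned — CGA arginine
codons at canonical 127 and 239 (C>T → TGA), TCA at 308 and GGG at 331
(missense), CAA at alternative codon 106 and GGA at 129 (stop-gains), TTT
at 137 — and every other base is drawn from a seeded RNG with a repair
loop that resamples any premature stop in either frame. Translating the
fixture yields exactly 337+stop and 143+stop residues.

One published table cell is not reproducible from the published
coordinates themselves: the variant at 6:125,759,503 maps to transcript
912, *inside* the alternative ORF's span, at codon 36 offset 3, where a
third-position C>T is synonymous for every codon of the standard code —
it cannot be the 5'UTR call the table prints. The fixture therefore
reports `synonymous_variant` there; the variant's overall impact (high,
canonical stop-gain) and all counting results are unaffected.

**Simulator.** Random genes with 1–4 exons, a canonical ORF of 40–80
codons, 50–90 nt 5'UTR, 60–120 nt 3'UTR, 40–90 nt introns, on either
strand, with an alternative ORF in one of four layouts: `nested`
(shifted frame inside the CDS), `overlap3` (shifted frame, running past
the canonical stop — the fixture's geometry), `upstream`, `downstream`.
Variants are drawn as SNVs anywhere in the span ±150 bp, MNPs (2–3 nt)
within exons, and indels (1–4 nt) in the CDS interior within a single
exon — deliberately avoiding start/stop codons and exon boundaries for
indels, where annotator conventions (rather than biology) dominate the
call. What the simulator does *not* emulate: sequencing artefacts,
multi-transcript loci, non-uniform mutation spectra, and boundary-spanning
indels; passing tests therefore validate coordinate arithmetic and
classification logic, not robustness to messy real-world annotation.

## Cluster statistic

`p = |seq₁ ∩ seq₂| / |seq₁ ∪ seq₂|` over 1-based closed interval sets;
`binomial_cluster_test(n, k, p)` reports mean `np`, sd `√(np(1−p))`,
`z = (k − mean)/sd` and the one-sided normal tail. `p ∈ {0, 1}` is an
explicit error (sd = 0, z undefined). The significance threshold 2.58 is
a constant with an override. `p` may be passed directly instead of being
computed from intervals: the published overlap fraction (printed as
38.7%) back-computes from the published expected counts as 0.3873, while
the fixture's transcript coordinates give 407/1039 ≈ 0.392 — the exact
sequence pair behind the published fraction (with or without stop codons,
and which transcript union) is not derivable, which is precisely why the
statistic accepts `p` as an argument.

## Impact map

`impact_profile` computes, for every position of a region, the mean of the
per-variant impact codes within ±half_window (default 30 bp), via prefix
sums; empty windows map to 0 (a choice that keeps profiles total over the
region). The per-variant input is the variant's overall max impact across
ORFs for the all-ORF track and the canonical-only max for the comparison
track. `normalize_profiles` divides by the maximum across a reference
profile set, so a reference scaled by itself peaks at 1.

## Numerical and design notes

- Ties among equal-impact records are broken by effect severity, then
  transcript and protein accession; canonical records precede alternative
  ones in all outputs.
- `in_ref`/`in_alt` in the max-impact table are true when the variant has
  at least one record on that ORF class whose effect is not
  intergenic/upstream/downstream, i.e. the variant lies within the
  transcript and is classified relative to that ORF.
- The summary is written as JSON (a language-neutral replacement for a
  serialized binary object).
- Figure export is omitted; every profile and table is emitted as TSV.
- Genome-build liftover is out of scope: coordinates are taken at face
  value.
- Problem sizes in the test suite: 100 simulated genes × 8 variants for
  the oracle-equivalence property and 10⁶ draws for the Monte-Carlo
  binomial check — small enough to run in seconds while covering all
  layout × strand × exon-count combinations.

## Known limitations

- One ORF table row per protein accession; duplicate accessions overwrite.
- HGVS strings for indels/MNPs are simplified (`p.107ins1aa`,
  `c.22_24del` style), sufficient for filtering but not full
  HGVS-compliant normalization.
- Splice terms are transcript-geometric and reported for every ORF of the
  transcript, including ORFs whose CDS does not span the affected intron.
- No deleteriousness scoring (SIFT/PolyPhen-class) — out of scope by
  design; the tool annotates, it does not prioritize.
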