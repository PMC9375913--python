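"""Binomial enrichment of variants in a dual-coding overlap.

Under a uniform-and-independent null, the number of variants falling in
the intersection of two coding regions among n variants in their union is
B(n, p) with p = |intersection|/|union|.  This reproduces the three
published HEY2 z-scores from their printed (n, k) counts, using the overlap
probability implied by the printed expected counts (10.07/26 = 0.3873),
and also shows p computed directly from the fixture's transcript
coordinates.
"""

from orfvar import binomial_cluster_test, build_fixture_hey2, overlap_probability

bundle, _ = build_fixture_hey2()
canon = bundle.orfs["Q9UBP5"]
alt = bundle.orfs["IP_145210"]
p_coords = overlap_probability(
    [(canon.cds_t_start, canon.cds_t_end)],
    [(alt.cds_t_start, alt.cds_t_end)])
print(f"p from fixture transcript coordinates: {p_coords:.4f}")
print("p from the published expected counts:   0.3873\n")

for label, n, k in [("SynMicDB", 26, 19),
                    ("COSMIC (union)", 157, 83),
                    ("COSMIC synonymous", 55, 32)]:
    res = binomial_cluster_test(n, k, 0.3873)
    verdict = "significant" if res.significant else "not significant"
    print(f"{label:<18} n={n:<4} k={k:<4} expected {res.mean:5.2f} "
          f"+/- {res.sd:4.2f}  z={res.z:.2f}  ({verdict})")

print("\nz > 2.58 (one-sided P < 0.01) in all three sets: variants cluster "
      "in the dual-coding\nregion far beyond what region length alone "
      "explains.")
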