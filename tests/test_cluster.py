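"""Binomial overlap-enrichment statistic."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from orfvar import binomial_cluster_test, count_overlap_variants, overlap_probability
from orfvar.model import Variant


class TestOverlapProbability:
    def test_identical_intervals(self):
        assert overlap_probability([(1, 100)], [(1, 100)]) == 1.0

    def test_half_overlap(self):
        assert overlap_probability([(1, 100)], [(51, 150)]) == pytest.approx(
            50 / 150)

    def test_disjoint_gives_zero(self):
        assert overlap_probability([(1, 10)], [(20, 30)]) == 0.0

    def test_fixture_transcript_coordinates(self):
        # canonical CDS 198-1211 vs alternative ORF 805-1236
        p = overlap_probability([(198, 1211)], [(805, 1236)])
        assert p == pytest.approx(407 / 1039)
        assert p == pytest.approx(0.39, abs=0.005)

    def test_scale_equivariance(self):
        a, b = [(198, 1211)], [(805, 1236)]
        scaled_a = [(s * 7, e * 7) for s, e in a]
        scaled_b = [(s * 7, e * 7) for s, e in b]
        # scaling coordinates scales |∩| and |∪| alike, so p is unchanged
        # up to the closed-interval end effects, which vanish with length
        p1 = overlap_probability(a, b)
        p2 = overlap_probability(scaled_a, scaled_b)
        assert p2 == pytest.approx(p1, abs=1e-3)

    def test_multi_interval_union(self):
        p = overlap_probability([(1, 10), (21, 30)], [(6, 25)])
        assert p == pytest.approx(10 / 30)


class TestBinomialClusterTest:
    def test_null_expectation_gives_zero_z(self):
        res = binomial_cluster_test(100, 50, 0.5)
        assert res.z == 0.0 and not res.significant

    def test_z_sign_follows_excess(self):
        assert binomial_cluster_test(50, 30, 0.4).z > 0
        assert binomial_cluster_test(50, 10, 0.4).z < 0

    def test_fields_consistent_with_formulas(self):
        res = binomial_cluster_test(26, 19, 0.387)
        assert res.mean == pytest.approx(26 * 0.387)
        assert res.sd == pytest.approx(math.sqrt(26 * 0.387 * 0.613))
        assert res.z == pytest.approx((19 - res.mean) / res.sd)

    def test_degenerate_probability_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                binomial_cluster_test(10, 5, p)

    def test_monte_carlo_oracle_matches_analytic_moments(self):
        # 10^6 draws of B(26, 0.387): empirical mean/sd must agree with
        # n*p and sqrt(np(1-p)) within 3 Monte-Carlo standard errors
        n, p, reps = 26, 0.387, 1_000_000
        rng = np.random.default_rng(12345)
        draws = rng.binomial(n, p, size=reps)
        res = binomial_cluster_test(n, 10, p)
        se_mean = res.sd / math.sqrt(reps)
        assert abs(draws.mean() - res.mean) < 3 * se_mean
        se_sd = res.sd / math.sqrt(2 * (reps - 1))
        assert abs(draws.std(ddof=1) - res.sd) < 3 * se_sd

    @pytest.mark.parametrize("n", [20, 40, 80, 160])
    def test_normal_tail_tracks_exact_binomial(self, n):
        # continuity-corrected exact survival vs normal approximation
        p = 0.387
        k = int(n * p + 2 * math.sqrt(n * p * (1 - p)))
        res = binomial_cluster_test(n, k, p)
        exact = binom.sf(k - 1, n, p)          # P(X >= k)
        assert res.p_value == pytest.approx(exact, abs=0.05)


class TestCountOverlapVariants:
    def _setup(self, hey2):
        bundle, _ = hey2
        tx = bundle.transcripts["ENST00000368364"]
        return bundle, tx, bundle.orfs["Q9UBP5"], bundle.orfs["IP_145210"]

    def test_all_in_intersection(self, hey2):
        bundle, tx, a, b = self._setup(hey2)
        # transcript 900-1100 lies inside both coding spans
        vs = [Variant.normalized("6", tx.transcript_to_genomic(t),
                                 bundle.reference.base(
                                     "6", tx.transcript_to_genomic(t)), "N")
              for t in (900, 1000, 1100)]
        n, k = count_overlap_variants(vs, a, b, tx)
        assert (n, k) == (3, 3)

    def test_union_counts_and_published_scenario(self, hey2):
        bundle, tx, a, b = self._setup(hey2)
        # 19 of 26 variants in the dual-coding overlap (t 805-1211), the
        # rest in the canonical-only portion (t 198-804)
        tpos = [850 + 17 * i for i in range(19)] + [300 + 60 * i
                                                    for i in range(7)]
        vs = [Variant.normalized("6", tx.transcript_to_genomic(t),
                                 bundle.reference.base(
                                     "6", tx.transcript_to_genomic(t)), "N")
              for t in tpos]
        n, k = count_overlap_variants(vs, a, b, tx)
        assert (n, k) == (26, 19)
        res = binomial_cluster_test(n, k, overlap_probability(
            [(a.cds_t_start, a.cds_t_end)], [(b.cds_t_start, b.cds_t_end)]))
        assert res.significant

    def test_variant_outside_both_excluded(self, hey2):
        bundle, tx, a, b = self._setup(hey2)
        g = tx.transcript_to_genomic(100)   # 5'UTR
        v = Variant.normalized("6", g, bundle.reference.base("6", g), "N")
        assert count_overlap_variants([v], a, b, tx) == (0, 0)
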