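import math
from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest

from topocleave.region_stats import (
    BinEnvelope,
    IntervalSet,
    TUAnnotation,
    associate_with_tus,
    binomial_enrichment,
    binomial_two_sided,
    compare_shared_gcs,
    fisher_2x2,
    genome_bin_scan,
    poisson_conditional_test,
)
from topocleave.gcs_caller import GCSCall


def mk_call(p0, strength=1.0):
    return GCSCall(
        left_wall=p0 - 1, right_wall=p0 + 4, position=p0,
        n3e_strength=strength, p_left=0.0, p_right=0.0,
    )


# ---------------------------------------------------------------------------
# Exact-fraction oracles
# ---------------------------------------------------------------------------

def binom_sf_exact(k, n, p: Fraction) -> Fraction:
    """P(X >= k) by direct summation in exact rational arithmetic."""
    return sum(
        Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def fisher_two_sided_exact(a, b, c, d) -> Fraction:
    """Full enumeration over tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return total


class TestIntervalSet:
    def test_merged_length(self):
        s = IntervalSet("x", [(0, 10), (5, 20), (30, 40)])
        assert s.merged() == [(0, 20), (30, 40)]
        assert s.total_length == 30

    def test_contains(self):
        s = IntervalSet("x", [(10, 20)])
        assert s.contains([5, 10, 19, 20]).tolist() == [False, True, True, False]

    def test_invalid_interval_errors(self):
        with pytest.raises(ValueError):
            IntervalSet("x", [(10, 10)])

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr\t100\t200\nchr\t500\t800\n")
        s = IntervalSet.from_bed(bed, "regions")
        assert s.total_length == 400


class TestBinomialEnrichment:
    def test_all_in_half_genome(self):
        iv = IntervalSet("half", [(0, 500)])
        r = binomial_enrichment(list(range(0, 500, 50)), iv, 1000)
        assert r.observed == 10
        assert math.isclose(r.p_over, 0.5**10, rel_tol=1e-12)
        assert math.isclose(r.p_over, 9.765625e-4, rel_tol=1e-9)

    def test_fold_one_at_expectation(self):
        iv = IntervalSet("half", [(0, 500)])
        r = binomial_enrichment([1, 2, 3, 4, 5, 600, 700, 800, 900, 999], iv, 1000)
        assert r.observed == 5 and math.isclose(r.fold, 1.0)

    def test_eight_of_ten(self):
        iv = IntervalSet("half", [(0, 500)])
        pos = [1, 2, 3, 4, 5, 6, 7, 8, 600, 700]
        r = binomial_enrichment(pos, iv, 1000)
        assert math.isclose(r.p_over, 56 / 1024, rel_tol=1e-12)

    def test_matches_exact_fraction_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 31))
            length = int(rng.integers(1, 1000))
            iv = IntervalSet("s", [(0, length)])
            pos = rng.integers(0, 1000, n)
            r = binomial_enrichment(pos, iv, 1000)
            oracle = binom_sf_exact(r.observed, n, Fraction(length, 1000))
            assert abs(r.p_over - float(oracle)) < 1e-12

    def test_full_coverage_errors(self):
        with pytest.raises(ValueError):
            binomial_enrichment([1], IntervalSet("all", [(0, 10)]), 10)

    def test_empty_positions_error(self):
        with pytest.raises(ValueError):
            binomial_enrichment([], IntervalSet("s", [(0, 5)]), 10)

    def test_accepts_calls(self):
        iv = IntervalSet("x", [(0, 50)])
        r = binomial_enrichment([mk_call(10), mk_call(70)], iv, 100)
        assert r.observed == 1

    def test_agrees_with_permutation_oracle(self, rng):
        iv = IntervalSet("s", [(100, 400)])
        pos = rng.integers(0, 1000, 12)
        r = binomial_enrichment(pos, iv, 1000)
        draws = rng.integers(0, 1000, size=(10_000, 12))
        inside = ((draws >= 100) & (draws < 400)).sum(axis=1)
        mc = (inside >= r.observed).mean()
        assert abs(mc - r.p_over) < 4 * math.sqrt(r.p_over * (1 - r.p_over) / 10_000) + 1e-3


class TestGenomeBinScan:
    def test_envelope_ten_positions(self):
        env = genome_bin_scan(list(range(10)), 1000, bins=10)
        assert (env.lower, env.upper) == (0, 5)

    def test_concentrated_positions_flag_high(self):
        env = genome_bin_scan([5] * 200, 1000, bins=10)
        assert env.flags[0] == "high"
        assert all(f == "low" for f in env.flags[1:])

    def test_uniform_positions_unflagged(self):
        env = genome_bin_scan(list(range(50, 1000, 100)), 1000, bins=10)
        assert all(f == "ok" for f in env.flags)
        assert env.counts.tolist() == [1] * 10

    def test_last_bin_absorbs_remainder(self):
        env = genome_bin_scan([0, 1002], 1003, bins=10)
        assert env.edges[-1] == 1003
        assert env.counts[-1] == 1

    def test_too_many_bins_errors(self):
        with pytest.raises(ValueError):
            genome_bin_scan([1], 5, bins=10)

    def test_envelope_coverage_under_uniform_null(self, rng):
        n, reps, bins = 1000, 200, 10
        inside = 0
        for _ in range(reps):
            env = genome_bin_scan(rng.integers(0, 100_000, n), 100_000, bins=bins)
            inside += sum(f == "ok" for f in env.flags)
        assert inside / (reps * bins) >= 0.999


class TestFisher:
    def test_example_table(self):
        assert math.isclose(fisher_2x2(3, 1, 1, 3), float(fisher_two_sided_exact(3, 1, 1, 3)), rel_tol=1e-9)
        assert math.isclose(fisher_2x2(3, 1, 1, 3), 0.4857142857142857, rel_tol=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_2x2(5, 5, 5, 5) == 1.0

    def test_diagonal_table(self):
        assert math.isclose(fisher_2x2(10, 0, 0, 10), 2 / comb(20, 10), rel_tol=1e-9)

    def test_all_zero_degenerate(self):
        assert fisher_2x2(0, 0, 0, 0) == 1.0

    def test_negative_entries_error(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_for_small_margins(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, 4))
            if a + b + c + d == 0:
                continue
            assert abs(fisher_2x2(a, b, c, d) - float(fisher_two_sided_exact(a, b, c, d))) < 1e-12


class TestPoissonConditional:
    def test_eight_two_equal_exposure(self):
        one, _ = poisson_conditional_test(8, 2, 1.0, 1.0)
        assert math.isclose(one, 56 / 1024, rel_tol=1e-12)

    def test_equal_counts_two_sided_one(self):
        _, two = poisson_conditional_test(5, 5, 1.0, 1.0)
        assert two == 1.0

    def test_zero_zero(self):
        assert poisson_conditional_test(0, 0, 1.0, 1.0) == (1.0, 1.0)

    def test_unequal_exposures_match_oracle(self, rng):
        for _ in range(20):
            k1, k2 = (int(v) for v in rng.integers(0, 16, 2))
            if k1 + k2 == 0:
                continue
            t1, t2 = rng.integers(1, 5, 2).astype(float)
            one, _ = poisson_conditional_test(k1, k2, t1, t2)
            oracle = binom_sf_exact(
                k1, k1 + k2, Fraction(int(t1), int(t1) + int(t2))
            )
            assert abs(one - float(oracle)) < 1e-12

    def test_two_sided_minimum_likelihood_oracle(self):
        # sum of pmf values not exceeding pmf(k), in exact fractions
        n, k, p = 10, 8, Fraction(1, 2)
        pmf = [Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(n + 1)]
        oracle = sum(q for q in pmf if q <= pmf[k])
        _, two = poisson_conditional_test(8, 2, 1.0, 1.0)
        assert abs(two - float(oracle)) < 1e-12

    def test_bad_exposure_errors(self):
        with pytest.raises(ValueError):
            poisson_conditional_test(1, 1, 0.0, 1.0)


class TestTUAssociation:
    def test_downstream_of_forward_tu(self):
        tu = TUAnnotation("t", 1000, 2000, "+")
        res = associate_with_tus([2500], [tu], 100_000)
        assert res["all"]["counts"]["downstream"] == 1
        assert sum(res["all"]["counts"].values()) == 1

    def test_same_position_reverse_tu_is_upstream(self):
        tu = TUAnnotation("t", 1000, 2000, "-")
        res = associate_with_tus([2500], [tu], 100_000)
        assert res["all"]["counts"]["upstream"] == 1

    def test_body_halves(self):
        tu = TUAnnotation("t", 1000, 2000, "+")
        res = associate_with_tus([1200, 1800], [tu], 100_000)
        assert res["all"]["counts"]["body_start"] == 1
        assert res["all"]["counts"]["body_end"] == 1

    def test_nearest_tu_wins(self):
        a = TUAnnotation("a", 1000, 2000, "+")
        b = TUAnnotation("b", 2600, 3000, "+")
        # 2550 is downstream of a (550 from boundary 2000) and upstream of b (50)
        res = associate_with_tus([2550], [a, b], 100_000)
        assert res["all"]["counts"]["upstream"] == 1
        assert res["all"]["counts"]["downstream"] == 0
        assert res["all"]["ties"] == 0

    def test_uniform_null_fold_near_one(self, rng):
        tus = [
            TUAnnotation(f"t{i}", int(s), int(s) + 2000, "+")
            for i, s in enumerate(range(10_000, 90_000, 20_000))
        ]
        pos = rng.integers(0, 100_000, 3000)
        res = associate_with_tus(pos, tus, 100_000, us_width=2000, ds_width=2000)
        for comp, enr in res["all"]["enrichment"].items():
            assert 0.8 < enr.fold < 1.2, comp

    def test_expression_strata(self):
        tus = [
            TUAnnotation("lo", 1000, 2000, "+", expression=1.0),
            TUAnnotation("hi", 5000, 6000, "+", expression=100.0),
        ]
        # 10500 is inside the high-expression TU's downstream window only
        res = associate_with_tus([10500], tus, 100_000, expression_strata=2)
        assert res["stratum_1"]["counts"]["downstream"] == 1
        assert res["stratum_0"]["counts"]["downstream"] == 0


class TestCompareShared:
    def test_all_ratios_below_one(self):
        a = [mk_call(p, 2.0) for p in (10, 20, 30, 40, 50)]
        b = [mk_call(p, 1.0) for p in (10, 20, 30, 40, 50)]
        res = compare_shared_gcs(a, b)
        assert res["informative"] == 5 and res["n_ratio_below_1"] == 5
        assert math.isclose(res["p_below"], 0.5**5, rel_tol=1e-12)

    def test_symmetric_ratios_not_significant(self):
        a = [mk_call(p, 2.0) for p in range(10, 110, 10)]
        strengths = [1.0, 3.0] * 5
        b = [mk_call(p, s) for p, s in zip(range(10, 110, 10), strengths)]
        res = compare_shared_gcs(a, b)
        assert res["p_below"] > 0.3 and res["p_above"] > 0.3

    def test_exact_ties_dropped(self):
        a = [mk_call(10, 2.0), mk_call(20, 2.0), mk_call(30, 4.0)]
        b = [mk_call(10, 2.0), mk_call(20, 1.0), mk_call(30, 2.0)]
        res = compare_shared_gcs(a, b)
        assert res["shared"] == 3 and res["informative"] == 2

    def test_region_filter(self):
        a = [mk_call(10, 2.0), mk_call(500, 2.0)]
        b = [mk_call(10, 1.0), mk_call(500, 1.0)]
        res = compare_shared_gcs(a, b, IntervalSet("r", [(0, 100)]))
        assert res["shared"] == 1

    def test_no_shared_in_region_errors(self):
        a, b = [mk_call(10)], [mk_call(20)]
        with pytest.raises(ValueError):
            compare_shared_gcs(a, b)


def test_binomial_two_sided_never_exceeds_one(rng):
    for _ in range(20):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0.05, 0.95))
        assert 0 <= binomial_two_sided(k, n, p) <= 1.0
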