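"""The cASE statistic: per-sample binomial z, Stouffer combination, nulls."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casekit import AllelicCountRecord
from casekit.case import (
    binomial_signed_z,
    binomial_two_sided_p,
    combine_weighted_z,
    empirical_p,
    permutation_null,
    run_case,
    sample_z_table,
    tail_p,
    PermutationNull,
    SampleZ,
)
from casekit.errors import DegenerateNullError, UndefinedResultError


def brute_force_p(ref, alt):
    """Enumerate the Binomial(n, 0.5) pmf and sum both tails."""
    n = ref + alt
    pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    d = abs(ref - n / 2)
    return min(1.0, sum(p for k, p in enumerate(pmf) if abs(k - n / 2) >= d))


def brute_force_stouffer(z, w):
    """Hand-summed weighted Stouffer combination."""
    num = math.fsum(wi * zi for wi, zi in zip(w, z))
    den = math.sqrt(math.fsum(wi * wi for wi in w))
    return num / den


def _rec(sid, ref, alt):
    return AllelicCountRecord(sid, "rep1", "chr8", 118_185_000, ref, alt)


class TestBinomialSignedZ:
    def test_balance_gives_p_one_z_zero(self):
        assert binomial_signed_z(10, 10) == (1.0, 0.0)

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_matches_pmf_enumeration(self, ref, alt):
        if ref + alt == 0:
            with pytest.raises(ValueError):
                binomial_two_sided_p(ref, alt)
            return
        assert binomial_two_sided_p(ref, alt) == pytest.approx(brute_force_p(ref, alt), abs=1e-12)

    def test_sign_follows_allele_excess(self):
        _, z_ref = binomial_signed_z(9, 1)
        _, z_alt = binomial_signed_z(1, 9)
        assert z_ref > 0 > z_alt
        assert z_ref == -z_alt

    def test_extreme_counts_capped_not_infinite(self):
        _, z = binomial_signed_z(20000, 0)
        assert z == 38.0

    def test_zero_coverage_skipped_in_batch(self):
        samples = sample_z_table([_rec("S1", 0, 0), _rec("S2", 3, 9)])
        assert [s.sample_id for s in samples] == ["S2"]


class TestCombineWeightedZ:
    def test_single_sample_identity(self):
        s = SampleZ("S1", 10, 0.02, 2.3, 10.0)
        assert combine_weighted_z([s]) == pytest.approx(2.3)

    def test_equal_coverage_antisymmetric_pair_cancels(self):
        a = SampleZ("S1", 20, 0.05, 2.0, 20.0)
        b = SampleZ("S2", 20, 0.05, -2.0, 20.0)
        assert combine_weighted_z([a, b]) == 0.0

    def test_order_invariance(self, toy_records):
        samples = sample_z_table(toy_records)
        assert combine_weighted_z(samples) == combine_weighted_z(samples[::-1])

    def test_empty_input_is_an_error(self):
        with pytest.raises(UndefinedResultError):
            combine_weighted_z([])

    def test_duplicating_a_sample_differs_from_doubling_its_weight(self):
        # guards against a naive sum(w) denominator: under sqrt(sum w^2)
        # a duplicated record and a doubled weight give different Z
        base = [SampleZ("S1", 20, 0.05, 2.0, 20.0), SampleZ("S2", 30, 0.3, 1.0, 30.0)]
        dup = base + [SampleZ("S1b", 20, 0.05, 2.0, 20.0)]
        doubled = [SampleZ("S1", 20, 0.05, 2.0, 40.0), base[1]]
        z_dup = combine_weighted_z(dup)
        z_doub = combine_weighted_z(doubled)
        assert z_dup != pytest.approx(z_doub)
        assert z_dup == pytest.approx(brute_force_stouffer([2.0, 1.0, 2.0], [20, 30, 20]))
        assert z_doub == pytest.approx(brute_force_stouffer([2.0, 1.0], [40, 30]))


class TestPermutationNull:
    def test_all_balanced_records_give_degenerate_null(self):
        recs = [_rec("S1", 5, 5), _rec("S2", 8, 8)]
        null = permutation_null(recs, n_perm=100, seed=1)
        assert np.all(null.z_values == 0.0)

    def test_single_sample_flip_frequencies(self):
        null = permutation_null([_rec("S1", 9, 1)], n_perm=1000, seed=3)
        _, z = binomial_signed_z(9, 1)
        values = set(np.round(null.z_values, 12))
        assert values <= {round(z, 12), round(-z, 12)}
        n_pos = int(np.sum(null.z_values > 0))
        assert 450 <= n_pos <= 550  # Bernoulli(0.5), 3 sigma ~ 47

    def test_seed_determinism_and_record_order_invariance(self, toy_records):
        a = permutation_null(toy_records, n_perm=200, seed=9)
        b = permutation_null(toy_records[::-1], n_perm=200, seed=9)
        assert np.array_equal(a.z_values, b.z_values)
        c = permutation_null(toy_records, n_perm=200, seed=10)
        assert not np.array_equal(a.z_values, c.z_values)


class TestEmpiricalAndTailP:
    def test_zero_observation_has_p_one(self):
        null = PermutationNull(np.array([-1.0, 0.0, 1.0, 2.0]), 4, 0)
        assert empirical_p(0.0, null) == 1.0

    def test_hand_counted_example(self):
        null = PermutationNull(np.array([-1.0, 0.0, 1.0, 2.0]), 4, 0)
        assert empirical_p(1.0, null) == pytest.approx((1 + 3) / 5)

    def test_floor_at_add_one_estimate(self):
        null = PermutationNull(np.zeros(1000), 1000, 0)
        assert empirical_p(5.0, null) == pytest.approx(1 / 1001)

    def test_tail_p_recovers_normal_quantile(self):
        rng = np.random.default_rng(0)
        null = PermutationNull(rng.standard_normal(200_000), 200_000, 0)
        assert tail_p(1.959964, null) == pytest.approx(0.05, abs=0.005)

    def test_tail_p_at_null_mean_is_one(self):
        null = PermutationNull(np.array([-2.0, -1.0, 1.0, 2.0] * 10), 40, 0)
        assert tail_p(0.0, null) == 1.0

    def test_tail_p_affine_invariance(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(500)
        p1 = tail_p(1.3, PermutationNull(draws, 500, 0))
        p2 = tail_p(1.3 * 7.0, PermutationNull(draws * 7.0, 500, 0))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_null_raises(self):
        with pytest.raises(DegenerateNullError):
            tail_p(1.0, PermutationNull(np.zeros(100), 100, 0))


class TestRunCase:
    def test_low_coverage_reporter_flagged_not_dropped(self):
        recs = [_rec("S1", 2, 1), _rec("S2", 1, 2)]
        results = run_case(recs, min_cov=10, n_perm=50, seed=1)
        (r,) = results
        assert r.low_coverage and r.direction == "none"
        assert r.p_perm == 1.0 and r.p_tail == 1.0

    def test_direction_matches_sign_convention(self, toy_records):
        # reference-allele excess in every sample -> positive Z, ref-biased
        (r,) = run_case(toy_records, min_cov=5, n_perm=100, seed=1)
        assert r.Z > 0 and r.direction == "ref-biased"
        flipped = [
            AllelicCountRecord(x.sample_id, x.variant_id, x.chrom, x.pos, x.alt_count, x.ref_count)
            for x in toy_records
        ]
        (rf,) = run_case(flipped, min_cov=5, n_perm=100, seed=1)
        assert rf.Z < 0 and rf.direction == "alt-biased"

    def test_results_sorted_by_tail_p_and_bh_adjusted(self, toy_records):
        other = [_rec("S1", 11, 9), _rec("S2", 10, 10)]
        other = [
            AllelicCountRecord(x.sample_id, "rep2", x.chrom, x.pos, x.ref_count, x.alt_count)
            for x in other
        ]
        results = run_case(toy_records + other, min_cov=5, n_perm=100, seed=1)
        assert [r.variant_id for r in results] == ["rep1", "rep2"]
        assert results[0].p_tail <= results[1].p_tail
        assert all(r.q_value >= r.p_tail for r in results)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_allele_swap(self, seed):
        rng = np.random.default_rng(seed)
        recs = [
            _rec(f"S{i}", int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            for i in range(8)
        ]
        recs = [r for r in recs if r.coverage > 0]
        if not recs:
            return
        swapped = [
            AllelicCountRecord(r.sample_id, r.variant_id, r.chrom, r.pos, r.alt_count, r.ref_count)
            for r in recs
        ]
        (a,) = run_case(recs, min_cov=1, n_perm=100, seed=5)
        (b,) = run_case(swapped, min_cov=1, n_perm=100, seed=5)
        if a.low_coverage:
            return
        assert b.Z == -a.Z
        assert b.p_perm == a.p_perm
        assert b.p_tail == pytest.approx(a.p_tail, rel=1e-9)
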