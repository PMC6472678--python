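"""Unit tests for the agreement-index core: aggregation, subset enumeration,
ES, distance summaries, AF, the index formula and classification."""

import math

import numpy as np
import pytest

from eoa import (
    EnsembleSample,
    Hypothesis,
    adjustment_factor,
    aggregate_members,
    classify_eoa,
    compute_eoa,
    count_subsets,
    distance_summaries,
    eoa_from_components,
    estimate_eoa_sampled,
    find_min_fulfilling_size,
    subset_aggregates,
)
from eoa.core import SizeDistanceSummary

from naive_oracle import naive_eoa


class TestAggregateMembers:
    @pytest.mark.parametrize(
        "values,method,expected",
        [
            ([3, 1, 2], "median", 2.0),
            ([-1, 1], "median", 0.0),
            ([10, 20, 30, 40], "mean", 25.0),
            ([10, 20, 30, 40], "median", 25.0),
            ([5], "median", 5.0),
        ],
    )
    def test_examples(self, values, method, expected):
        assert aggregate_members(values, method) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty ensemble"):
            aggregate_members([], "median")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            aggregate_members([1, 2], "weighted")


class TestCountSubsets:
    @pytest.mark.parametrize("n,expected", [(17, 131071), (1, 1), (4, 15)])
    def test_closed_form(self, n, expected):
        assert count_subsets(n) == expected

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            count_subsets(0)


class TestSubsetAggregates:
    def test_singletons_are_the_members(self):
        sample = EnsembleSample.from_values([5, -5])
        assert sorted(subset_aggregates(sample, 1)) == [-5, 5]

    def test_pairwise_medians(self):
        sample = EnsembleSample.from_values([0, 10, 20])
        assert sorted(subset_aggregates(sample, 2, "median")) == [5, 10, 15]

    def test_total_count_n17(self):
        sample = EnsembleSample.from_values(np.linspace(-1, 1, 17))
        total = sum(subset_aggregates(sample, k).size for k in range(1, 18))
        assert total == 131071

    @pytest.mark.parametrize("size", [0, 8])
    def test_size_out_of_range(self, size):
        sample = EnsembleSample.from_values([1, 2, 3])
        with pytest.raises(ValueError, match="out of range"):
            subset_aggregates(sample, size)


class TestMinFulfillingSize:
    def test_all_members_above_gives_one(self, h0):
        sample = EnsembleSample.from_values([1, 2, 3, 4])
        assert find_min_fulfilling_size(sample, h0) == 1

    def test_two_strong_dissenters_give_five(self, two_level_7, h0):
        # brute-force over all 127 subsets agrees (see naive_oracle tests)
        assert find_min_fulfilling_size(two_level_7, h0) == 5

    def test_balanced_ensemble_has_no_fulfilling_size(self, symmetric_4, h0):
        assert find_min_fulfilling_size(symmetric_4, h0) is None

    def test_less_direction(self):
        sample = EnsembleSample.from_values([-5, -4, -3])
        h = Hypothesis(threshold=0.0, direction="less")
        assert find_min_fulfilling_size(sample, h) == 1


class TestDistanceSummaries:
    def test_es_one_gives_empty_list(self, two_level_7, h0):
        assert distance_summaries(two_level_7, h0, "median", 1) == []

    def test_singleton_distances(self, two_level_7, h0):
        (s1,) = distance_summaries(two_level_7, h0, "median", 2)
        assert s1.size == 1
        assert s1.my == pytest.approx(5.0)
        assert s1.mn == pytest.approx(10.0)
        assert s1.n_fulfilling == 5
        assert s1.n_total == 7

    def test_counts_partition_and_mn_absent_when_all_fulfil(self, h0):
        sample = EnsembleSample.from_values([-3, 1, 1, 1, 1, 1, 1])
        # at size 3 every median is 1 (at most one dissenter per triple)
        summaries = distance_summaries(sample, h0, "median", 4)
        for s in summaries:
            assert s.n_fulfilling <= s.n_total == math.comb(7, s.size)
        assert summaries[2].mn is None
        assert summaries[2].n_fulfilling == summaries[2].n_total


class TestAdjustmentFactor:
    def test_es_one_is_zero(self):
        assert adjustment_factor([], 1) == 0.0

    def test_balanced_ratios_give_zero(self):
        # fulfilling and dissenting aggregates equidistant: r_i = 1 at all sizes
        summaries = [
            SizeDistanceSummary(size=i, my=2.0, mn=2.0, n_fulfilling=3, n_total=6)
            for i in (1, 2, 3)
        ]
        assert adjustment_factor(summaries, 4) == 0.0

    def test_dominant_agreement_approaches_one(self):
        summaries = [
            SizeDistanceSummary(size=i, my=1e9, mn=1e-9, n_fulfilling=5, n_total=6)
            for i in (1, 2)
        ]
        assert adjustment_factor(summaries, 3) == pytest.approx(1.0, abs=1e-6)

    def test_absent_mn_borrows_max_defined_ratio(self):
        summaries = [
            SizeDistanceSummary(size=1, my=6.0, mn=2.0, n_fulfilling=4, n_total=5),
            SizeDistanceSummary(size=2, my=4.0, mn=None, n_fulfilling=10, n_total=10),
        ]
        # r = [3, fallback 3]; AF = 1 - 2/6
        assert adjustment_factor(summaries, 3) == pytest.approx(1 - 2 / 6)

    def test_missing_size_rejected(self):
        summaries = [
            SizeDistanceSummary(size=2, my=1.0, mn=1.0, n_fulfilling=1, n_total=2)
        ]
        with pytest.raises(ValueError, match="sizes"):
            adjustment_factor(summaries, 3)

    def test_mean_ratio_grouping_differs(self):
        summaries = [
            SizeDistanceSummary(size=1, my=0.2, mn=1.0, n_fulfilling=4, n_total=5),
            SizeDistanceSummary(size=2, my=3.0, mn=1.0, n_fulfilling=4, n_total=5),
        ]
        ratio_sum = adjustment_factor(summaries, 3, grouping="ratio_sum")
        mean_ratio = adjustment_factor(summaries, 3, grouping="mean_ratio")
        assert ratio_sum == pytest.approx(1 - 2 / 3.2)
        assert mean_ratio == 0.0  # 1 - 3.2/2 clamps at 0


class TestEOAFromComponents:
    @pytest.mark.parametrize(
        "es,af,n,expected",
        [
            (1, 0.0, 16, 1.0),
            (9, 0.0, 16, 0.5),     # half the members plus one
            (5, 0.0, 16, 0.75),    # a quarter of the members plus one
            (13, 0.0, 16, 0.25),   # three quarters plus one
            (1, 0.0, 11, 1.0),
            (None, 0.0, 16, 0.0),  # no sub-ensemble fulfils
        ],
    )
    def test_anchor_values(self, es, af, n, expected):
        assert eoa_from_components(es, af, n) == pytest.approx(expected, abs=1e-12)

    def test_af_raises_the_index(self):
        assert eoa_from_components(5, 0.5, 16) > eoa_from_components(5, 0.0, 16)

    @pytest.mark.parametrize("es,af,n", [(17, 0.0, 16), (3, 1.5, 16), (3, 0.0, 0)])
    def test_invalid_components_rejected(self, es, af, n):
        with pytest.raises(ValueError):
            eoa_from_components(es, af, n)


class TestClassifyEOA:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "Low"), (0.2499, "Low"),
            (0.25, "Medium"), (0.49, "Medium"),
            (0.5, "High"), (0.6, "High"),
            (0.75, "Very high"), (0.9999, "Very high"),
            (1.0, "Maximum"),
        ],
    )
    def test_interval_lookup(self, value, label):
        assert classify_eoa(value) == label

    def test_float_noise_near_boundary_snaps(self):
        assert classify_eoa(0.75 - 1e-14) == "Very high"
        assert classify_eoa(1.0 - 1e-13) == "Maximum"

    @pytest.mark.parametrize("value", [-0.1, 1.1])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_eoa(value)


class TestComputeEOA:
    def test_balanced_ensemble_scores_zero(self, symmetric_4, h0):
        res = compute_eoa(symmetric_4, h0)
        assert res.eoa == 0.0
        assert res.es is None
        assert res.af == 0.0
        assert res.eoa_class == "Low"

    def test_unanimous_ensemble_scores_one(self, h0):
        sample = EnsembleSample.from_values([5.0] * 11)
        res = compute_eoa(sample, h0)
        assert res.es == 1
        assert res.af == 0.0
        assert res.eoa == 1.0
        assert res.eoa_class == "Maximum"

    def test_matches_naive_enumeration(self, two_level_7, h0):
        res = compute_eoa(two_level_7, h0)
        expected = naive_eoa(two_level_7.values, threshold=0.0)
        assert res.es == expected["es"] == 5
        assert res.af == pytest.approx(expected["af"], abs=1e-12)
        assert res.eoa == pytest.approx(expected["eoa"], abs=1e-12)

    def test_enumerate_all_counts_every_subset(self, two_level_7, h0):
        res = compute_eoa(two_level_7, h0, enumerate_all=True)
        assert res.n_aggregates == 127

    def test_permutation_invariance(self, rng, h0):
        values = rng.normal(0.3, 1.0, size=9)
        base = compute_eoa(EnsembleSample.from_values(values), h0)
        for _ in range(5):
            rng.shuffle(values)
            res = compute_eoa(EnsembleSample.from_values(values), h0)
            assert (res.es, res.af, res.eoa) == (base.es, base.af, base.eoa)

    def test_mean_aggregation_supported(self, h0):
        sample = EnsembleSample.from_values([-1, -1, 10])
        res_mean = compute_eoa(sample, h0, method="mean")
        res_med = compute_eoa(sample, h0, method="median")
        # only the full ensemble's mean (8/3) clears the threshold
        assert res_mean.es == 3
        assert res_mean.eoa > 0
        assert res_med.eoa == 0.0  # median of the full ensemble is -1


class TestSampledEstimator:
    def test_degenerates_to_exhaustive_for_small_n(self, two_level_7, h0):
        exact = compute_eoa(two_level_7, h0)
        est = estimate_eoa_sampled(two_level_7, h0, n_samples_per_size=500, seed=1)
        assert est.exhaustive  # every size enumerable within the budget
        assert est.es == exact.es
        assert est.af == pytest.approx(exact.af, abs=1e-12)
        assert est.eoa == pytest.approx(exact.eoa, abs=1e-12)

    def test_seed_determinism(self, rng, h0):
        sample = EnsembleSample.from_values(rng.normal(1.0, 2.0, size=17))
        a = estimate_eoa_sampled(sample, h0, n_samples_per_size=200, seed=42)
        b = estimate_eoa_sampled(sample, h0, n_samples_per_size=200, seed=42)
        assert (a.es, a.af, a.eoa, a.exhaustive) == (b.es, b.af, b.eoa, b.exhaustive)
        assert not a.exhaustive

    def test_requires_seed(self, two_level_7, h0):
        with pytest.raises(ValueError, match="seed"):
            estimate_eoa_sampled(two_level_7, h0, n_samples_per_size=10, seed=None)


class TestEnsembleSampleValidation:
    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            EnsembleSample(member_ids=(), values=())

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="unique"):
            EnsembleSample(member_ids=("a", "a"), values=(1.0, 2.0))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            EnsembleSample.from_values([1.0, float("nan")])

    def test_rejects_non_finite_threshold(self):
        with pytest.raises(ValueError, match="finite"):
            Hypothesis(threshold=float("inf"))
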