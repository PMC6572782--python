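"""Population statistics: ON threshold, Fano factor, distributions, KS test."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from smfishquant import expression_stats as es


def brute_force_basal_threshold(counts, coverage=0.95):
    """Independent oracle: scan T upward until the cumulative fraction reaches coverage."""
    counts = list(counts)
    t = 0
    while sum(c <= t for c in counts) / len(counts) < coverage - 1e-12:
        t += 1
    return t


class TestBasalOnThreshold:
    def test_all_zero_basal(self):
        assert es.basal_on_threshold([0] * 50) == 0

    def test_stated_cumulative_example(self):
        counts = [0] * 60 + [1] * 20 + [2] * 15 + [7] * 5
        assert es.basal_on_threshold(counts) == 2

    def test_on_means_strictly_more_than_threshold(self):
        """With T = 2, a cell is ON only with more than two molecules."""
        counts = [0] * 60 + [1] * 20 + [2] * 15 + [7] * 5
        t = es.basal_on_threshold(counts)
        assert es.on_fraction(counts, t) == pytest.approx(0.05)
        assert es.on_fraction([2], t) == 0.0
        assert es.on_fraction([3], t) == 1.0

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            counts = rng.poisson(rng.uniform(0.1, 12), size=rng.integers(1, 60))
            coverage = rng.uniform(0.5, 1.0)
            assert es.basal_on_threshold(counts, coverage) == (
                brute_force_basal_threshold(counts, coverage)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.basal_on_threshold([])


class TestOnFraction:
    def test_direct_count(self):
        assert es.on_fraction([0, 0, 0, 5], 2) == 0.25

    def test_threshold_at_max_gives_zero(self, rng):
        counts = rng.integers(0, 20, size=30)
        assert es.on_fraction(counts, int(counts.max())) == 0.0

    def test_mixture_sampling(self, rng):
        """95/5 mixture of 0 and 20 molecules: ON-fraction estimates p = 0.05."""
        n = 10_000
        counts = np.where(rng.random(n) < 0.05, 20, 0)
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(es.on_fraction(counts, 2) - 0.05) < 3 * se

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nonincreasing_in_threshold(self, counts):
        fracs = [es.on_fraction(counts, t) for t in range(0, 52)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestFano:
    def test_zero_variance(self):
        assert es.fano([5, 5, 5, 5]) == 0.0

    def test_poisson_draws_near_unity(self, rng):
        """Fano of a Poisson sample is 1 within sampling error (SE ~ sqrt(2/n))."""
        n = 100_000
        counts = rng.poisson(10, size=n)
        se = math.sqrt(2 / n)
        assert abs(es.fano(counts) - 1.0) < 3 * se

    def test_population_variance_convention(self):
        # population variance of [0, 4] is 4, mean is 2
        assert es.fano([0, 4]) == 2.0
        # sample-variance convention is switchable
        assert es.fano([0, 4], ddof=1) == 4.0

    def test_zero_mean_is_missing_not_zero(self):
        assert math.isnan(es.fano([0, 0, 0]))


class TestDistributions:
    def test_marginal_direct_frequencies(self):
        np.testing.assert_allclose(
            es.marginal_distribution([1, 1, 2]), [0, 2 / 3, 1 / 3]
        )

    def test_marginal_point_mass(self):
        np.testing.assert_allclose(es.marginal_distribution([4, 4, 4]), [0, 0, 0, 0, 1])

    def test_marginal_matches_histogram(self, rng):
        counts = rng.integers(0, 15, size=500)
        hist = np.bincount(counts) / 500
        np.testing.assert_allclose(es.marginal_distribution(counts), hist)

    def test_joint_point_mass(self):
        joint = es.joint_distribution([1, 1], [2, 2])
        assert joint.shape == (2, 3)
        assert joint[1, 2] == 1.0
        assert joint.sum() == 1.0

    @given(
        st.lists(st.integers(0, 12), min_size=1, max_size=200),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_marginalization_identity_exact(self, nuc):
        """Joint marginals equal the marginal distributions exactly.

        Exactness is checked in counting space (de-normalized by n), where
        both sides are integers and no float summation order intervenes.
        """
        rng = np.random.default_rng(7)
        cyt = rng.integers(0, 9, size=len(nuc)).tolist()
        n = len(nuc)
        joint_counts = np.rint(es.joint_distribution(nuc, cyt) * n).astype(int)
        np.testing.assert_array_equal(
            joint_counts.sum(axis=1),
            np.rint(es.marginal_distribution(nuc) * n).astype(int),
        )
        np.testing.assert_array_equal(
            joint_counts.sum(axis=0),
            np.rint(es.marginal_distribution(cyt) * n).astype(int),
        )
        # and the normalized identity holds to float precision
        np.testing.assert_allclose(
            es.joint_distribution(nuc, cyt).sum(axis=1),
            es.marginal_distribution(nuc), rtol=0, atol=1e-12,
        )

    def test_independent_counts_factorize(self, rng):
        """For independent nuclear/cytoplasmic counts the joint is ~ the
        product of its marginals (chi-square not rejected at alpha = 0.01)."""
        n = 20_000
        nuc = rng.poisson(2, size=n)
        cyt = rng.poisson(4, size=n)
        joint = es.joint_distribution(nuc, cyt)
        expected = np.outer(es.marginal_distribution(nuc), es.marginal_distribution(cyt))
        mask = expected * n >= 5  # standard chi-square validity cut
        chi2 = (n * (joint[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        dof = mask.sum() - 1
        assert sstats.chi2.sf(chi2, dof) > 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            es.joint_distribution([1, 2], [1])


class TestAggregateReplicates:
    def _summary(self, mean, fano=1.0, on=0.2, tp=0.0):
        return es.ExpressionSummary(
            condition="0.2M", gene="STL1", timepoint=tp, n_cells=100,
            mean=mean, fano=fano, on_fraction=on, on_threshold=2,
        )

    def test_identical_replicas_zero_sd(self):
        agg = es.aggregate_replicates([self._summary(4.0), self._summary(4.0)])
        assert agg.replicate_stats["mean"] == (4.0, 0.0)

    def test_two_replicas_sample_sd(self):
        agg = es.aggregate_replicates([self._summary(4.0), self._summary(6.0)])
        mean, sd = agg.replicate_stats["mean"]
        assert mean == 5.0
        assert sd == pytest.approx(np.std([4, 6], ddof=1))  # = sqrt(2)

    def test_single_replica_sd_missing(self):
        agg = es.aggregate_replicates([self._summary(4.0)])
        assert math.isnan(agg.replicate_stats["mean"][1])

    def test_misaligned_timepoints_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            es.aggregate_replicates([self._summary(4.0, tp=0.0), self._summary(4.0, tp=5.0)])


class TestKsCompare:
    def test_identical_samples_d_zero(self, rng):
        sample = rng.integers(0, 10, size=50).tolist()
        d, p = es.ks_compare(sample, sample)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, _ = es.ks_compare([0, 0, 0], [9, 9, 9])
        assert d == 1.0

    def test_null_pvalues_roughly_uniform(self, rng):
        """Repeated same-distribution comparisons give ~uniform p-values.

        Discrete ties make the asymptotic p conservative, so the KS-of-KS
        check is one-sided: the p-value distribution must not pile up near 0.
        """
        pvals = []
        for _ in range(200):
            a = rng.poisson(20, size=150)
            b = rng.poisson(20, size=150)
            pvals.append(es.ks_compare(a, b)[1])
        assert np.mean(np.array(pvals) < 0.01) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            es.ks_compare([], [1, 2])


class TestSummarize:
    def test_mean_additivity_over_compartments(self, rng):
        nuc = rng.integers(0, 5, size=200)
        cyt = rng.integers(0, 20, size=200)
        total = nuc + cyt
        assert total.mean() == pytest.approx(nuc.mean() + cyt.mean())
        s = es.summarize(total, on_threshold=2, nuclear=nuc, cytoplasmic=cyt)
        assert s.mean == pytest.approx(total.mean())
        assert s.joint.sum() == pytest.approx(1.0)

    def test_threshold_from_basal_sample(self):
        basal = [0] * 95 + [9] * 5
        s = es.summarize([0, 5, 9, 1], basal_counts=basal)
        assert s.on_threshold == 0
        assert s.on_fraction == 0.75
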