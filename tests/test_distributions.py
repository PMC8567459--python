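"""Unit and property tests for the probability primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from refreshcat.distributions import (
    CRPParams,
    IWParams,
    PartitionVector,
    bell_number,
    canonical_partition,
    crp_assignment_probs,
    crp_joint_logprob,
    enumerate_partitions,
    hcrp_component_probs,
    hcrp_joint_logprob,
    iw_logpdf,
    iw_sample,
    truncnorm_logpdf,
    truncnorm_sample,
)


class TestCRP:
    @pytest.mark.parametrize("counts, alpha, expected", [
        ([2, 1], 10.0, [2 / 13, 1 / 13, 10 / 13]),
        ([], 3.0, [1.0]),
        ([5], 1.0, [5 / 6, 1 / 6]),
    ])
    def test_assignment_probs(self, counts, alpha, expected):
        np.testing.assert_allclose(crp_assignment_probs(counts, alpha), expected)

    def test_assignment_probs_reject_bad_alpha(self):
        with pytest.raises(ValueError):
            crp_assignment_probs([1, 1], 0.0)

    def test_joint_single_cluster(self):
        # sequential product 1 * (1/2) * (2/3) * ... = (n-1)!/n! = 1/n
        for n in (2, 3, 5):
            assert crp_joint_logprob([0] * n, 1.0) == pytest.approx(-math.log(n))

    def test_joint_all_singletons(self):
        # alpha/(i - 1 + alpha) at each step with alpha = 1: 1 * 1/2 * 1/3
        assert crp_joint_logprob([0, 1, 2], 1.0) == pytest.approx(math.log(1 / 6))

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=6),
           st.floats(0.1, 20.0))
    @settings(deadline=None, max_examples=60)
    def test_exchangeability(self, assignment, alpha):
        """The partition probability is identical under any item permutation."""
        base = crp_joint_logprob(assignment, alpha)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(assignment))
            assert crp_joint_logprob([assignment[i] for i in perm], alpha) == base

    def test_joint_equals_sequential_product(self):
        """Closed form agrees with multiplying seating probabilities."""
        alpha = 2.5
        assignment = [0, 0, 1, 0, 2, 1]
        logp = 0.0
        counts = []
        for a in assignment:
            probs = crp_assignment_probs(counts, alpha)
            if a < len(counts):
                logp += math.log(probs[a])
                counts[a] += 1
            else:
                logp += math.log(probs[-1])
                counts.append(1)
        assert crp_joint_logprob(assignment, alpha) == pytest.approx(logp)


class TestHierarchicalCRP:
    def test_symmetry_fixed_set(self):
        p = hcrp_component_probs([0, 0], [0.5, 0.5], CRPParams(alpha_g=0.0))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_context_dominance(self):
        p = hcrp_component_probs([3, 0], [0.5, 0.5],
                                 CRPParams(alpha_c=0.001, alpha_g=0.0))
        np.testing.assert_allclose(p, [3.0005 / 3.001, 0.0005 / 3.001])

    def test_infinite_alpha_c_gives_global_weights(self):
        p = hcrp_component_probs([7, 0, 0], [0.2, 0.3, 0.5],
                                 CRPParams(alpha_c=math.inf, alpha_g=0.0))
        np.testing.assert_allclose(p, [0.2, 0.3, 0.5])

    def test_zero_alpha_g_requires_fixed_set(self):
        with pytest.raises(ValueError):
            hcrp_component_probs([1, 2], None, CRPParams(alpha_g=0.0))

    def test_new_component_slot(self):
        p = hcrp_component_probs([0], [4.0], CRPParams(alpha_c=1.0, alpha_g=1.0))
        assert p.size == 2
        assert p.sum() == pytest.approx(1.0)

    def test_joint_matches_sequential_urn(self):
        alpha_c, j = 0.7, 3
        u = [0, 0, 2, 0, 1]
        logp, counts = 0.0, np.zeros(j)
        for uk in u:
            p = (counts + alpha_c / j) / (counts.sum() + alpha_c)
            logp += math.log(p[uk])
            counts[uk] += 1
        assert hcrp_joint_logprob(u, j, alpha_c) == pytest.approx(logp)


class TestInverseWishart:
    def test_mode_formula(self):
        params = IWParams(np.eye(2), 30.0)
        np.testing.assert_allclose(params.mode, np.eye(2) / 33)
        # numerical argmax over diagonal SPD matrices confirms the formula
        grid = np.linspace(0.005, 0.2, 400)
        dens = [iw_logpdf(np.diag([v, 1 / 33]), params) for v in grid]
        assert grid[int(np.argmax(dens))] == pytest.approx(1 / 33, abs=2e-3)

    def test_1d_reduces_to_inverse_gamma_and_normalizes(self):
        params = IWParams(np.array([[2.0]]), 5.0)
        val, _ = integrate.quad(
            lambda s: math.exp(iw_logpdf(np.array([[s]]), params)), 1e-6, 200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        x = np.array([[1.2, 0.3], [0.3, 0.8]])
        phi = np.array([[2.0, 0.5], [0.5, 1.5]])
        t = 0.7
        q = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        a = iw_logpdf(x, IWParams(phi, 12.0))
        b = iw_logpdf(q @ x @ q.T, IWParams(q @ phi @ q.T, 12.0))
        assert a == pytest.approx(b, abs=1e-9)

    def test_sampling_mean_and_spd(self, rng):
        params = IWParams(np.eye(2), 30.0)
        draws = iw_sample(params, rng, size=20000)
        mean = draws.mean(axis=0)
        np.testing.assert_allclose(mean, np.eye(2) / 27, atol=0.02 / 27 * 27 * 0.1)
        assert abs(mean[0, 0] - 1 / 27) / (1 / 27) < 0.05
        for d in draws[:100]:
            np.linalg.cholesky(d)

    def test_sampling_reproducible(self):
        params = IWParams(np.eye(3), 10.0)
        a = iw_sample(params, np.random.default_rng(7))
        b = iw_sample(params, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_sample_density_agreement_1d(self, rng):
        """KS smoke test: 1-D draws match the density."""
        params = IWParams(np.array([[1.0]]), 8.0)
        draws = iw_sample(params, rng, size=5000).ravel()
        # 1-D inverse-Wishart is inverse-gamma(dof/2, scale/2)
        ks = stats.kstest(draws, stats.invgamma(4.0, scale=0.5).cdf)
        assert ks.pvalue > 0.01


class TestTruncatedNormal:
    def test_support(self, rng):
        draws = truncnorm_sample(30.0, 30.0, 3.0, rng, size=10000)
        assert (draws >= 3.0).all()

    def test_density_normalizes(self):
        val, _ = integrate.quad(
            lambda v: math.exp(truncnorm_logpdf(v, 30.0, 30.0, 3.0)), 3.0, 400.0)
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_untruncated_limit(self):
        a = truncnorm_logpdf(1.0, 0.0, 1.0, -1e8)
        assert a == pytest.approx(stats.norm.logpdf(1.0), abs=1e-9)


class TestPartitions:
    @pytest.mark.parametrize("n, count", [(1, 1), (3, 5), (4, 15), (6, 203)])
    def test_counts(self, n, count):
        parts = enumerate_partitions(n)
        assert len(parts) == count == bell_number(n)
        assert len(set(parts)) == count

    def test_canonical_order_and_validity(self):
        for p in enumerate_partitions(5):
            assert p == canonical_partition(p)
            assert p[0] == 0

    def test_cap(self):
        with pytest.raises(ValueError):
            enumerate_partitions(11)

    def test_bell_small(self):
        assert [bell_number(n) for n in range(7)] == [1, 1, 2, 5, 15, 52, 203]

    def test_bell_100_leading_figures(self):
        lead = bell_number(100) // 10**114
        assert lead == 47

    def test_partition_vector_invariants(self):
        pv = PartitionVector((5, 5, 7, 5))
        assert pv.assignments == (0, 0, 1, 0)
        assert pv.counts == (3, 1)
        with pytest.raises(ValueError):
            PartitionVector((0, 1), counts=(2,))
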