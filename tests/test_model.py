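"""The generative model's predictives, decision rule and updates."""

import math

import numpy as np
import pytest
from scipy import integrate

from refreshcat.distributions import CRPParams
from refreshcat.model import (
    ClusterState,
    ComponentState,
    HierarchyState,
    Hyperparameters,
    assignment_posterior,
    classify,
    cluster_predictive_fixed_cov,
    gaussian_logpdf,
    joint_logprob,
    observe,
)


def make_trained_state(hyper, cov=np.eye(2)):
    return HierarchyState(
        hyper=hyper,
        components=[ComponentState(fixed_cov=cov)],
    )


class TestClusterPredictive:
    def test_empty_cluster_closed_form(self):
        hyper = Hyperparameters(dim=2, sigma_r2=1.0, omega=np.zeros(2))
        x = np.array([0.3, -0.5])
        got = cluster_predictive_fixed_cov(x, None, np.eye(2), hyper)
        want = gaussian_logpdf(x, np.zeros(2), 2 * np.eye(2))
        assert got == pytest.approx(want)

    def test_posterior_concentration(self):
        """With many members at a point, the predictive approaches
        a Gaussian centered there with the cluster covariance."""
        hyper = Hyperparameters(dim=2, sigma_r2=1.0, omega=np.zeros(2))
        mu_star = np.array([1.5, -0.2])
        members = np.tile(mu_star, (4000, 1))
        x = np.array([2.0, 0.3])
        got = cluster_predictive_fixed_cov(x, members, 0.5 * np.eye(2), hyper)
        want = gaussian_logpdf(x, mu_star, 0.5 * np.eye(2))
        assert got == pytest.approx(want, abs=1e-2)

    def test_matches_quadrature_1d(self):
        """The analytic marginal equals numerical integration over the mean."""
        hyper = Hyperparameters(dim=1, sigma_r2=0.7, omega=np.array([0.2]))
        members = np.array([[0.1], [0.4], [-0.3]])
        sig = np.array([[0.5]])
        x = np.array([0.25])

        def integrand(mu):
            val = math.exp(gaussian_logpdf(np.array([mu]), np.array([0.2]),
                                           np.array([[0.7]])))
            for m in members:
                val *= math.exp(gaussian_logpdf(m, np.array([mu]), sig))
            val *= math.exp(gaussian_logpdf(x, np.array([mu]), sig))
            return val

        numer, _ = integrate.quad(integrand, -8, 8)
        denom, _ = integrate.quad(
            lambda mu: math.exp(gaussian_logpdf(np.array([mu]), np.array([0.2]),
                                                np.array([[0.7]])))
            * np.prod([math.exp(gaussian_logpdf(m, np.array([mu]), sig))
                       for m in members]),
            -8, 8)
        want = math.log(numer / denom)
        got = cluster_predictive_fixed_cov(x, members, sig, hyper)
        assert got == pytest.approx(want, abs=1e-8)

    def test_rejects_non_spd(self):
        hyper = Hyperparameters(dim=2)
        with pytest.raises(ValueError):
            cluster_predictive_fixed_cov(np.zeros(2), None,
                                         np.array([[1.0, 2.0], [2.0, 1.0]]), hyper)


class TestAssignmentAndClassification:
    def _two_cluster_state(self, hyper):
        state = make_trained_state(hyper)
        state.data = [np.array([-1.0, 0.0])] * 2 + [np.array([1.0, 0.0])] * 2
        state.labels = [0, 0, 1, 1]
        state.item_context = [0] * 4
        state.clusters = [
            ClusterState(members=[0, 1], label=0, context=0, component=0),
            ClusterState(members=[2, 3], label=1, context=0, component=0),
        ]
        return state

    def test_symmetric_clusters_equal_mass(self, hyper2):
        state = self._two_cluster_state(hyper2)
        options, logp = assignment_posterior(np.zeros(2), state, context=0)
        p = dict(zip(options, np.exp(logp)))
        assert p[("cluster", 0)] == pytest.approx(p[("cluster", 1)])

    def test_small_alpha_kills_new_cluster_mass(self):
        hyper = Hyperparameters(dim=2, crp=CRPParams(alpha=1e-8, alpha_c=0.001,
                                                     alpha_g=0.0), sigma_r2=0.1)
        state = self._two_cluster_state(hyper)
        options, logp = assignment_posterior(np.zeros(2), state, context=0)
        new_mass = sum(math.exp(lp) for (kind, _), lp in zip(options, logp)
                       if kind == "new")
        assert new_mass < 1e-6

    def test_classify_midpoint_symmetry(self, hyper2):
        state = self._two_cluster_state(hyper2)
        probs = classify(np.zeros(2), state, context=0, label_set=(0, 1))
        assert probs[0] == pytest.approx(0.5)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_classify_matches_hand_bayes(self, hyper2):
        """Two clusters, one component: posterior odds computed by hand."""
        state = self._two_cluster_state(hyper2)
        x = np.array([0.4, 0.0])
        alpha = hyper2.crp.alpha
        lik = [math.exp(cluster_predictive_fixed_cov(
            x, np.array([state.data[i] for i in c.members]), np.eye(2), hyper2))
            for c in state.clusters]
        new_lik = math.exp(cluster_predictive_fixed_cov(x, None, np.eye(2), hyper2))
        w0, w1, wn = 2 * lik[0], 2 * lik[1], alpha * new_lik
        want0 = (w0 + 0.5 * wn) / (w0 + w1 + wn)
        probs = classify(x, state, context=0, label_set=(0, 1))
        assert probs[0] == pytest.approx(want0, rel=1e-9)

    def test_classify_dominant_cluster_tiny_alpha(self):
        """At the center of a large labeled cluster with tiny dispersion,
        the label probability approaches one."""
        hyper = Hyperparameters(dim=2, crp=CRPParams(alpha=1e-4, alpha_c=0.001,
                                                     alpha_g=0.0), sigma_r2=0.1)
        state = self._two_cluster_state(hyper)
        for _ in range(100):                       # grow cluster 0
            i = len(state.data)
            state.data.append(np.array([-1.0, 0.0]))
            state.labels.append(0)
            state.item_context.append(0)
            state.clusters[0].members.append(i)
        probs = classify(np.array([-1.0, 0.0]), state, context=0)
        assert probs[0] > 0.99

    def test_distant_cluster_changes_nothing(self, hyper2):
        state = self._two_cluster_state(hyper2)
        before = classify(np.zeros(2), state, context=0)
        state.data += [np.array([500.0, 500.0])]
        state.labels += [1]
        state.item_context += [0]
        state.clusters.append(ClusterState(members=[4], label=1, context=0,
                                           component=0))
        after = classify(np.zeros(2), state, context=0)
        assert abs(before[0] - after[0]) < 1e-6


class TestObserve:
    def test_first_observation_creates_cluster(self, hyper2):
        state = make_trained_state(hyper2)
        observe(np.array([0.0, 0.0]), 0, state, context=0, mode="map")
        assert len(state.clusters) == 1
        assert state.clusters[0].label == 0

    def test_map_mode_deterministic(self, hyper2):
        runs = []
        for _ in range(2):
            state = make_trained_state(hyper2)
            for t, (x, y) in enumerate([((0, 0), 0), ((0.1, 0), 0),
                                        ((3, 3), 1), ((0.05, 0), 0)]):
                observe(np.asarray(x, float), y, state, mode="map")
            runs.append(state.z_vector())
        assert runs[0] == runs[1]

    def test_sample_mode_reproducible(self, hyper2):
        outs = []
        for _ in range(2):
            state = make_trained_state(hyper2)
            rng = np.random.default_rng(42)
            for x, y in [((0, 0), 0), ((0.3, 0), 0), ((1, 1), 1), ((0.2, 0.2), 0)]:
                observe(np.asarray(x, float), y, state, mode="sample", rng=rng)
            outs.append(state.z_vector())
        assert outs[0] == outs[1]

    def test_label_purity_invariant(self, hyper2):
        state = make_trained_state(hyper2)
        rng = np.random.default_rng(0)
        for t in range(30):
            x = rng.normal(size=2) * 0.1
            observe(x, t % 2, state, mode="sample", rng=rng)
        state.validate()
        for c in state.clusters:
            labs = {state.labels[i] for i in c.members}
            assert len(labs) == 1


class TestJointLogprob:
    def _singleton_state(self, hyper):
        state = HierarchyState(
            hyper=hyper,
            data=[np.array([0.5, -0.2])],
            labels=[None],
            item_context=[0],
            components=[ComponentState(scale=np.eye(2), dof=30.0)],
        )
        state.clusters = [ClusterState(
            members=[0], context=0, component=0,
            mean=np.array([0.4, 0.0]), cov=0.2 * np.eye(2))]
        return state

    def test_term_by_term(self, hyper2_untrained):
        """The joint equals the sum of its independently computed terms."""
        from refreshcat.distributions import IWParams, iw_logpdf, truncnorm_logpdf

        hyper = hyper2_untrained
        state = self._singleton_state(hyper)
        cl = state.clusters[0]
        comp = state.components[0]
        want = 0.0                                    # CRP: single item, log 1
        want += math.log(hyper.crp.alpha_g / hyper.crp.alpha_g)  # first component
        want += iw_logpdf(comp.scale, IWParams(np.eye(2), hyper.v_t))
        want += float(truncnorm_logpdf(comp.dof, hyper.v_t, hyper.v_t, 2))
        want += iw_logpdf(cl.cov, IWParams(comp.scale, comp.dof))
        want += gaussian_logpdf(cl.mean, hyper.omega, hyper.sigma_r2 * np.eye(2))
        want += gaussian_logpdf(state.data[0], cl.mean, cl.cov)
        assert joint_logprob(state) == pytest.approx(want)

    def test_rotation_invariance(self, hyper2_untrained):
        """Rotating data and all parameters together leaves the joint fixed
        (isotropic top scale and mean prior)."""
        t = math.radians(37.0)
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        a = self._singleton_state(hyper2_untrained)
        b = self._singleton_state(hyper2_untrained)
        b.data = [rot @ x for x in b.data]
        cl = b.clusters[0]
        cl.mean = rot @ cl.mean
        cl.cov = rot @ cl.cov @ rot.T
        comp = b.components[0]
        comp.scale = rot @ comp.scale @ rot.T
        assert joint_logprob(a) == pytest.approx(joint_logprob(b), abs=1e-9)

    def test_inconsistent_state_rejected(self, hyper2_untrained):
        state = self._singleton_state(hyper2_untrained)
        state.clusters[0].members = [0, 1]  # phantom item
        with pytest.raises(ValueError):
            joint_logprob(state)


class TestSerialization:
    def test_round_trip(self, hyper2_untrained):
        state = HierarchyState(
            hyper=hyper2_untrained,
            data=[np.array([0.1, 0.2]), np.array([0.3, -0.1])],
            labels=[0, 0],
            item_context=[0, 0],
            components=[ComponentState(scale=np.eye(2), dof=12.0)],
        )
        state.clusters = [ClusterState(members=[0, 1], label=0, context=0,
                                       component=0, mean=np.zeros(2),
                                       cov=np.eye(2))]
        again = HierarchyState.from_json(state.to_json())
        assert again.z_vector() == state.z_vector()
        np.testing.assert_allclose(again.clusters[0].cov, np.eye(2))
        assert joint_logprob(again) == pytest.approx(joint_logprob(state))
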