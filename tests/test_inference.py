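"""Exact enumeration, particle filter, and Gibbs samplers."""

import math

import numpy as np
import pytest

from refreshcat.components import build_component_set
from refreshcat.distributions import CRPParams, canonical_partition
from refreshcat.inference import (
    GibbsConfig,
    ParticleFilterConfig,
    TrainedParticleFilter,
    exact_label_predictive,
    exact_posterior,
    run_gibbs,
    run_particle_filter,
)
from refreshcat.inference.exact import block_marginal_loglik_diag
from refreshcat.model import Hyperparameters
from refreshcat.tasks import biconditional_structure, generate_cluster_training


class TestExactPosterior:
    def test_normalizes_and_counts(self, hyper2, cset_nw_wn):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [2.0, 2.0]])
        parts, probs = exact_posterior(x, cset_nw_wn, hyper2)
        assert len(parts) == 5
        assert probs.sum() == pytest.approx(1.0)

    def test_identical_points_cluster_together(self):
        """Two coincident points away from the prior mean share a cluster:
        the second point's predictive under the first's cluster dwarfs the
        fresh-cluster predictive, overcoming even a large dispersion."""
        hyper = Hyperparameters(dim=2, crp=CRPParams(alpha=50.0, alpha_c=0.001,
                                                     alpha_g=0.0), sigma_r2=1.0)
        cset = build_component_set(("ww",), (2.0, 2.0))
        x = np.full((2, 2), 3.0)
        parts, probs = exact_posterior(x, cset, hyper)
        together = probs[parts.index((0, 0))]
        apart = probs[parts.index((0, 1))]
        assert together > apart

    def test_cap_enforced(self, hyper2, cset_nw_wn):
        with pytest.raises(ValueError):
            exact_posterior(np.zeros((9, 2)), cset_nw_wn, hyper2)

    def test_block_marginal_matches_chain_rule(self, hyper2):
        """Closed-form cluster marginal equals the sequential predictive chain."""
        from refreshcat.model import cluster_predictive_fixed_cov

        psi = np.array([0.3, 1.4])
        pts = np.array([[0.1, 0.2], [0.4, -0.1], [0.0, 0.3]])
        chain = 0.0
        for i in range(3):
            chain += cluster_predictive_fixed_cov(
                pts[i], pts[:i] if i else None, np.diag(psi), hyper2)
        closed = block_marginal_loglik_diag(pts, psi, hyper2.sigma_r2, hyper2.omega)
        assert closed == pytest.approx(chain, abs=1e-10)

    def test_label_predictive_first_trial_uniform(self, hyper2, cset_nw_wn):
        st = biconditional_structure()
        x = st.stimuli[:, [0, 2]]
        probs = exact_label_predictive(x, st.labels, cset_nw_wn, hyper2)
        np.testing.assert_allclose(probs[0], [0.5, 0.5])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)


class TestParticleFilter:
    def _setup(self):
        st = biconditional_structure()
        x = st.stimuli[:, [0, 2]]
        cset = build_component_set(("nw", "wn"), (1.3, 1.3))
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 0.0),
                                sigma_r2=0.1, omega=x.mean(axis=0))
        return x, st.labels, cset, hyper

    def test_single_particle_runs_normalized(self):
        x, labels, cset, hyper = self._setup()
        probs, _ = run_particle_filter(x, labels, cset, hyper,
                                       ParticleFilterConfig(n_particles=1, seed=0))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_seed_reproducibility(self):
        x, labels, cset, hyper = self._setup()
        a, _ = run_particle_filter(x, labels, cset, hyper,
                                   ParticleFilterConfig(n_particles=50, seed=3))
        b, _ = run_particle_filter(x, labels, cset, hyper,
                                   ParticleFilterConfig(n_particles=50, seed=3))
        np.testing.assert_array_equal(a, b)

    def test_matches_exact_sequential_predictive(self):
        """Trial-by-trial label probabilities agree with exact enumeration."""
        x, labels, cset, hyper = self._setup()
        exact = exact_label_predictive(x, labels, cset, hyper)
        pf, _ = run_particle_filter(x, labels, cset, hyper,
                                    ParticleFilterConfig(n_particles=10_000, seed=1))
        np.testing.assert_allclose(pf, exact, atol=0.02)

    def test_resampling_stability(self):
        """Mean predictive across seeded runs is stable (weights preserved)."""
        x, labels, cset, hyper = self._setup()
        exact = exact_label_predictive(x, labels, cset, hyper)
        vals = []
        for seed in range(30):
            pf, _ = run_particle_filter(
                np.tile(x, (3, 1)), np.tile(labels, 3), cset, hyper,
                ParticleFilterConfig(n_particles=200, seed=seed))
            vals.append(pf[-1, labels[-1]])
        assert np.std(vals) < 0.05

    def test_partition_distribution_sums_to_one(self):
        x, labels, cset, hyper = self._setup()
        pf = TrainedParticleFilter(cset, hyper, n_labels=2,
                                   cfg=ParticleFilterConfig(500, seed=2))
        pf.run(x, labels)
        dist = pf.partition_distribution()
        assert sum(dist.values()) == pytest.approx(1.0)
        for p in dist:
            assert p == canonical_partition(p)


class TestFullGibbs:
    def test_seed_reproducibility(self):
        ts = generate_cluster_training(preset="six_axis_aligned", seed=1)
        x = ts.points[:40]
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 1.0),
                                v_t=30.0, sigma_r2=1.0, omega=x.mean(axis=0))
        cfg = GibbsConfig(n_samples=20, burn_in=5, seed=9)
        a = run_gibbs(x, hyper, cfg)
        b = run_gibbs(x, hyper, cfg)
        assert [s["partition"] for s in a.samples] == [s["partition"] for s in b.samples]
        np.testing.assert_allclose(a.samples[-1]["data_loglik"],
                                   b.samples[-1]["data_loglik"])

    def test_no_systematic_drift_after_burn_in(self):
        """Stationarity smoke test: data log likelihood has no upward trend."""
        ts = generate_cluster_training(preset="six_axis_aligned", seed=2)
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 1.0),
                                v_t=30.0, sigma_r2=1.0,
                                omega=ts.points.mean(axis=0))
        post = run_gibbs(ts.points, hyper,
                         GibbsConfig(n_samples=160, burn_in=60, seed=4),
                         contexts=ts.contexts)
        lls = np.array([s["data_loglik"] for s in post.samples])
        half = len(lls) // 2
        spread = lls.std()
        assert abs(lls[half:].mean() - lls[:half].mean()) < max(3 * spread, 30.0)

    def test_label_purity_and_context_purity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(24, 2)) * 0.2
        labels = np.arange(24) % 2
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 1.0),
                                v_t=30.0, sigma_r2=1.0, omega=x.mean(axis=0))
        post = run_gibbs(x, hyper, GibbsConfig(n_samples=30, burn_in=10, seed=1),
                         labels=labels)
        for snap in post.samples:
            z = np.asarray(snap["partition"])
            for k in set(z.tolist()):
                assert len(set(labels[z == k].tolist())) == 1

    def test_cluster_covariance_recovery(self):
        """Posterior cluster covariances recover the generating narrow/wide
        axis ratio within a factor of two (six-cluster training regime)."""
        ts = generate_cluster_training(preset="six_axis_aligned", seed=7)
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 1.0),
                                v_t=30.0, sigma_r2=1.0,
                                omega=ts.points.mean(axis=0))
        post = run_gibbs(ts.points, hyper,
                         GibbsConfig(n_samples=120, burn_in=40, seed=3),
                         contexts=ts.contexts)
        ratios = []
        for snap in post.samples[::10]:
            for cl in snap["clusters"]:
                if cl["size"] >= 15:
                    ev = np.sort(np.linalg.eigvalsh(cl["sigma"]))
                    ratios.append(math.sqrt(ev[1] / ev[0]))
        med = float(np.median(ratios))
        assert 5.0 < med < 20.0   # generating sd ratio is 10
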