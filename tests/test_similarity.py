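"""Similarity fields, metric fitting, metric diagnostics, d-prime."""

import numpy as np
import pytest

from refreshcat.components import build_component_set
from refreshcat.distributions import CRPParams
from refreshcat.model import Hyperparameters
from refreshcat.similarity import (
    SimilarityField,
    convexity_and_triangle_check,
    dprime,
    fit_minkowski,
    iso_similarity_field,
    learning_curve,
    similarity,
)
from refreshcat.tasks import biconditional_structure


def forward_field(r, decay=1.0, w1=0.5, theta_deg=0.0, n=41, extent=3.0):
    """A similarity field generated from a known Minkowski metric."""
    xs = np.linspace(-extent, extent, n)
    dx, dy = np.meshgrid(xs, xs, indexing="ij")
    if theta_deg:
        t = np.deg2rad(theta_deg)
        dx, dy = np.cos(t) * dx + np.sin(t) * dy, -np.sin(t) * dx + np.cos(t) * dy
    d = (w1 * np.abs(dx) ** r + (1 - w1) * np.abs(dy) ** r) ** (1 / r)
    return SimilarityField(reference=np.zeros(2), dims=(0, 1), xs=xs, ys=xs,
                           values=np.exp(-decay * d))


class TestMinkowskiFit:
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_exponent_recovery(self, r):
        fit = fit_minkowski(forward_field(r))
        assert fit.r == pytest.approx(r, abs=0.1)

    def test_weight_recovery(self):
        fit = fit_minkowski(forward_field(1.0, w1=0.7))
        assert fit.weights[0] == pytest.approx(0.7, abs=0.1)

    def test_rotation_recovery(self):
        fit = fit_minkowski(forward_field(1.0, theta_deg=45.0), fit_rotation=True)
        assert fit.angle_deg == pytest.approx(45.0, abs=8.0)
        assert fit.r == pytest.approx(1.0, abs=0.15)

    def test_flat_field_rejected(self):
        fld = forward_field(2.0)
        fld.values = np.ones_like(fld.values)
        with pytest.raises(ValueError):
            fit_minkowski(fld)


class TestTriangleDiagnostics:
    @pytest.mark.parametrize("r", [1.0, 1.5, 2.0])
    def test_metric_fields_have_no_witnesses(self, r):
        rep = convexity_and_triangle_check(forward_field(r), level=0.2)
        assert rep["n_witnesses"] == 0

    def test_submetric_field_has_witnesses(self):
        rep = convexity_and_triangle_check(forward_field(0.5), level=0.2)
        assert rep["n_witnesses"] > 0

    def test_euclidean_contour_convex(self):
        rep = convexity_and_triangle_check(forward_field(2.0, decay=2.0), level=0.3)
        assert rep["contour_convex"] is True


class TestDprime:
    def test_textbook_rates(self):
        # hit 0.84, false alarm 0.16 -> d' close to 2
        sims = np.array([0.16] * 50 + [0.84] * 50)
        is_diff = np.array([True] * 50 + [False] * 50)
        val = dprime(sims, is_diff, n_clip=10_000)
        assert val == pytest.approx(1.9884, abs=1e-3)

    def test_equal_rates_zero(self):
        sims = np.array([0.5, 0.5, 0.5, 0.5])
        val = dprime(sims, np.array([True, True, False, False]))
        assert val == 0.0

    def test_perfect_separation_clipped_finite(self):
        sims = np.concatenate([np.zeros(20), np.ones(20)])
        is_diff = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        val = dprime(sims, is_diff)
        assert np.isfinite(val) and val > 3

    def test_swapping_roles_flips_sign(self):
        sims = np.array([0.2] * 10 + [0.7] * 10)
        is_diff = np.array([True] * 10 + [False] * 10)
        assert dprime(sims, is_diff) == pytest.approx(-dprime(sims, ~is_diff))

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            dprime(np.array([0.5, 0.6]), np.array([True, True]))


class TestSimilarityEvaluation:
    def test_self_similarity_is_one(self, hyper2, cset_nw_wn):
        x = np.array([0.3, 0.1])
        s = similarity(x, x, cset_nw_wn, hyper2)
        assert s == pytest.approx(1.0)

    def test_trained_components_align_field(self, hyper2):
        """Two singly narrow components produce an axis-aligned field:
        similarity decays more slowly along the axes than diagonally."""
        cset = build_component_set(("nw", "wn"), (1.0, 1.0))
        fld = iso_similarity_field(cset, hyper2, reference=np.zeros(2),
                                   extent=1.5, n_grid=21)
        c = 10
        axis = 0.5 * (fld.values[c, c + 6] + fld.values[c + 6, c])
        diag = fld.values[c + 4, c + 4]   # comparable Euclidean radius
        assert axis > diag

    def test_field_values_in_unit_interval(self, hyper2, cset_nw_wn):
        fld = iso_similarity_field(cset_nw_wn, hyper2, reference=np.zeros(2),
                                   extent=2.0, n_grid=15)
        assert fld.values.min() >= 0.0 and fld.values.max() <= 1.0 + 1e-12

    def test_hand_computed_mixture_value(self):
        """One fixed component: the similarity is the predictive ratio of
        the cluster seeded at the reference, computed by hand."""
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 0.0),
                                sigma_r2=0.5, omega=np.zeros(2))
        sig = np.diag([0.4, 0.4])
        x = np.zeros(2)
        t = np.array([0.6, 0.0])
        v = 1.0 / (1.0 / 0.5 + 1.0 / 0.4)
        pred_cov = 0.4 + v
        # posterior mean of the cluster seeded at x = omega = 0 stays at 0
        want_fwd = np.exp(-0.5 * (0.6**2) / pred_cov)
        got = similarity(t, x, np.array([[0.4, 0.4]]), hyper, symmetrize=False)
        assert got == pytest.approx(want_fwd, rel=1e-6)


class TestLearningCurve:
    def test_first_trial_at_chance_and_ci_scaling(self, hyper2):
        st = biconditional_structure(n_blocks=2)
        cset = build_component_set(("nw", "wn"), (1.3, 1.3))
        hyper = Hyperparameters(dim=2, crp=CRPParams(10.0, 0.001, 0.0),
                                sigma_r2=0.1,
                                omega=st.stimuli[:, [0, 2]].mean(axis=0))
        from dataclasses import replace

        st2 = replace(st, stimuli=st.stimuli[:, [0, 2]], dims=("a", "b"))
        small = learning_curve(st2, cset, hyper, n_learners=8, seed=0)
        big = learning_curve(st2, cset, hyper, n_learners=32, seed=0)
        # quadrupling the learners shrinks the Monte-Carlo error
        assert big["block_sem"][1] < small["block_sem"][1]
        # the very first trial is at chance before any feedback
        from refreshcat.inference import ParticleFilterConfig, TrainedParticleFilter

        pf = TrainedParticleFilter(cset, hyper, n_labels=2,
                                   cfg=ParticleFilterConfig(20, seed=0))
        first = pf.step(st2.stimuli[0], int(st2.labels[0]))
        np.testing.assert_allclose(first, [0.5, 0.5])
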