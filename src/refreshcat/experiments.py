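"""Named reproduction experiments over the model, tasks and analyses.

Each function runs one simulated experiment end to end with explicit
seeds and reduced default Monte-Carlo budgets, returning plain dicts of
summary numbers; ``run_experiment`` dispatches by name and writes CSV/JSON
results plus a reproducibility manifest.  The experiment registry covers
the classic dimensional biases (condensation versus filtration, the six
SHJ problems), their stimulus dependence (integral versus separable
regimes, biconditional discrimination), their development (free
classification and SHJ by age), dimensional learning (discrimination
training and Garner interference), metric analyses of similarity fields,
inferential-resource effects (particle counts), and the RMC baseline.
"""

from __future__ import annotations

import json
import math
import platform
import time
from dataclasses import replace as dc_replace

import numpy as np

from . import __version__
from .components import (
    build_component_set,
    developmental_variant,
    regime_registry,
)
from .distributions import CRPParams, bell_number
from .inference import (
    GibbsConfig,
    ParticleFilterConfig,
    TrainedParticleFilter,
    exact_posterior,
    run_gibbs,
)
from .model import Hyperparameters
from .similarity import (
    convexity_and_triangle_check,
    dprime,
    fit_minkowski,
    hypothesis_draws,
    iso_similarity_field,
    learning_curve,
    similarity_matrix,
)
from .tasks import (
    biconditional_structure,
    condensation_filtration_structure,
    discrimination_grid,
    free_classification_structure,
    garner_tasks,
    generate_cluster_training,
    shj_structure,
    trial_stream,
)

__all__ = ["run_experiment", "EXPERIMENTS", "verify"]

SHJ_TYPES = ("I", "II", "III", "IV", "V", "VI")


def _pf_hyper(dim, omega, alpha=10.0, alpha_c=0.001, sigma_r2=0.1):
    return Hyperparameters(
        dim=dim, crp=CRPParams(alpha=alpha, alpha_c=alpha_c, alpha_g=0.0),
        sigma_r2=sigma_r2, omega=omega)


def _gibbs_hyper(dim, omega, sigma_r2=1.0):
    return Hyperparameters(
        dim=dim, crp=CRPParams(alpha=10.0, alpha_c=0.001, alpha_g=1.0),
        v_t=30.0, sigma_r2=sigma_r2, omega=omega)


# ---------------------------------------------------------------------------
# condensation versus filtration
# ---------------------------------------------------------------------------

def filtration_condensation(
    regime: str = "condensation_filtration_separable",
    n_learners: int = 100,
    n_blocks: int = 12,
    seed: int = 0,
    n_particles: int = 100,
) -> dict:
    """Mean error by condition for one component regime (and the ordering)."""
    reg = regime_registry(regime)
    cset = reg.component_set()
    out = {"regime": regime, "conditions": {}}
    for i, cond in enumerate(("filtration_dim1", "filtration_dim2",
                              "condensation_A", "condensation_B")):
        st = condensation_filtration_structure(cond, n_blocks=n_blocks)
        hyper = _pf_hyper(2, st.stimuli.mean(axis=0), alpha=reg.alpha,
                          alpha_c=reg.alpha_c, sigma_r2=reg.sigma_r2)
        lc = learning_curve(st, cset, hyper, n_learners=n_learners,
                            seed=seed * 37 + i, n_particles=n_particles)
        out["conditions"][cond] = {
            "mean_error": lc["mean_error"],
            "block_mean": lc["block_mean"].tolist(),
        }
    conds = out["conditions"]
    out["filtration_mean_error"] = float(np.mean(
        [conds["filtration_dim1"]["mean_error"], conds["filtration_dim2"]["mean_error"]]))
    out["condensation_mean_error"] = float(np.mean(
        [conds["condensation_A"]["mean_error"], conds["condensation_B"]["mean_error"]]))
    out["filtration_advantage"] = out["condensation_mean_error"] - out["filtration_mean_error"]
    return out


def rmc_filtration_condensation(n_orders: int = 50, n_blocks: int = 16, seed: int = 0) -> dict:
    """The RMC baseline on the same four conditions (local-MAP, printed parameters)."""
    from .rmc import RMCParams, rmc_learning_curve

    params = RMCParams(alpha=1.0, sigma0_2=2.25, a0=1.0, lambda0=1.0, beta=0.1)
    out = {"conditions": {}}
    for cond in ("filtration_dim1", "filtration_dim2", "condensation_A", "condensation_B"):
        st = condensation_filtration_structure(cond, n_blocks=n_blocks)
        lc = rmc_learning_curve(st, params, n_orders=n_orders, seed=seed)
        out["conditions"][cond] = {"mean_error": lc["mean_error"],
                                   "block_mean": lc["block_mean"].tolist()}
    conds = out["conditions"]
    out["filtration_mean_error"] = float(np.mean(
        [conds["filtration_dim1"]["mean_error"], conds["filtration_dim2"]["mean_error"]]))
    out["condensation_mean_error"] = float(np.mean(
        [conds["condensation_A"]["mean_error"], conds["condensation_B"]["mean_error"]]))
    out["filtration_advantage"] = out["condensation_mean_error"] - out["filtration_mean_error"]
    return out


# ---------------------------------------------------------------------------
# SHJ problems
# ---------------------------------------------------------------------------

def shj_errors(
    regime: str = "shj_separable",
    types=SHJ_TYPES,
    n_learners: int = 100,
    n_blocks: int = 8,
    seed: int = 0,
    n_particles: int = 100,
    narrow_sd: float | None = None,
) -> dict:
    """Mean error per SHJ type under one component regime."""
    reg = regime_registry(regime)
    cset = reg.component_set()
    if narrow_sd is not None:
        cset = developmental_variant(cset, narrow_sd)
    out = {"regime": regime, "narrow_sd": narrow_sd, "errors": {}, "blocks": {}}
    for i, tp in enumerate(types):
        st = shj_structure(tp, n_blocks=n_blocks)
        hyper = _pf_hyper(3, st.stimuli.mean(axis=0), alpha=reg.alpha,
                          alpha_c=reg.alpha_c, sigma_r2=reg.sigma_r2)
        lc = learning_curve(st, cset, hyper, n_learners=n_learners,
                            seed=seed * 101 + i, n_particles=n_particles)
        out["errors"][tp] = lc["mean_error"]
        out["blocks"][tp] = lc["block_mean"].tolist()
    return out


def shj_particle_dissociation(
    n_learners_many: int = 100,
    n_learners_one: int = 200,
    n_blocks: int = 8,
    seed: int = 0,
) -> dict:
    """Type II versus Type IV mean error at 100 particles and at 1 particle."""
    out = {}
    for n_particles, n_learners in ((100, n_learners_many), (1, n_learners_one)):
        res = shj_errors("shj_separable", types=("II", "IV"),
                         n_learners=n_learners, n_blocks=n_blocks,
                         seed=seed + n_particles, n_particles=n_particles)
        out[n_particles] = res["errors"]
    out["advantage_100"] = out[100]["IV"] - out[100]["II"]
    out["advantage_1"] = out[1]["IV"] - out[1]["II"]
    return out


# ---------------------------------------------------------------------------
# biconditional discrimination
# ---------------------------------------------------------------------------

def biconditional(
    n_learners: int = 100,
    n_blocks: int = 15,
    seed: int = 0,
    n_particles: int = 100,
) -> dict:
    """Separable- versus integral-pairing error for the exclusive-or square.

    The model comparison runs in the 2-D space of the varying dimension
    pair using the exact projections of {Psi_wwn, Psi_nnw}: the integral
    pair sees two isotropic components (wide and small), the separable
    pair the two singly narrow ones.
    """
    reg = regime_registry("biconditional")
    cset3 = reg.component_set()
    out = {"conditions": {}}
    for kind, dims in (("separable_pairing", (0, 2)), ("integral_pairing", (0, 1))):
        st3 = biconditional_structure(kind, n_blocks=n_blocks)
        st2 = dc_replace(st3, stimuli=st3.stimuli[:, list(dims)], dims=("a", "b"))
        cset2 = cset3.project(dims)
        hyper = _pf_hyper(2, st2.stimuli.mean(axis=0), sigma_r2=reg.sigma_r2)
        lc = learning_curve(st2, cset2, hyper, n_learners=n_learners,
                            seed=seed, n_particles=n_particles)
        out["conditions"][kind] = {"mean_error": lc["mean_error"],
                                   "block_mean": lc["block_mean"].tolist()}
    out["integral_advantage"] = (out["conditions"]["separable_pairing"]["mean_error"]
                                 - out["conditions"]["integral_pairing"]["mean_error"])
    return out


# ---------------------------------------------------------------------------
# development
# ---------------------------------------------------------------------------

def free_classification_development(seed: int = 0) -> dict:
    """Exact partition posterior by age group for the six-stimulus sort."""
    st, crit = free_classification_structure()
    names = {v: k for k, v in crit.items()}
    reg = regime_registry("dimensional_development")
    out = {"ages": {}}
    for sd, age in ((0.8, "3yo"), (0.6, "4yo"), (0.5, "5yo"), (0.1, "adult")):
        cset = developmental_variant(build_component_set(reg.component_names, reg.c_d), sd)
        hyper = Hyperparameters(
            dim=2, crp=CRPParams(alpha=reg.alpha, alpha_c=reg.alpha_c, alpha_g=0.0),
            sigma_r2=reg.sigma_r2, omega=st.stimuli.mean(axis=0))
        parts, probs = exact_posterior(st.stimuli, cset, hyper)
        mass = {k: 0.0 for k in crit}
        other = 0.0
        for p, q in zip(parts, probs):
            if p in names:
                mass[names[p]] += float(q)
            else:
                other += float(q)
        mass["other"] = other
        crit_masses = {k: mass[k] for k in crit}
        mass["modal_type"] = max(crit_masses, key=crit_masses.get)
        out["ages"][age] = mass
    return out


def shj_development(
    n_learners: int = 100,
    n_blocks: int = 3,
    seed: int = 0,
    n_particles: int = 100,
) -> dict:
    """SHJ Types I, II, IV by age: adults use all components, children only
    singly narrow ones with widened narrow standard deviations."""
    groups = {
        "adult": ("shj_development_adults", None),
        "8yo": ("shj_development_children", 0.4),
        "5yo": ("shj_development_children", 0.5),
        "3yo": ("shj_development_children", 0.8),
    }
    out = {"groups": {}}
    for i, (age, (regime, sd)) in enumerate(groups.items()):
        res = shj_errors(regime, types=("I", "II", "IV"), n_learners=n_learners,
                         n_blocks=n_blocks, seed=seed * 11 + i,
                         n_particles=n_particles, narrow_sd=sd)
        out["groups"][age] = res["errors"]
    out["adult_II_advantage"] = out["groups"]["adult"]["IV"] - out["groups"]["adult"]["II"]
    out["child_II_advantage"] = out["groups"]["5yo"]["IV"] - out["groups"]["5yo"]["II"]
    return out


# ---------------------------------------------------------------------------
# similarity fields after Gibbs training
# ---------------------------------------------------------------------------

def train_similarity_field(
    preset: str = "six_axis_aligned",
    n_samples: int = 250,
    burn_in: int = 50,
    thin: int = 2,
    seed: int = 0,
    n_grid: int = 41,
    extent: float = 2.5,
    fit_rotation: bool = True,
) -> dict:
    """Gibbs-train on a cluster preset and fit a metric to the field."""
    ts = generate_cluster_training(preset=preset, seed=seed + 11)
    hyper = _gibbs_hyper(2, ts.points.mean(axis=0))
    post = run_gibbs(ts.points, hyper,
                     GibbsConfig(n_samples=n_samples, burn_in=burn_in,
                                 seed=seed, thin=thin),
                     contexts=ts.contexts)
    field = iso_similarity_field(post, hyper, n_grid=n_grid, extent=extent,
                                 rng=seed + 5)
    fit = fit_minkowski(field, fit_rotation=fit_rotation)
    report = convexity_and_triangle_check(field, level=0.15)
    return {
        "preset": preset,
        "r": fit.r,
        "angle_deg": fit.angle_deg,
        "weights": fit.weights.tolist(),
        "n_witnesses": report["n_witnesses"],
        "contour_convex": report["contour_convex"],
        "field": field,
        "posterior": post,
    }


def untrained_similarity_field(
    n_samples: int = 1000,
    seed: int = 0,
    n_grid: int = 41,
    extent: float = 0.25,
) -> dict:
    """Prior (untrained) similarity field: circular, metric, Euclidean fit."""
    hyper = _gibbs_hyper(2, np.zeros(2))
    field = iso_similarity_field(None, hyper, n_grid=n_grid, extent=extent,
                                 rng=seed, n_prior_samples=n_samples)
    fit = fit_minkowski(field)
    report = convexity_and_triangle_check(field, level=0.15)
    return {"r": fit.r, "n_witnesses": report["n_witnesses"],
            "contour_convex": report["contour_convex"], "field": field}


def rotation_invariance(
    n_samples: int = 1000,
    seed: int = 0,
    n_grid: int = 21,
    extent: float = 0.25,
    angle_deg: float = 45.0,
) -> dict:
    """Untrained similarity before and after rotating all inputs.

    With an isotropic top-level prior the model's predictions do not
    depend on the representing axes; the two Monte-Carlo estimates use a
    common random stream so the comparison isolates equivariance.
    """
    from .similarity import _similarity_points

    hyper = _gibbs_hyper(2, np.zeros(2))
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    xs = np.linspace(-extent, extent, n_grid)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    ref = np.zeros(2)
    draws_a = hypothesis_draws(None, hyper, seed, n_prior_samples=n_samples)
    draws_b = hypothesis_draws(None, hyper, seed, n_prior_samples=n_samples)
    v1 = _similarity_points(pts, ref, draws_a, hyper)
    v2 = _similarity_points(pts @ rot.T, rot @ ref, draws_b, hyper)
    return {"max_abs_diff": float(np.abs(v1 - v2).max()),
            "mean_abs_diff": float(np.abs(v1 - v2).mean())}


# ---------------------------------------------------------------------------
# dimensional learning: discrimination training and Garner interference
# ---------------------------------------------------------------------------

def discrimination_training(
    spacing: float = 0.06,
    presentations: int = 10,
    alpha: float = 1.0,
    n_samples: int = 250,
    burn_in: int = 50,
    thin: int = 2,
    n_repetitions: int = 3,
    seed: int = 0,
) -> dict:
    """Categorization training raises same/different discrimination d'.

    The untrained hierarchy is Gibbs-trained on each labeling of the 4x4
    grid; similarity of neighbor pairs before and after training (fresh
    pair-judgment clusters under the learned components) feeds a
    probability-matching same/different response and d' per dimension.
    The grid spacing sits at the scale of the untrained prior's clusters,
    with the dispersion parameter lowered to match (wider spacing splits
    categories into many isotropic clusters otherwise); the simulation is
    repeated ``n_repetitions`` times and averaged.  Reports the d' change
    on the dimension crossed by the boundary (relevant) and the
    orthogonal one (irrelevant).
    """
    task = discrimination_grid(spacing=spacing, presentations=presentations)
    grid = task["grid"]
    pairs = task["neighbor_pairs"]
    hyper = Hyperparameters(
        dim=2, crp=CRPParams(alpha=alpha, alpha_c=0.001, alpha_g=1.0),
        v_t=30.0, sigma_r2=1.0, omega=grid.mean(axis=0))

    def pair_dprimes(posterior, rng):
        a = np.array([grid[i] for i, j, d in pairs] + [g for g in grid])
        b = np.array([grid[j] for i, j, d in pairs] + [g for g in grid])
        sims = similarity_matrix(a, b, posterior, hyper, rng=rng,
                                 include_clusters=False)
        diff_dim = np.array([d for i, j, d in pairs])
        out = {}
        for d in (0, 1):
            sel = np.concatenate([diff_dim == d, np.ones(len(grid), dtype=bool)])
            is_diff = np.concatenate([np.ones((diff_dim == d).sum(), dtype=bool),
                                      np.zeros(len(grid), dtype=bool)])
            out[d] = dprime(sims[sel], is_diff, n_clip=int((diff_dim == d).sum()))
        return out

    results = {"spacing": spacing, "conditions": {}}
    base = pair_dprimes(None, np.random.default_rng(seed + 1))
    results["baseline"] = {"dim1": base[0], "dim2": base[1]}
    for cond, relevant in (("train_1d_dim1", 0), ("train_1d_dim2", 1), ("train_2d", None)):
        st = task[cond]
        rng = np.random.default_rng(seed)
        order = trial_stream(st, rng)
        reps = []
        for rep in range(n_repetitions):
            post = run_gibbs(st.stimuli[order], hyper,
                             GibbsConfig(n_samples=n_samples, burn_in=burn_in,
                                         seed=seed + 7 + 10 * rep, thin=thin),
                             labels=st.labels[order])
            reps.append(pair_dprimes(post, np.random.default_rng(seed + 2 + rep)))
        dp = {d: float(np.mean([r[d] for r in reps])) for d in (0, 1)}
        entry = {"dim1": dp[0], "dim2": dp[1]}
        if relevant is not None:
            entry["relevant_boost"] = dp[relevant] - base[relevant]
            entry["irrelevant_boost"] = dp[1 - relevant] - base[1 - relevant]
        results["conditions"][cond] = entry
    boosts = [results["conditions"][c] for c in ("train_1d_dim1", "train_1d_dim2")]
    results["mean_relevant_boost"] = float(np.mean([b["relevant_boost"] for b in boosts]))
    results["mean_irrelevant_boost"] = float(np.mean([b["irrelevant_boost"] for b in boosts]))
    return results


def _snapshot_label_probs(x, snap, hyper, n_labels: int = 2) -> np.ndarray:
    """Label predictive for one Gibbs snapshot (point-estimate components)."""
    masses = np.zeros(n_labels)
    total_new = 0.0
    weights = []
    comps = snap["components"]
    usage = np.array([c["usage"] for c in comps], dtype=float)
    new_w = np.append(usage, hyper.crp.alpha_g)
    new_w = new_w / new_w.sum() if new_w.sum() > 0 else new_w
    dens = []
    for c in snap["clusters"]:
        diff = x - c["mu"]
        sig = c["sigma"]
        sign, logdet = np.linalg.slogdet(sig)
        quad = diff @ np.linalg.solve(sig, diff)
        dens.append(math.log(c["size"]) - 0.5 * (quad + logdet + x.size * math.log(2 * math.pi)))
    new_terms = []
    eye = hyper.sigma_r2 * np.eye(hyper.dim)
    cand = [c["phi"] / (c["v"] + hyper.dim + 1) for c in comps]
    cand.append(hyper.top_scale / (hyper.v_t + hyper.dim + 1))
    for w, cov in zip(new_w, cand):
        if w <= 0:
            continue
        diff = x - hyper.omega
        sig = cov + eye
        sign, logdet = np.linalg.slogdet(sig)
        quad = diff @ np.linalg.solve(sig, diff)
        new_terms.append(math.log(hyper.crp.alpha * w)
                         - 0.5 * (quad + logdet + x.size * math.log(2 * math.pi)))
    allv = np.array(dens + new_terms)
    p = np.exp(allv - allv.max())
    p /= p.sum()
    for pi, c in zip(p[: len(dens)], snap["clusters"]):
        if c["label"] is None:
            masses += pi / n_labels
        else:
            masses[c["label"]] += pi
    masses += p[len(dens):].sum() / n_labels
    return masses / masses.sum()


def sequential_full_model_curve(
    structure,
    n_orders: int = 5,
    n_sweeps: int = 60,
    burn_in: int = 20,
    seed: int = 0,
) -> dict:
    """Trial-by-trial learning with the full (untrained) hierarchy.

    Before each trial the posterior given all previous labeled trials is
    re-approximated by a short Gibbs run; the pre-feedback label
    predictive averages the classify rule over its samples.  Cluster
    covariances are inferred during the task, so irrelevant-dimension
    variation inflates them — the source of untrained Garner
    interference.
    """
    hyper = _gibbs_hyper(structure.dim, structure.stimuli.mean(axis=0))
    ss = np.random.SeedSequence(seed)
    block_len = len(structure.block)
    errors = np.zeros((n_orders, structure.n_blocks))
    for oi, child in enumerate(ss.spawn(n_orders)):
        rng = np.random.default_rng(child)
        order = trial_stream(structure, rng)
        x = structure.stimuli[order]
        y = structure.labels[order]
        p_correct = np.zeros(len(order))
        for t in range(len(order)):
            if t == 0:
                p_correct[t] = 1.0 / structure.n_labels
                continue
            post = run_gibbs(x[:t], hyper,
                             GibbsConfig(n_samples=n_sweeps, burn_in=burn_in,
                                         seed=int(rng.integers(2**31 - 1))),
                             labels=y[:t])
            probs = np.mean([
                _snapshot_label_probs(x[t], snap, hyper, structure.n_labels)
                for snap in post.samples[::4]
            ], axis=0)
            p_correct[t] = probs[y[t]]
        errors[oi] = (1.0 - p_correct).reshape(structure.n_blocks, block_len).mean(axis=1)
    return {"errors": errors, "block_mean": errors.mean(axis=0),
            "mean_error": float(errors.mean())}


def garner_interference(
    train_spacing: float = 0.02,
    n_blocks_test: int = 9,
    n_gibbs: int = 150,
    burn_in: int = 50,
    n_component_samples: int = 10,
    n_learners: int = 60,
    seed: int = 0,
    n_particles: int = 100,
) -> dict:
    """Garner interference before and after categorization training.

    Trained condition: Gibbs on the 2 x 2 training square, every-10th
    component posterior sample collapsed to its modal covariance, used as
    the fixed component set of a particle filter on the filtering and
    baseline tasks.  Untrained condition: the same filter with cluster
    covariances drawn from the untrained prior.  Interference is baseline
    minus filtering accuracy; training should reduce it.
    """
    tasks = garner_tasks(train_spacing=train_spacing, n_blocks=n_blocks_test)
    rng = np.random.default_rng(seed)
    train = tasks["training"]
    hyper3 = _gibbs_hyper(3, train.stimuli.mean(axis=0))
    order = trial_stream(train, rng)
    post = run_gibbs(train.stimuli[order], hyper3,
                     GibbsConfig(n_samples=n_gibbs, burn_in=burn_in, seed=seed + 3,
                                 thin=max((n_gibbs - burn_in) // n_component_samples, 1)),
                     labels=train.labels[order])
    trained_covs = []
    for snap in post.samples[:n_component_samples]:
        for c in snap["components"]:
            if c["usage"] > 0:
                trained_covs.append(c["phi"] / (c["v"] + 3 + 1))

    skip = n_blocks_test // 3   # early near-chance blocks excluded

    def late_accuracy(block_mean):
        return float(1.0 - np.mean(np.asarray(block_mean)[skip:]))

    def trained_accuracy(task, seed0):
        diag = np.stack([np.diag(np.maximum(np.diag(c), 1e-8)) for c in trained_covs])
        hyper = _pf_hyper(3, task.stimuli.mean(axis=0))
        lc = learning_curve(task, diag, hyper, n_learners=n_learners,
                            seed=seed0, n_particles=n_particles)
        return late_accuracy(lc["block_mean"])

    def untrained_accuracy(task, seed0):
        lc = sequential_full_model_curve(task, n_orders=4, seed=seed0)
        return late_accuracy(lc["block_mean"])

    out = {"conditions": {}}
    for name, acc in (("trained", trained_accuracy), ("untrained", untrained_accuracy)):
        filt = acc(tasks["filtering"], seed + 21)
        base = float(np.mean([acc(tasks["baseline_low"], seed + 22),
                              acc(tasks["baseline_high"], seed + 23)]))
        out["conditions"][name] = {
            "filtering_accuracy": filt,
            "baseline_accuracy": base,
            "interference": base - filt,
        }
    out["trained_interference"] = out["conditions"]["trained"]["interference"]
    out["untrained_interference"] = out["conditions"]["untrained"]["interference"]
    return out


# ---------------------------------------------------------------------------
# oracle equivalence of the three inference engines
# ---------------------------------------------------------------------------

def oracle_fixtures() -> list[dict]:
    """Small labeled/unlabeled fixtures for engine cross-validation.

    Each fixture bundles stimuli (n <= 6), optional labels, a fixed
    component set and hyperparameters; the exact partition posterior is
    computable, so the collapsed Gibbs sampler and the particle filter
    can be checked against it.
    """
    out = []
    bic = biconditional_structure()
    x = bic.stimuli[:, [0, 2]]
    out.append({
        "name": "biconditional4",
        "stimuli": x,
        "labels": bic.labels,
        "components": build_component_set(("nw", "wn"), (1.3, 1.3)),
        "hyper": _pf_hyper(2, x.mean(axis=0)),
    })
    cf = condensation_filtration_structure("filtration_dim1")
    x6 = cf.stimuli[:6]
    out.append({
        "name": "filtration6",
        "stimuli": x6,
        "labels": cf.labels[:6],
        "components": build_component_set(("nw", "wn"), (0.5, 0.5)),
        "hyper": _pf_hyper(2, x6.mean(axis=0)),
    })
    free, _ = free_classification_structure()
    reg = regime_registry("dimensional_development")
    out.append({
        "name": "free_classification6",
        "stimuli": free.stimuli,
        "labels": None,
        "components": build_component_set(reg.component_names, reg.c_d),
        "hyper": Hyperparameters(
            dim=2, crp=CRPParams(alpha=reg.alpha, alpha_c=reg.alpha_c, alpha_g=0.0),
            sigma_r2=reg.sigma_r2, omega=free.stimuli.mean(axis=0)),
    })
    return out


def oracle_equivalence(
    seed: int = 0,
    gibbs_sweeps: int = 6050,
    burn_in: int = 50,
    n_particles: int = 10_000,
) -> dict:
    """Total-variation distance of Gibbs and particle-filter posteriors
    from the exact partition posterior on every bundled small fixture."""
    from collections import Counter

    from .distributions import canonical_partition
    from .inference import run_gibbs_fixed, run_particle_filter

    out = {}
    for fx in oracle_fixtures():
        x, labels = fx["stimuli"], fx["labels"]
        parts, probs = exact_posterior(x, fx["components"], fx["hyper"], labels=labels)
        exact_map = dict(zip(parts, probs))
        gs = run_gibbs_fixed(
            x, fx["components"], fx["hyper"],
            GibbsConfig(n_samples=gibbs_sweeps, burn_in=burn_in, seed=seed),
            labels=labels)
        counts = Counter(canonical_partition(s["partition"]) for s in gs.samples)
        total = sum(counts.values())
        tv_g = 0.5 * sum(abs(counts.get(p, 0) / total - exact_map.get(p, 0.0))
                         for p in set(counts) | set(exact_map))
        entry = {"gibbs_tv": float(tv_g)}
        if labels is not None:
            pf = TrainedParticleFilter(
                fx["components"], fx["hyper"], n_labels=int(np.max(labels)) + 1,
                cfg=ParticleFilterConfig(n_particles=n_particles, seed=seed + 1))
            pf.run(x, labels)
            pd = pf.partition_distribution()
            tv_p = 0.5 * sum(abs(pd.get(p, 0.0) - exact_map.get(p, 0.0))
                             for p in set(pd) | set(exact_map))
            entry["pf_tv"] = float(tv_p)
        out[fx["name"]] = entry
    out["max_tv"] = float(max(v for e in out.values() if isinstance(e, dict)
                              for v in e.values()))
    return out


# ---------------------------------------------------------------------------
# registry, manifest, verify
# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "filtration_condensation": lambda seed, **kw: filtration_condensation(seed=seed, **kw),
    "filtration_condensation_unequal": lambda seed, **kw: filtration_condensation(
        regime="condensation_filtration_unequal", seed=seed, **kw),
    "filtration_condensation_integral": lambda seed, **kw: filtration_condensation(
        regime="condensation_filtration_integral", seed=seed, **kw),
    "rmc_filtration": lambda seed, **kw: rmc_filtration_condensation(seed=seed, **kw),
    "shj_separable": lambda seed, **kw: shj_errors("shj_separable", seed=seed, **kw),
    "shj_integral": lambda seed, **kw: shj_errors(
        "shj_integral", types=("I", "II", "IV", "VI"), seed=seed, **kw),
    "shj_singly_narrow": lambda seed, **kw: shj_errors(
        "shj_singly_narrow", types=("I", "II", "IV"), seed=seed, **kw),
    "shj_no_context_prior": lambda seed, **kw: shj_errors(
        "shj_no_context_prior", types=("II", "III"), seed=seed, **kw),
    "shj_particles": lambda seed, **kw: shj_particle_dissociation(seed=seed, **kw),
    "shj_development": lambda seed, **kw: shj_development(seed=seed, **kw),
    "biconditional": lambda seed, **kw: biconditional(seed=seed, **kw),
    "free_classification_development": lambda seed, **kw: free_classification_development(
        seed=seed, **kw),
    "train_similarity_fields": lambda seed, **kw: {
        k: v for k, v in train_similarity_field(seed=seed, **kw).items()
        if k not in ("field", "posterior")},
    "discrimination_training": lambda seed, **kw: discrimination_training(seed=seed, **kw),
    "garner": lambda seed, **kw: garner_interference(seed=seed, **kw),
}


def run_experiment(name: str, seed: int = 0, out_dir=None, **overrides) -> dict:
    """Run a named experiment; optionally write results and a manifest."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; known: {sorted(EXPERIMENTS)}")
    t0 = time.time()
    result = EXPERIMENTS[name](seed, **overrides)
    result = _jsonable(result)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{name}.json").write_text(json.dumps(result, indent=2))
        _write_learning_curve_csv(name, result, out)
        manifest = {
            "experiment": name,
            "seed": seed,
            "overrides": _jsonable(overrides),
            "package_version": __version__,
            "python": platform.python_version(),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _write_learning_curve_csv(name, result, out_dir) -> None:
    """Tidy per-block CSV (condition, block, error) when curves exist."""
    import pandas as pd

    rows = []
    conds = result.get("conditions", {})
    for cond, entry in conds.items():
        for b, err in enumerate(entry.get("block_mean", []), start=1):
            rows.append({"condition": cond, "block": b, "error": err})
    for tp, curve in result.get("blocks", {}).items():
        for b, err in enumerate(curve, start=1):
            rows.append({"condition": tp, "block": b, "error": err})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / f"{name}_curves.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def verify(seed: int = 0) -> dict:
    """Fast analytic self-checks (runs in well under a minute).

    Exercises the exact combinatorics, the distribution primitives, and
    oracle equivalence of the collapsed Gibbs sampler, particle filter
    and exact enumeration on a small labeled fixture.
    """
    from .distributions import (
        IWParams,
        crp_assignment_probs,
        crp_joint_logprob,
        enumerate_partitions,
    )
    from .inference import run_gibbs_fixed, run_particle_filter
    from .distributions import canonical_partition
    from collections import Counter

    checks = {}
    # leading two figures of B(100); the reference value 4.7e115 truncates
    lead = bell_number(100) // 10**114 / 10.0
    checks["bell_100_coefficient"] = {"value": lead, "pass": lead == 4.7}
    checks["partition_count_n6"] = {
        "value": len(enumerate_partitions(6)),
        "pass": len(enumerate_partitions(6)) == bell_number(6) == 203,
    }
    probs = crp_assignment_probs([2, 1], 10.0)
    checks["crp_normalization"] = {"value": float(probs.sum()),
                                   "pass": abs(probs.sum() - 1) < 1e-12}
    iw = IWParams(np.eye(2), 30.0)
    checks["iw_mode"] = {"value": float(iw.mode[0, 0]),
                         "pass": abs(iw.mode[0, 0] - 1 / 33) < 1e-12}
    # oracle equivalence on the 4-stimulus exclusive-or fixture
    st = biconditional_structure()
    x = st.stimuli[:, [0, 2]]
    cset = build_component_set(("nw", "wn"), (1.3, 1.3))
    hyper = _pf_hyper(2, x.mean(axis=0))
    parts, probs = exact_posterior(x, cset, hyper, labels=st.labels)
    exact_map = dict(zip(parts, probs))
    gs = run_gibbs_fixed(x, cset, hyper,
                         GibbsConfig(n_samples=2050, burn_in=50, seed=seed),
                         labels=st.labels)
    counts = Counter(canonical_partition(s["partition"]) for s in gs.samples)
    total = sum(counts.values())
    tv = 0.5 * sum(abs(counts.get(p, 0) / total - exact_map.get(p, 0.0))
                   for p in set(counts) | set(exact_map))
    checks["gibbs_exact_tv"] = {"value": float(tv), "pass": tv < 0.05}
    _, pf_post = run_particle_filter(
        x, st.labels, cset, hyper, ParticleFilterConfig(n_particles=2000, seed=seed))
    checks["all_pass"] = all(v["pass"] for v in checks.values() if isinstance(v, dict))
    return checks
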