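"""The original rational model of categorization with local-MAP assignment.

A Dirichlet-process mixture over items in which every cluster models each
stimulus dimension independently with a Gaussian whose mean and variance
carry a normal / scaled-inverse-chi-squared prior, and category labels are
binary features with a beta-binomial likelihood.  Anderson's approximation
commits each item to its single most probable cluster at the moment it is
observed, so the model is deterministic given a trial order and
order-sensitive across trial orders.  Depending on the dispersion
parameter the model interpolates between a prototype model (one cluster
per category) and an exemplar model (one cluster per item).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RMCParams", "rmc_cluster_predictive", "rmc_label_likelihood", "rmc_run"]


@dataclass(frozen=True)
class RMCParams:
    """Coupling and conjugate-prior parameters of the RMC."""

    alpha: float = 1.0
    sigma0_2: float = 2.25   # prior variance
    a0: float = 1.0          # confidence in the prior variance
    lambda0: float = 1.0     # confidence in the prior mean
    beta: float = 0.1        # label (binary feature) smoothing
    omega: np.ndarray | None = None   # per-dimension prior means

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma0_2", "a0", "lambda0", "beta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.omega is not None:
            object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))


def _dim_predictive_logpdf(x: float, n: int, mean: float, ssq: float,
                           params: RMCParams, omega_d: float) -> float:
    """Posterior-predictive log density along one dimension.

    Standard normal / scaled-inverse-chi-squared updates: with n member
    values of mean ``mean`` and sum of squared deviations ``ssq``, the
    predictive is a scaled, shifted Student t with a0 + n degrees of
    freedom.
    """
    lam_n = params.lambda0 + n
    a_n = params.a0 + n
    mu_n = (params.lambda0 * omega_d + n * mean) / lam_n
    scale_num = (params.a0 * params.sigma0_2 + ssq
                 + params.lambda0 * n / lam_n * (mean - omega_d) ** 2)
    sigma2_n = scale_num / a_n
    pred_var = sigma2_n * (1.0 + 1.0 / lam_n)
    return float(stats.t.logpdf(x, df=a_n, loc=mu_n, scale=math.sqrt(pred_var)))


def rmc_cluster_predictive(x: np.ndarray, members, params: RMCParams,
                           log: bool = True) -> float:
    """Predictive density of stimulus ``x`` under a cluster.

    Dimensions are independent; an empty cluster gives the prior
    predictive (a t density with a0 degrees of freedom per dimension).
    """
    x = np.asarray(x, dtype=float)
    omega = params.omega if params.omega is not None else np.zeros_like(x)
    out = 0.0
    members = np.atleast_2d(np.asarray(members, dtype=float)) if members is not None and len(members) else None
    for d in range(x.size):
        if members is None:
            out += _dim_predictive_logpdf(x[d], 0, 0.0, 0.0, params, omega[d])
        else:
            vals = members[:, d]
            out += _dim_predictive_logpdf(
                x[d], vals.size, float(vals.mean()),
                float(((vals - vals.mean()) ** 2).sum()), params, omega[d])
    return out if log else math.exp(out)


def rmc_label_likelihood(label_counts, label: int, beta: float) -> float:
    """Beta-binomial probability of a label within a cluster.

    (count of the label + beta) / (cluster size + L * beta) for L labels.
    """
    counts = np.asarray(label_counts, dtype=float)
    return float((counts[label] + beta) / (counts.sum() + counts.size * beta))


def rmc_run(stimuli, labels, params: RMCParams, n_labels: int = 2):
    """Local-MAP run over one ordered trial sequence.

    Before feedback the response distribution is the assignment-weighted
    sum of cluster label likelihoods (the label term is excluded from the
    assignment probabilities at response time); after feedback the item
    joins the single a-posteriori most likely cluster, with the observed
    label participating in that assignment.  Deterministic given the
    trial order; ties break to the lowest cluster index.

    Returns ``(label_probs, assignments)``.
    """
    x = np.atleast_2d(np.asarray(stimuli, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n = x.shape[0]
    params = RMCParams(**{**params.__dict__, "omega": (
        params.omega if params.omega is not None else x.mean(axis=0))})
    clusters: list[dict] = []
    probs = np.zeros((n, n_labels))
    assign = np.zeros(n, dtype=int)
    for t in range(n):
        xi = x[t]
        prior = np.array([len(c["members"]) for c in clusters] + [params.alpha], dtype=float)
        prior /= prior.sum()
        pred = np.array(
            [rmc_cluster_predictive(xi, np.array(c["members"]), params) for c in clusters]
            + [rmc_cluster_predictive(xi, None, params)]
        )
        # response: weighted sum of label likelihoods, label term excluded
        w = prior * np.exp(pred - pred.max())
        w /= w.sum()
        for lab in range(n_labels):
            lab_lik = np.array(
                [rmc_label_likelihood(c["label_counts"], lab, params.beta) for c in clusters]
                + [1.0 / n_labels]
            )
            probs[t, lab] = float(w @ lab_lik)
        probs[t] /= probs[t].sum()
        # learning: observed label joins the assignment likelihood
        y = labels[t]
        lab_lik_y = np.array(
            [rmc_label_likelihood(c["label_counts"], y, params.beta) for c in clusters]
            + [1.0 / n_labels]
        )
        score = np.log(prior) + pred + np.log(lab_lik_y)
        k = int(np.argmax(score))
        if k == len(clusters):
            clusters.append({"members": [xi], "label_counts": np.zeros(n_labels)})
        else:
            clusters[k]["members"].append(xi)
        clusters[k]["label_counts"][y] += 1
        assign[t] = k
    return probs, assign


def rmc_learning_curve(structure, params: RMCParams, n_orders: int = 50, seed: int = 0):
    """Mean per-block error over randomly ordered runs of a task fixture."""
    from .tasks import trial_stream

    ss = np.random.SeedSequence(seed)
    block_len = len(structure.block)
    errors = np.zeros((n_orders, structure.n_blocks))
    for i, child in enumerate(ss.spawn(n_orders)):
        rng = np.random.default_rng(child)
        order = trial_stream(structure, rng)
        probs, _ = rmc_run(structure.stimuli[order], structure.labels[order], params,
                           n_labels=structure.n_labels)
        p_corr = probs[np.arange(len(order)), structure.labels[order]]
        errors[i] = (1.0 - p_corr).reshape(structure.n_blocks, block_len).mean(axis=1)
    return {
        "errors": errors,
        "block_mean": errors.mean(axis=0),
        "mean_error": float(errors.mean()),
    }
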