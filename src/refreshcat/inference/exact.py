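"""Exact posteriors over partitions by exhaustive enumeration.

Feasible for small stimulus sets (n <= 8): every set partition is scored
by the CRP prior, summed over all cluster -> component assignments under
the two-level CRP (Dirichlet-multinomial closed form for a fixed finite
component set), with cluster means integrated out analytically under
fixed diagonal component covariances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import logsumexp

from ..distributions import (
    crp_joint_logprob,
    enumerate_partitions,
    hcrp_joint_logprob,
)

__all__ = ["exact_posterior", "exact_label_predictive", "block_marginal_loglik_diag"]

LOG2PI = math.log(2.0 * math.pi)


def _component_variances(components) -> np.ndarray:
    """(J, D) diagonal variances from a TrainedComponentSet or array-like."""
    if hasattr(components, "variances"):
        return components.variances()
    arr = np.asarray(components, dtype=float)
    if arr.ndim == 3:  # stack of diagonal matrices
        return np.stack([np.diag(m) for m in arr])
    return np.atleast_2d(arr)


def block_marginal_loglik_diag(points: np.ndarray, psi: np.ndarray, sigma_r2: float, omega: np.ndarray) -> float:
    """Marginal log likelihood of a cluster under a fixed diagonal covariance.

    Integrates the cluster mean out of prod_i N(x_i; mu, diag(psi)) under
    mu ~ N(omega, sigma_r2 I); factorizes over dimensions.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    m = x.shape[0]
    psi = np.asarray(psi, dtype=float)
    s = x.sum(axis=0)
    q = (x**2).sum(axis=0)
    prior_prec = 1.0 / sigma_r2
    post_prec = prior_prec + m / psi
    post_mean = (omega * prior_prec + s / psi) / post_prec
    # log of the Gaussian-integral normalizer, per dimension
    ll = (
        -0.5 * m * (LOG2PI + np.log(psi))
        - 0.5 * np.log(sigma_r2 * post_prec)
        - 0.5 * (q / psi + omega**2 * prior_prec - post_mean**2 * post_prec)
    )
    return float(ll.sum())


def _partition_blocks(assignment: tuple[int, ...]) -> list[list[int]]:
    k = max(assignment) + 1
    blocks: list[list[int]] = [[] for _ in range(k)]
    for i, a in enumerate(assignment):
        blocks[a].append(i)
    return blocks


def _label_consistent(blocks, labels) -> bool:
    for b in blocks:
        if len({labels[i] for i in b}) > 1:
            return False
    return True


def _sum_over_components(block_ll: np.ndarray, alpha_c: float) -> float:
    """log sum over all cluster -> component assignments.

    ``block_ll[k, j]`` is the marginal log likelihood of block k under
    component j; the prior over assignment vectors is the exchangeable
    two-level CRP closed form for J equally weighted fixed components.
    """
    k, j = block_ll.shape
    if j == 1:
        return float(block_ll[:, 0].sum() + hcrp_joint_logprob([0] * k, 1, alpha_c))
    combos = np.array(list(itertools.product(range(j), repeat=k)), dtype=int)
    lik = block_ll[np.arange(k), combos].sum(axis=1)
    prior = np.array([hcrp_joint_logprob(u, j, alpha_c) for u in combos])
    return float(logsumexp(lik + prior))


def exact_posterior(
    data,
    components,
    hyper,
    labels=None,
    cap: int = 8,
):
    """Exact posterior probability of every set partition of the stimuli.

    Returns ``(partitions, probs)``: the canonical restricted-growth
    strings and their normalized posterior probabilities.  When ``labels``
    are given, only label-pure partitions receive mass and each cluster
    contributes a uniform label base-rate factor.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[0]
    if n > cap:
        raise ValueError(
            f"n = {n} exceeds the exact-posterior cap ({cap}); "
            "use Gibbs sampling or the particle filter instead"
        )
    psi = _component_variances(components)
    crp = hyper.crp
    if crp.alpha_g != 0:
        raise ValueError("exact_posterior requires a fixed component set (alpha_g = 0)")
    n_labels = len(set(labels)) if labels is not None else 0
    parts = enumerate_partitions(n, cap=cap)
    logp = np.full(len(parts), -np.inf)
    for idx, part in enumerate(parts):
        blocks = _partition_blocks(part)
        if labels is not None and not _label_consistent(blocks, labels):
            continue
        lp = crp_joint_logprob(part, crp.alpha)
        if labels is not None:
            lp += -len(blocks) * math.log(n_labels)
        block_ll = np.empty((len(blocks), psi.shape[0]))
        for k, b in enumerate(blocks):
            for j in range(psi.shape[0]):
                block_ll[k, j] = block_marginal_loglik_diag(
                    x[b], psi[j], hyper.sigma_r2, hyper.omega
                )
        lp += _sum_over_components(block_ll, crp.alpha_c)
        logp[idx] = lp
    z = logsumexp(logp)
    return parts, np.exp(logp - z)


def exact_label_predictive(
    trials,
    labels,
    components,
    hyper,
    label_set=(0, 1),
    cap: int = 8,
):
    """Exact pre-feedback label probabilities for an ordered trial sequence.

    For each trial t, computes P(label_t | x_1..x_t, labels_1..t-1) by
    summing the joint evidence over all label-pure partitions with the
    candidate label attached to trial t.  The quantity is the one the
    particle filter approximates; feasible only for short sequences.
    """
    x = np.atleast_2d(np.asarray(trials, dtype=float))
    n = x.shape[0]
    out = np.zeros((n, len(label_set)))

    def log_evidence(xs, labs):
        parts, _ = None, None
        psi = _component_variances(components)
        m = xs.shape[0]
        lps = []
        for part in enumerate_partitions(m, cap=cap):
            blocks = _partition_blocks(part)
            if not _label_consistent(blocks, labs):
                continue
            lp = crp_joint_logprob(part, hyper.crp.alpha)
            lp += -len(blocks) * math.log(len(label_set))
            block_ll = np.empty((len(blocks), psi.shape[0]))
            for k, b in enumerate(blocks):
                for j in range(psi.shape[0]):
                    block_ll[k, j] = block_marginal_loglik_diag(
                        xs[b], psi[j], hyper.sigma_r2, hyper.omega
                    )
            lp += _sum_over_components(block_ll, hyper.crp.alpha_c)
            lps.append(lp)
        return logsumexp(lps)

    for t in range(n):
        evid = np.array([
            log_evidence(x[: t + 1], list(labels[:t]) + [cand])
            for cand in label_set
        ])
        out[t] = np.exp(evid - logsumexp(evid))
    return out
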