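"""Rao-Blackwellized particle filter for the trained approximation.

Each particle stores only the discrete structure — which cluster every
item belongs to and which fixed covariance component every cluster uses —
while cluster means are integrated out analytically (all components are
diagonal, so predictives factorize over dimensions).  Per trial the filter

1. reports the mixture predictive over category labels (the model's
   response, computed before feedback),
2. reveals the label and propagates every particle by the exact
   conditional posterior over (cluster, component) for the new item
   (the optimal proposal, feasible because components are fixed),
3. reweights by each particle's marginal predictive of the observation,
4. systematically resamples when the effective sample size falls below a
   threshold fraction of the particle count.

The particle count doubles as a working-memory-capacity analog: with many
particles the filter tracks the exact posterior; with one particle it
collapses to sequential sampling of a single clustering history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..distributions import canonical_partition

__all__ = ["ParticleFilterConfig", "TrainedParticleFilter", "run_particle_filter"]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ParticleFilterConfig:
    n_particles: int = 100
    resample_threshold: float = 0.5   # resample when ESS < threshold * n
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 <= self.resample_threshold <= 1:
            raise ValueError("resample_threshold is a fraction of n_particles")


def _component_variances(components) -> np.ndarray:
    if hasattr(components, "variances"):
        return components.variances()
    arr = np.asarray(components, dtype=float)
    if arr.ndim == 3:
        return np.stack([np.diag(m) for m in arr])
    return np.atleast_2d(arr)


class TrainedParticleFilter:
    """Vectorized particle filter over clusterings with fixed components."""

    def __init__(self, components, hyper, n_labels: int = 2,
                 cfg: ParticleFilterConfig = ParticleFilterConfig(),
                 track_assignments: bool = True):
        self.psi = _component_variances(components)       # (J, D) variances
        self.hyper = hyper
        self.J, self.D = self.psi.shape
        if hyper.dim != self.D:
            raise ValueError("component dimension does not match hyperparameters")
        if hyper.crp.alpha_g != 0:
            raise ValueError("the trained filter requires a fixed component set (alpha_g = 0)")
        self.n_labels = n_labels
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.track_assignments = track_assignments
        p, k0 = cfg.n_particles, 4
        self.P, self.K = p, k0
        self.active = np.zeros((p, k0), dtype=bool)
        self.m = np.zeros((p, k0))
        self.sumx = np.zeros((p, k0, self.D))
        self.comp = np.zeros((p, k0), dtype=int)
        self.lab = np.full((p, k0), -1, dtype=int)
        self.comp_counts = np.zeros((p, self.J))          # clusters per component
        self.logw = np.zeros(p)
        self.n_items = 0
        self.assignments: list[np.ndarray] = []           # per trial: (P,) cluster ids
        self.n_resamples = 0

    # -- internals ---------------------------------------------------------
    def _grow(self) -> None:
        grow = self.K
        for name in ("active", "m", "comp", "lab"):
            arr = getattr(self, name)
            pad = np.zeros((self.P, grow), dtype=arr.dtype)
            if name == "lab":
                pad -= 1
            setattr(self, name, np.concatenate([arr, pad], axis=1))
        self.sumx = np.concatenate(
            [self.sumx, np.zeros((self.P, grow, self.D))], axis=1)
        self.K += grow

    def _existing_loglik(self, x: np.ndarray) -> np.ndarray:
        """(P, K) log predictive of x under each active cluster."""
        psi_k = self.psi[self.comp]                        # (P, K, D)
        post_prec = 1.0 / self.hyper.sigma_r2 + self.m[..., None] / psi_k
        v = 1.0 / post_prec
        post_mean = v * (self.hyper.omega / self.hyper.sigma_r2 + self.sumx / psi_k)
        pred_var = psi_k + v
        ll = -0.5 * (np.log(2 * np.pi * pred_var) + (x - post_mean) ** 2 / pred_var).sum(axis=2)
        ll[~self.active] = -np.inf
        return ll

    def _new_loglik(self, x: np.ndarray) -> np.ndarray:
        """(J,) log prior predictive of x under a fresh cluster per component."""
        var = self.psi + self.hyper.sigma_r2               # (J, D)
        return -0.5 * (np.log(2 * np.pi * var) + (x - self.hyper.omega) ** 2 / var).sum(axis=1)

    def _log_priors(self):
        """CRP + component priors: (P, K) existing and (P, J) new-cluster."""
        alpha = self.hyper.crp.alpha
        alpha_c = self.hyper.crp.alpha_c
        denom = math.log(self.n_items + alpha)
        with np.errstate(divide="ignore"):
            lp_exist = np.where(self.active, np.log(np.maximum(self.m, 1e-300)), -np.inf) - denom
        nclus = self.comp_counts.sum(axis=1, keepdims=True)
        if math.isinf(alpha_c):
            comp_prior = np.full((self.P, self.J), 1.0 / self.J)
        else:
            comp_prior = (self.comp_counts + alpha_c / self.J) / (nclus + alpha_c)
        lp_new = math.log(alpha) + np.log(comp_prior) - denom
        return lp_exist, lp_new

    def _particle_weights(self) -> np.ndarray:
        w = self.logw - logsumexp(self.logw)
        return np.exp(w)

    # -- public API --------------------------------------------------------
    def label_probs(self, x: np.ndarray) -> np.ndarray:
        """Mixture predictive over labels for stimulus x (pre-feedback).

        Computes P(y | x, history) with the clustering conditioned on x as
        well: each particle contributes its unnormalized option masses
        (CRP prior times predictive, a common scale across particles), and
        label masses are normalized jointly under the particle weights.
        """
        x = np.asarray(x, dtype=float)
        lp_exist, lp_new = self._log_priors()
        ll = self._existing_loglik(x)
        ll0 = self._new_loglik(x)
        opts_exist = lp_exist + ll + self.logw[:, None]      # (P, K)
        opts_new = lp_new + ll0 + self.logw[:, None]         # (P, J)
        shift = max(opts_exist.max(initial=-np.inf), opts_new.max(initial=-np.inf))
        w_exist = np.exp(opts_exist - shift)
        w_exist[~self.active] = 0.0
        new_total = np.exp(opts_new - shift).sum()
        out = np.zeros(self.n_labels)
        for lab in range(self.n_labels):
            out[lab] = w_exist[self.lab == lab].sum()
        out += new_total / self.n_labels
        return out / out.sum()

    def step(self, x: np.ndarray, label: int) -> np.ndarray:
        """Report label probabilities for x, then observe (x, label)."""
        x = np.asarray(x, dtype=float)
        probs = self.label_probs(x)
        lp_exist, lp_new = self._log_priors()
        ll = self._existing_loglik(x)
        ll0 = self._new_loglik(x)
        opts_exist = np.where(self.lab == label, lp_exist + ll, -np.inf)
        opts_new = lp_new + ll0 - math.log(self.n_labels)
        big = np.concatenate([opts_exist, opts_new], axis=1)   # (P, K + J)
        marginal = logsumexp(big, axis=1)
        self.logw += marginal
        # sample the conditional posterior per particle (Gumbel-max trick)
        gumbel = self.rng.gumbel(size=big.shape)
        choice = np.argmax(np.where(np.isfinite(big), big + gumbel, -np.inf), axis=1)
        chose_new = choice >= self.K
        # existing-cluster updates
        rows = np.where(~chose_new)[0]
        ks = choice[rows]
        self.m[rows, ks] += 1.0
        self.sumx[rows, ks] += x
        assigned = np.empty(self.P, dtype=int)
        assigned[rows] = ks
        # new clusters
        rows_new = np.where(chose_new)[0]
        if rows_new.size:
            if self.active.all(axis=1).any():
                self._grow()
            slots = np.argmin(self.active[rows_new], axis=1)
            js = choice[rows_new] - (big.shape[1] - self.J)
            self.active[rows_new, slots] = True
            self.m[rows_new, slots] = 1.0
            self.sumx[rows_new, slots] = x
            self.comp[rows_new, slots] = js
            self.lab[rows_new, slots] = label
            self.comp_counts[rows_new, js] += 1.0
            assigned[rows_new] = slots
        if self.track_assignments:
            self.assignments.append(assigned)
        self.n_items += 1
        self._maybe_resample()
        return probs

    def _maybe_resample(self) -> None:
        w = self._particle_weights()
        ess = 1.0 / np.sum(w**2)
        if ess >= self.cfg.resample_threshold * self.P or self.P == 1:
            return
        # systematic resampling
        positions = (self.rng.random() + np.arange(self.P)) / self.P
        idx = np.searchsorted(np.cumsum(w), positions)
        idx = np.clip(idx, 0, self.P - 1)
        for name in ("active", "m", "sumx", "comp", "lab", "comp_counts"):
            setattr(self, name, getattr(self, name)[idx].copy())
        if self.track_assignments and self.assignments:
            self.assignments = [a[idx].copy() for a in self.assignments]
        self.logw = np.zeros(self.P)
        self.n_resamples += 1

    def run(self, stimuli, labels) -> np.ndarray:
        """Process an ordered trial sequence; returns (T, n_labels) probabilities."""
        stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
        out = np.zeros((stimuli.shape[0], self.n_labels))
        for t, (x, y) in enumerate(zip(stimuli, labels)):
            out[t] = self.step(x, int(y))
        return out

    def partition_distribution(self) -> dict[tuple, float]:
        """Weighted distribution over item partitions across particles."""
        if not self.track_assignments:
            raise ValueError("construct with track_assignments=True")
        w = self._particle_weights()
        z = np.stack(self.assignments, axis=1) if self.assignments else np.zeros((self.P, 0), int)
        out: dict[tuple, float] = {}
        for p in range(self.P):
            key = canonical_partition(z[p])
            out[key] = out.get(key, 0.0) + w[p]
        return out

    def snapshot(self) -> list[dict]:
        """Per-particle summaries (weights, cluster stats) for inspection."""
        w = self._particle_weights()
        out = []
        for p in range(self.P):
            ks = np.where(self.active[p])[0]
            out.append({
                "weight": float(w[p]),
                "clusters": [
                    {
                        "size": float(self.m[p, k]),
                        "sum": self.sumx[p, k].tolist(),
                        "component": int(self.comp[p, k]),
                        "label": int(self.lab[p, k]),
                    }
                    for k in ks
                ],
            })
        return out


def run_particle_filter(
    trials,
    labels,
    components,
    hyper,
    cfg: ParticleFilterConfig = ParticleFilterConfig(),
    n_labels: int | None = None,
):
    """Run the trained filter over an ordered labeled sequence.

    Returns ``(label_probs, sample_set)`` where ``label_probs[t]`` is the
    pre-feedback predictive distribution over labels at trial t and
    ``sample_set`` is a ``PosteriorSampleSet`` of per-particle summaries.
    """
    from . import PosteriorSampleSet

    labels = np.asarray(labels, dtype=int)
    n_labels = n_labels or int(labels.max()) + 1
    pf = TrainedParticleFilter(components, hyper, n_labels=n_labels, cfg=cfg)
    probs = pf.run(trials, labels)
    snaps = pf.snapshot()
    weights = np.array([s["weight"] for s in snaps])
    return probs, PosteriorSampleSet(snaps, weights / weights.sum())
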