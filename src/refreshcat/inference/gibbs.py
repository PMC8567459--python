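"""Gibbs samplers for the clustering hierarchy.

``run_gibbs`` samples the full untrained hierarchy — item partitions,
instantiated cluster means and covariances, cluster -> component
assignments, and component parameters (Phi_j, v_j) — using an
auxiliary-parameter scheme for the non-conjugate new-cluster moves
(fresh candidate clusters and components are drawn from the prior) and
Metropolis-Hastings updates for the component parameters.

``run_gibbs_fixed`` is the collapsed sampler for the trained
approximation: components are a fixed finite set of diagonal covariance
matrices and cluster means are integrated out, so the state is just
(z, u).  It targets the same distribution as ``exact_posterior`` and is
used for oracle-equivalence checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from ..distributions import hcrp_component_probs, truncnorm_logpdf, truncnorm_sample

__all__ = ["GibbsConfig", "run_gibbs", "run_gibbs_fixed"]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GibbsConfig:
    n_samples: int = 1050
    burn_in: int = 50
    seed: int = 0
    n_aux: int = 3                 # auxiliary candidates for new clusters/components
    phi_proposal_dof: float = 60.0  # Wishart proposal concentration for Phi_j
    v_proposal_sd: float = 0.4      # random-walk scale on log(v_j - D)
    thin: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("require 0 <= burn_in < n_samples")
        if self.n_aux < 1:
            raise ValueError("n_aux must be >= 1")


# ---------------------------------------------------------------------------
# fast matrix-variate helpers (small D; avoids per-call scipy overhead)
# ---------------------------------------------------------------------------

def _multigammaln(a: float, d: int) -> float:
    out = d * (d - 1) / 4.0 * math.log(math.pi)
    for i in range(d):
        out += gammaln(a - i / 2.0)
    return out


def _wishart_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """Bartlett-decomposition Wishart draw (mean df * scale)."""
    d = scale.shape[0]
    a = np.zeros((d, d))
    for i in range(d):
        a[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    l = np.linalg.cholesky(scale)
    la = l @ a
    return la @ la.T


def _wishart_logpdf(x: np.ndarray, df: float, scale: np.ndarray) -> float:
    d = x.shape[0]
    sign_x, logdet_x = np.linalg.slogdet(x)
    sign_s, logdet_s = np.linalg.slogdet(scale)
    tr = np.trace(np.linalg.solve(scale, x))
    return (
        0.5 * (df - d - 1) * logdet_x - 0.5 * tr
        - 0.5 * df * d * math.log(2.0) - 0.5 * df * logdet_s
        - _multigammaln(df / 2.0, d)
    )


def _iw_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    w = _wishart_rvs(df, np.linalg.inv(scale), rng)
    return np.linalg.inv(w)


def _iw_logpdf_fast(sig_logdet: float, sig_inv: np.ndarray, df: float,
                    phi: np.ndarray, phi_logdet: float) -> float:
    d = phi.shape[0]
    return (
        0.5 * df * phi_logdet - 0.5 * df * d * math.log(2.0)
        - _multigammaln(df / 2.0, d)
        - 0.5 * (df + d + 1) * sig_logdet
        - 0.5 * float(np.sum(phi * sig_inv))
    )


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, cov_inv: np.ndarray, logdet: float) -> float:
    diff = x - mean
    return -0.5 * (diff @ cov_inv @ diff + logdet + diff.size * LOG2PI)


# ---------------------------------------------------------------------------
# full hierarchy sampler
# ---------------------------------------------------------------------------

class _Cluster:
    __slots__ = ("members", "mu", "sigma", "sig_inv", "sig_logdet", "comp",
                 "label", "context")

    def __init__(self, members, mu, sigma, comp, label, context):
        self.members = set(members)
        self.mu = mu
        self.comp = comp
        self.label = label
        self.context = context
        self.set_sigma(sigma)

    def set_sigma(self, sigma: np.ndarray) -> None:
        self.sigma = sigma
        self.sig_inv = np.linalg.inv(sigma)
        self.sig_logdet = float(np.linalg.slogdet(sigma)[1])


class _Component:
    __slots__ = ("phi", "v", "phi_logdet")

    def __init__(self, phi, v):
        self.v = float(v)
        self.set_phi(phi)

    def set_phi(self, phi: np.ndarray) -> None:
        self.phi = phi
        self.phi_logdet = float(np.linalg.slogdet(phi)[1])


class _FullGibbs:
    def __init__(self, x, hyper, cfg, labels=None, contexts=None):
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.n, self.d = self.x.shape
        self.hyper = hyper
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.labels = None if labels is None else np.asarray(labels, dtype=int)
        self.contexts = (np.zeros(self.n, dtype=int) if contexts is None
                         else np.asarray(contexts, dtype=int))
        self.clusters: dict[int, _Cluster] = {}
        self.components: dict[int, _Component] = {}
        self.z = np.zeros(self.n, dtype=int)
        self._next_cluster = 0
        self._next_comp = 0
        self.accept = {"phi": 0, "phi_total": 0, "v": 0, "v_total": 0}
        self._init_state()

    # -- initialization: one cluster and one component per item ------------
    def _init_state(self) -> None:
        h = self.hyper
        for i in range(self.n):
            cid = self._next_comp
            self._next_comp += 1
            phi = _iw_rvs(h.v_t, h.top_scale, self.rng)
            v = float(truncnorm_sample(h.v_t, h.v_t, self.d, self.rng))
            self.components[cid] = _Component(phi, v)
            sigma = _iw_rvs(v, phi, self.rng)
            kid = self._next_cluster
            self._next_cluster += 1
            lab = None if self.labels is None else int(self.labels[i])
            self.clusters[kid] = _Cluster([i], self.x[i].copy(), sigma, cid,
                                          lab, int(self.contexts[i]))
            self.z[i] = kid

    # -- bookkeeping -------------------------------------------------------
    def _comp_usage(self, exclude_cluster=None):
        usage: dict[int, int] = {c: 0 for c in self.components}
        for kid, cl in self.clusters.items():
            if kid == exclude_cluster:
                continue
            usage[cl.comp] += 1
        return usage

    def _ctx_comp_counts(self, context, exclude_cluster=None):
        counts: dict[int, int] = {c: 0 for c in self.components}
        for kid, cl in self.clusters.items():
            if kid == exclude_cluster or cl.context != context:
                continue
            counts[cl.comp] += 1
        return counts

    def _component_prior_probs(self, context, exclude_cluster=None):
        """(comp ids, probabilities incl. trailing new-component slot)."""
        ids = sorted(self.components)
        counts = np.array([self._ctx_comp_counts(context, exclude_cluster).get(c, 0)
                           for c in ids], dtype=float)
        usage = np.array([self._comp_usage(exclude_cluster).get(c, 0)
                          for c in ids], dtype=float)
        probs = hcrp_component_probs(counts, usage, self.hyper.crp)
        return ids, probs

    def _draw_new_component(self):
        h = self.hyper
        phi = _iw_rvs(h.v_t, h.top_scale, self.rng)
        v = float(truncnorm_sample(h.v_t, h.v_t, self.d, self.rng))
        return _Component(phi, v)

    def _remove_item(self, i: int) -> None:
        kid = self.z[i]
        cl = self.clusters[kid]
        cl.members.discard(i)
        if not cl.members:
            comp = cl.comp
            del self.clusters[kid]
            if self._comp_usage().get(comp, 0) == 0:
                del self.components[comp]

    # -- sweep blocks ------------------------------------------------------
    def _update_z(self) -> None:
        h = self.hyper
        alpha = h.crp.alpha
        for i in range(self.n):
            self._remove_item(i)
            ctx = int(self.contexts[i])
            lab = None if self.labels is None else int(self.labels[i])
            cand_ids, logps = [], []
            for kid, cl in self.clusters.items():
                if cl.context != ctx:
                    continue
                if lab is not None and cl.label is not None and cl.label != lab:
                    continue
                logps.append(math.log(len(cl.members))
                             + _gauss_logpdf(self.x[i], cl.mu, cl.sig_inv, cl.sig_logdet))
                cand_ids.append(("old", kid))
            ids, comp_probs = self._component_prior_probs(ctx)
            # a fresh cluster draws its label uniformly from the label set
            label_lp = 0.0
            if self.labels is not None:
                label_lp = -math.log(int(self.labels.max()) + 1)
            for _ in range(self.cfg.n_aux):
                pick = self.rng.choice(len(comp_probs), p=comp_probs)
                if pick < len(ids):
                    comp_id, comp = ids[pick], self.components[ids[pick]]
                else:
                    comp_id, comp = None, self._draw_new_component()
                sigma = _iw_rvs(comp.v, comp.phi, self.rng)
                mu = h.omega + math.sqrt(h.sigma_r2) * self.rng.standard_normal(self.d)
                sig_inv = np.linalg.inv(sigma)
                sig_logdet = float(np.linalg.slogdet(sigma)[1])
                logps.append(math.log(alpha / self.cfg.n_aux) + label_lp
                             + _gauss_logpdf(self.x[i], mu, sig_inv, sig_logdet))
                cand_ids.append(("aux", (comp_id, comp, mu, sigma)))
            logps = np.asarray(logps)
            g = self.rng.gumbel(size=logps.size)
            pick = int(np.argmax(logps + g))
            kind, payload = cand_ids[pick]
            if kind == "old":
                self.clusters[payload].members.add(i)
                self.z[i] = payload
            else:
                comp_id, comp, mu, sigma = payload
                if comp_id is None:
                    comp_id = self._next_comp
                    self._next_comp += 1
                    self.components[comp_id] = comp
                kid = self._next_cluster
                self._next_cluster += 1
                self.clusters[kid] = _Cluster([i], mu, sigma, comp_id, lab, ctx)
                self.z[i] = kid

    def _update_cluster_params(self) -> None:
        h = self.hyper
        for cl in self.clusters.values():
            pts = self.x[sorted(cl.members)]
            m = pts.shape[0]
            comp = self.components[cl.comp]
            # mu | Sigma: conjugate Gaussian
            prec = np.eye(self.d) / h.sigma_r2 + m * cl.sig_inv
            cov = np.linalg.inv(prec)
            mean = cov @ (h.omega / h.sigma_r2 + cl.sig_inv @ pts.sum(axis=0))
            cl.mu = mean + np.linalg.cholesky(cov) @ self.rng.standard_normal(self.d)
            # Sigma | mu: conjugate inverse-Wishart
            diff = pts - cl.mu
            scatter = diff.T @ diff
            cl.set_sigma(_iw_rvs(comp.v + m, comp.phi + scatter, self.rng))

    def _update_u(self) -> None:
        for kid, cl in list(self.clusters.items()):
            ids, comp_probs = self._component_prior_probs(cl.context, exclude_cluster=kid)
            cands, logps = [], []
            for idx, comp_id in enumerate(ids):
                comp = self.components[comp_id]
                logps.append(math.log(max(comp_probs[idx], 1e-300))
                             + _iw_logpdf_fast(cl.sig_logdet, cl.sig_inv, comp.v,
                                               comp.phi, comp.phi_logdet))
                cands.append((comp_id, comp))
            new_mass = comp_probs[-1] if comp_probs.size > len(ids) else 0.0
            if new_mass > 0:
                for _ in range(self.cfg.n_aux):
                    comp = self._draw_new_component()
                    logps.append(math.log(new_mass / self.cfg.n_aux)
                                 + _iw_logpdf_fast(cl.sig_logdet, cl.sig_inv, comp.v,
                                                   comp.phi, comp.phi_logdet))
                    cands.append((None, comp))
            logps = np.asarray(logps)
            pick = int(np.argmax(logps + self.rng.gumbel(size=logps.size)))
            comp_id, comp = cands[pick]
            old_comp = cl.comp
            if comp_id is None:
                comp_id = self._next_comp
                self._next_comp += 1
                self.components[comp_id] = comp
            cl.comp = comp_id
            if self._comp_usage().get(old_comp, 0) == 0 and old_comp in self.components:
                del self.components[old_comp]

    def _component_loglik(self, comp_id: int, phi: np.ndarray, phi_logdet: float,
                          v: float) -> float:
        out = 0.0
        for cl in self.clusters.values():
            if cl.comp == comp_id:
                out += _iw_logpdf_fast(cl.sig_logdet, cl.sig_inv, v, phi, phi_logdet)
        return out

    def _update_components(self) -> None:
        h = self.hyper
        df = self.cfg.phi_proposal_dof
        top_logdet = float(np.linalg.slogdet(h.top_scale)[1])
        top_inv = np.linalg.inv(h.top_scale)
        for comp_id, comp in self.components.items():
            # Phi: Wishart random-walk proposal centered on the current value
            prop = _wishart_rvs(df, comp.phi / df, self.rng)
            prop_logdet = float(np.linalg.slogdet(prop)[1])

            def prior_lp(phi, phi_logdet):
                inv = np.linalg.inv(phi)
                return _iw_logpdf_fast(phi_logdet, inv, h.v_t, h.top_scale, top_logdet)

            cur_post = (prior_lp(comp.phi, comp.phi_logdet)
                        + self._component_loglik(comp_id, comp.phi, comp.phi_logdet, comp.v))
            new_post = (prior_lp(prop, prop_logdet)
                        + self._component_loglik(comp_id, prop, prop_logdet, comp.v))
            log_q_fwd = _wishart_logpdf(prop, df, comp.phi / df)
            log_q_rev = _wishart_logpdf(comp.phi, df, prop / df)
            self.accept["phi_total"] += 1
            if math.log(self.rng.random() + 1e-300) < new_post - cur_post + log_q_rev - log_q_fwd:
                comp.set_phi(prop)
                self.accept["phi"] += 1
            # v: Gaussian random walk on log(v - D), respecting truncation
            t_cur = math.log(comp.v - self.d) if comp.v > self.d else -20.0
            t_new = t_cur + self.cfg.v_proposal_sd * self.rng.standard_normal()
            v_new = self.d + math.exp(t_new)
            def v_post(v):
                return (float(truncnorm_logpdf(v, h.v_t, h.v_t, self.d))
                        + self._component_loglik(comp_id, comp.phi, comp.phi_logdet, v))
            cur = v_post(comp.v) + t_cur          # + log-Jacobian dv/dt = (v - D)
            new = v_post(v_new) + t_new
            self.accept["v_total"] += 1
            if math.log(self.rng.random() + 1e-300) < new - cur:
                comp.v = v_new
                self.accept["v"] += 1

    def data_loglik(self) -> float:
        out = 0.0
        for cl in self.clusters.values():
            for i in cl.members:
                out += _gauss_logpdf(self.x[i], cl.mu, cl.sig_inv, cl.sig_logdet)
        return out

    def snapshot(self) -> dict:
        comp_ids = sorted(self.components)
        remap = {c: j for j, c in enumerate(comp_ids)}
        usage = self._comp_usage()
        return {
            "components": [
                {"phi": self.components[c].phi.copy(),
                 "v": self.components[c].v,
                 "usage": usage.get(c, 0)}
                for c in comp_ids
            ],
            "clusters": [
                {"mu": cl.mu.copy(), "sigma": cl.sigma.copy(),
                 "component": remap[cl.comp], "label": cl.label,
                 "context": cl.context, "size": len(cl.members)}
                for cl in self.clusters.values()
            ],
            "partition": tuple(int(v) for v in self.z),
            "data_loglik": self.data_loglik(),
        }

    def sweep(self) -> None:
        self._update_z()
        self._update_cluster_params()
        self._update_u()
        self._update_components()


def run_gibbs(data, hyper, cfg: GibbsConfig = GibbsConfig(), labels=None, contexts=None):
    """Sample the full untrained hierarchy.

    Returns a ``PosteriorSampleSet`` whose samples are state dictionaries
    with keys ``components`` (phi, v, usage), ``clusters`` (mu, sigma,
    component, label, context, size), ``partition`` and ``data_loglik``.
    The chain is initialized with one cluster and one component per item
    and is fully reproducible from the config seed.
    """
    from . import PosteriorSampleSet

    sampler = _FullGibbs(data, hyper, cfg, labels=labels, contexts=contexts)
    samples = []
    for it in range(cfg.n_samples):
        sampler.sweep()
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            samples.append(sampler.snapshot())
    out = PosteriorSampleSet(samples)
    out.acceptance = {
        "phi": sampler.accept["phi"] / max(sampler.accept["phi_total"], 1),
        "v": sampler.accept["v"] / max(sampler.accept["v_total"], 1),
    }
    return out


# ---------------------------------------------------------------------------
# collapsed sampler with fixed diagonal components
# ---------------------------------------------------------------------------

def _stats_marginal_ll(m, s, q, psi, sigma_r2, omega):
    """Marginal log lik of a cluster from sufficient stats (diag covariance)."""
    prior_prec = 1.0 / sigma_r2
    post_prec = prior_prec + m / psi
    post_mean = (omega * prior_prec + s / psi) / post_prec
    ll = (
        -0.5 * m * (LOG2PI + np.log(psi))
        - 0.5 * np.log(sigma_r2 * post_prec)
        - 0.5 * (q / psi + omega**2 * prior_prec - post_mean**2 * post_prec)
    )
    return float(ll.sum())


def run_gibbs_fixed(
    data,
    components,
    hyper,
    cfg: GibbsConfig = GibbsConfig(),
    labels=None,
):
    """Collapsed Gibbs over (z, u) with a fixed diagonal component set.

    Cluster means are integrated out analytically; each sweep resamples
    every item's cluster and every cluster's component from their exact
    conditionals.  Samples are dictionaries with keys ``partition`` and
    ``u``.  Targets the same posterior as ``exact_posterior``.
    """
    from . import PosteriorSampleSet

    x = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = x.shape
    if hasattr(components, "variances"):
        psi = components.variances()
    else:
        psi = np.atleast_2d(np.asarray(components, dtype=float))
    j_total = psi.shape[0]
    crp = hyper.crp
    if crp.alpha_g != 0:
        raise ValueError("run_gibbs_fixed requires alpha_g = 0 (fixed component set)")
    labels = None if labels is None else np.asarray(labels, dtype=int)
    n_labels = 0 if labels is None else int(labels.max()) + 1
    rng = np.random.default_rng(cfg.seed)

    # state: z[i] -> cluster id; per cluster: members, m, s, q, comp, label
    z = np.arange(n)
    clus: dict[int, dict] = {}
    for i in range(n):
        clus[i] = {"members": {i}, "m": 1.0, "s": x[i].copy(), "q": x[i] ** 2,
                   "comp": int(rng.integers(j_total)),
                   "label": None if labels is None else int(labels[i])}
    next_id = n

    def comp_counts(exclude=None):
        counts = np.zeros(j_total)
        for kid, c in clus.items():
            if kid != exclude:
                counts[c["comp"]] += 1
        return counts

    def pred_ll(c, xi):
        ps = psi[c["comp"]]
        post_prec = 1.0 / hyper.sigma_r2 + c["m"] / ps
        post_mean = (hyper.omega / hyper.sigma_r2 + c["s"] / ps) / post_prec
        var = ps + 1.0 / post_prec
        return float(-0.5 * (np.log(2 * np.pi * var) + (xi - post_mean) ** 2 / var).sum())

    samples = []
    for it in range(cfg.n_samples):
        # -- z updates
        for i in range(n):
            kid = int(z[i])
            c = clus[kid]
            c["members"].discard(i)
            c["m"] -= 1.0
            c["s"] -= x[i]
            c["q"] -= x[i] ** 2
            if not c["members"]:
                del clus[kid]
            cands, logps = [], []
            for ck, c2 in clus.items():
                if labels is not None and c2["label"] != int(labels[i]):
                    continue
                logps.append(math.log(c2["m"]) + pred_ll(c2, x[i]))
                cands.append(("old", ck))
            counts = comp_counts()
            if math.isinf(crp.alpha_c):
                cprior = np.full(j_total, 1.0 / j_total)
            else:
                cprior = (counts + crp.alpha_c / j_total) / (counts.sum() + crp.alpha_c)
            # a fresh cluster also draws its label uniformly from the label set
            label_lp = -math.log(n_labels) if labels is not None else 0.0
            for j in range(j_total):
                ps = psi[j]
                var = ps + hyper.sigma_r2
                ll0 = float(-0.5 * (np.log(2 * np.pi * var)
                                    + (x[i] - hyper.omega) ** 2 / var).sum())
                logps.append(math.log(crp.alpha) + math.log(max(cprior[j], 1e-300))
                             + label_lp + ll0)
                cands.append(("new", j))
            logps = np.asarray(logps)
            pick = int(np.argmax(logps + rng.gumbel(size=logps.size)))
            kind, payload = cands[pick]
            if kind == "old":
                c2 = clus[payload]
                c2["members"].add(i)
                c2["m"] += 1.0
                c2["s"] += x[i]
                c2["q"] += x[i] ** 2
                z[i] = payload
            else:
                clus[next_id] = {
                    "members": {i}, "m": 1.0, "s": x[i].copy(), "q": x[i] ** 2,
                    "comp": payload,
                    "label": None if labels is None else int(labels[i]),
                }
                z[i] = next_id
                next_id += 1
        # -- u updates
        for kid, c in clus.items():
            counts = comp_counts(exclude=kid)
            if math.isinf(crp.alpha_c):
                cprior = np.full(j_total, 1.0 / j_total)
            else:
                cprior = (counts + crp.alpha_c / j_total) / (counts.sum() + crp.alpha_c)
            logps = np.array([
                math.log(max(cprior[j], 1e-300))
                + _stats_marginal_ll(c["m"], c["s"], c["q"], psi[j],
                                     hyper.sigma_r2, hyper.omega)
                for j in range(j_total)
            ])
            c["comp"] = int(np.argmax(logps + rng.gumbel(size=j_total)))
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            samples.append({
                "partition": tuple(int(v) for v in z),
                "u": tuple(clus[kid]["comp"] for kid in clus),
            })
    return PosteriorSampleSet(samples)
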