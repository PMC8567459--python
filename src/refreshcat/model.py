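"""The hierarchical family-resemblance generative model and its predictives.

Items are grouped into clusters (multivariate Gaussians); clusters are
grouped into *components* that describe the covariances expected of
clusters across learning contexts.  The generative cascade for a cluster k
assigned to component j is

    mu_k    ~ N(omega, sigma_r^2 I)
    Sigma_k ~ IW_{v_j}(Phi_j)
    Phi_j   ~ IW_{v_t}(I)
    v_j     ~ TN(v_t, v_t^2) truncated below at D

with a CRP prior over item -> cluster assignments within each context and
a two-level (hierarchical) CRP over cluster -> component assignments.
Cluster means are independent of cluster covariances, and every cluster
contains items of a single category label.

Two flavors of component are supported: *fitted* components carrying
(Phi_j, v_j), instantiated by the Gibbs sampler, and *fixed* components
whose inverse-Wishart prior has collapsed to a single covariance matrix
(the trained approximation).  Cluster means may be instantiated (Gibbs) or
analytically marginalized (trained approximation, particle filter).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .distributions import (
    CRPParams,
    IWParams,
    canonical_partition,
    crp_joint_logprob,
    ensure_spd,
    hcrp_component_probs,
    iw_logpdf,
    iw_mode,
    truncnorm_logpdf,
)

__all__ = [
    "Hyperparameters",
    "ClusterState",
    "ComponentState",
    "HierarchyState",
    "cluster_predictive_fixed_cov",
    "gaussian_logpdf",
    "joint_logprob",
    "assignment_posterior",
    "classify",
    "observe",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed model-level parameters.

    ``omega`` is the prior mean of cluster means (by convention the mean
    stimulus of the task), ``sigma_r2`` the isotropic variance of the
    cluster-mean prior, ``v_t`` the top-level degrees of freedom (also the
    mean and standard deviation of each component's truncated-normal dof
    prior), and ``top_scale`` the top-level inverse-Wishart scale (identity
    unless overridden; an isotropic top scale is what makes the untrained
    model rotation invariant).
    """

    dim: int
    crp: CRPParams = CRPParams()
    v_t: float = 30.0
    sigma_r2: float = 1.0
    omega: np.ndarray | None = None
    top_scale: np.ndarray | None = None
    label_set: tuple = (0, 1)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        omega = np.zeros(self.dim) if self.omega is None else np.asarray(self.omega, float)
        if omega.shape != (self.dim,):
            raise ValueError("omega must be a length-dim vector")
        object.__setattr__(self, "omega", omega)
        top = np.eye(self.dim) if self.top_scale is None else ensure_spd(self.top_scale)
        object.__setattr__(self, "top_scale", top)
        if not self.sigma_r2 > 0:
            raise ValueError("sigma_r2 must be positive")
        if not self.v_t > self.dim - 1:
            raise ValueError("v_t must exceed dim - 1")


@dataclass
class ComponentState:
    """One covariance component: either fitted (scale, dof) or fixed."""

    scale: np.ndarray | None = None
    dof: float | None = None
    fixed_cov: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.fixed_cov is not None:
            self.fixed_cov = ensure_spd(self.fixed_cov)
        elif self.scale is not None:
            self.scale = ensure_spd(self.scale)
            d = self.scale.shape[0]
            if self.dof is None or not self.dof >= d:
                raise ValueError("component dof must be >= dim")
        else:
            raise ValueError("component needs either fixed_cov or (scale, dof)")

    @property
    def is_fixed(self) -> bool:
        return self.fixed_cov is not None

    def cov_point_estimate(self) -> np.ndarray:
        """Fixed covariance, or the IW mode Phi/(dof + D + 1) if fitted."""
        if self.is_fixed:
            return self.fixed_cov
        return iw_mode(self.scale, self.dof)


@dataclass
class ClusterState:
    """One cluster: member items, label, context, component, parameters.

    ``mean``/``cov`` are instantiated by the Gibbs sampler; the trained
    approximation leaves ``mean`` as None (analytically marginalized) and
    takes ``cov`` from the cluster's component.
    """

    members: list[int]
    label: int | None = None
    context: int = 0
    component: int = 0
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster must have at least one member")
        if self.cov is not None:
            self.cov = ensure_spd(self.cov)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HierarchyState:
    """A joint assignment of items to clusters and clusters to components."""

    hyper: Hyperparameters
    data: list = field(default_factory=list)           # item coordinate vectors
    labels: list = field(default_factory=list)         # item labels (or None)
    item_context: list = field(default_factory=list)
    clusters: list[ClusterState] = field(default_factory=list)
    components: list[ComponentState] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.data)
        seen: list[int] = []
        for c in self.clusters:
            if c.component >= len(self.components):
                raise ValueError("cluster refers to a missing component")
            if any(i < 0 or i >= n for i in c.members):
                raise ValueError("cluster member index out of range")
            labs = {self.labels[i] for i in c.members if self.labels[i] is not None}
            if len(labs) > 1:
                raise ValueError("cluster mixes category labels")
            ctxs = {self.item_context[i] for i in c.members}
            if len(ctxs) > 1:
                raise ValueError("cluster mixes contexts")
            seen.extend(c.members)
        if sorted(seen) != list(range(n)):
            raise ValueError("cluster membership does not partition the items")

    # -- bookkeeping -------------------------------------------------------
    def z_vector(self) -> tuple[int, ...]:
        z = [0] * len(self.data)
        for k, c in enumerate(self.clusters):
            for i in c.members:
                z[i] = k
        return canonical_partition(z)

    def clusters_in_context(self, context) -> list[int]:
        return [k for k, c in enumerate(self.clusters) if c.context == context]

    def context_component_counts(self, context, exclude_cluster: int | None = None) -> np.ndarray:
        counts = np.zeros(len(self.components))
        for k, c in enumerate(self.clusters):
            if k == exclude_cluster or c.context != context:
                continue
            counts[c.component] += 1
        return counts

    def global_component_usage(self, exclude_cluster: int | None = None) -> np.ndarray:
        usage = np.zeros(len(self.components))
        for k, c in enumerate(self.clusters):
            if k == exclude_cluster:
                continue
            usage[c.component] += 1
        return usage

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "dim": self.hyper.dim,
            "sigma_r2": self.hyper.sigma_r2,
            "v_t": self.hyper.v_t,
            "omega": arr(self.hyper.omega),
            "crp": [self.hyper.crp.alpha, self.hyper.crp.alpha_c, self.hyper.crp.alpha_g],
            "data": [arr(x) for x in self.data],
            "labels": list(self.labels),
            "item_context": list(self.item_context),
            "clusters": [
                {
                    "members": list(c.members), "label": c.label,
                    "context": c.context, "component": c.component,
                    "mean": arr(c.mean), "cov": arr(c.cov),
                }
                for c in self.clusters
            ],
            "components": [
                {
                    "scale": arr(c.scale), "dof": c.dof,
                    "fixed_cov": arr(c.fixed_cov), "name": c.name,
                }
                for c in self.components
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyState":
        alpha, alpha_c, alpha_g = d["crp"]
        hyper = Hyperparameters(
            dim=d["dim"],
            crp=CRPParams(alpha=alpha, alpha_c=alpha_c, alpha_g=alpha_g),
            v_t=d["v_t"], sigma_r2=d["sigma_r2"], omega=np.asarray(d["omega"]),
        )
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        state = cls(
            hyper=hyper,
            data=[np.asarray(x, dtype=float) for x in d["data"]],
            labels=list(d["labels"]),
            item_context=list(d["item_context"]),
            clusters=[
                ClusterState(
                    members=list(c["members"]), label=c["label"],
                    context=c["context"], component=c["component"],
                    mean=arr(c["mean"]), cov=arr(c["cov"]),
                )
                for c in d["clusters"]
            ],
            components=[
                ComponentState(
                    scale=arr(c["scale"]), dof=c["dof"],
                    fixed_cov=arr(c["fixed_cov"]), name=c.get("name", ""),
                )
                for c in d["components"]
            ],
        )
        state.validate()
        return state

    @classmethod
    def from_json(cls, s: str) -> "HierarchyState":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Gaussian predictives
# ---------------------------------------------------------------------------

def gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal log density (full covariance)."""
    x = np.asarray(x, float)
    diff = x - np.asarray(mean, float)
    cov = np.asarray(cov, float)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    sol = np.linalg.solve(cov, diff)
    return float(-0.5 * (diff @ sol + logdet + diff.size * LOG2PI))


def _mean_posterior(members: np.ndarray, cov: np.ndarray, hyper: Hyperparameters):
    """Posterior N(mu | members) for a cluster with known covariance.

    Returns (posterior mean, posterior covariance V).  With m members and
    coordinate sum s:  V = (I/sigma_r^2 + m Sigma^-1)^-1 and
    mean = V (omega/sigma_r^2 + Sigma^-1 s).
    """
    d = hyper.dim
    prior_prec = np.eye(d) / hyper.sigma_r2
    if members is None or len(members) == 0:
        v = hyper.sigma_r2 * np.eye(d)
        return hyper.omega.copy(), v
    members = np.atleast_2d(np.asarray(members, float))
    m = members.shape[0]
    s = members.sum(axis=0)
    cov_inv = np.linalg.inv(cov)
    prec = prior_prec + m * cov_inv
    v = np.linalg.inv(prec)
    mean = v @ (prior_prec @ hyper.omega + cov_inv @ s)
    return mean, v


def cluster_predictive_fixed_cov(
    x: np.ndarray,
    members,
    cov: np.ndarray,
    hyper: Hyperparameters,
    log: bool = True,
) -> float:
    """Predictive density of ``x`` in a cluster with known covariance.

    The cluster mean is marginalized analytically under its
    N(omega, sigma_r^2 I) prior: the predictive is Gaussian with mean equal
    to the posterior mean of mu and covariance Sigma + V.  With no members
    this reduces to N(omega, Sigma + sigma_r^2 I).
    """
    cov = ensure_spd(cov)
    mean, v = _mean_posterior(members, cov, hyper)
    val = gaussian_logpdf(x, mean, cov + v)
    return val if log else math.exp(val)


def _cluster_loglik(x: np.ndarray, cluster: ClusterState, state: HierarchyState) -> float:
    """Log predictive of x under an existing cluster.

    Instantiated clusters (Gibbs) use N(x; mu_k, Sigma_k); collapsed
    clusters (trained approximation) marginalize the mean analytically
    under the component's fixed covariance.
    """
    if cluster.mean is not None:
        return gaussian_logpdf(x, cluster.mean, cluster.cov)
    comp = state.components[cluster.component]
    cov = cluster.cov if cluster.cov is not None else comp.cov_point_estimate()
    pts = np.array([state.data[i] for i in cluster.members])
    return cluster_predictive_fixed_cov(x, pts, cov, state.hyper)


def _new_cluster_loglik(x: np.ndarray, comp: ComponentState, state: HierarchyState) -> float:
    cov = comp.cov_point_estimate()
    return cluster_predictive_fixed_cov(x, None, cov, state.hyper)


# ---------------------------------------------------------------------------
# Joint density
# ---------------------------------------------------------------------------

def _hcrp_sequential_logprob(state: HierarchyState) -> float:
    """Sequential two-level CRP log prior over cluster -> component draws.

    Clusters are visited in index order; component j is reused within a
    context with probability proportional to its context count plus
    alpha_c times its global weight (usage, or alpha_g for a new one).
    """
    crp = state.hyper.crp
    j_total = len(state.components)
    ctx_counts: dict = {}
    global_usage = np.zeros(j_total)
    out = 0.0
    for c in state.clusters:
        counts = ctx_counts.setdefault(c.context, np.zeros(j_total))
        if crp.alpha_g > 0:
            probs = hcrp_component_probs(counts, global_usage, crp)[:-1]
            # mass for *this particular* new component when unused anywhere
            if global_usage[c.component] == 0 and counts[c.component] == 0:
                new_mass = hcrp_component_probs(counts, global_usage, crp)[-1]
                p = new_mass
            else:
                p = probs[c.component]
        else:
            w = np.full(j_total, 1.0 / j_total)
            probs = hcrp_component_probs(counts, w, crp)
            p = probs[c.component]
        out += math.log(max(p, 1e-300))
        counts[c.component] += 1
        global_usage[c.component] += 1
    return out


def joint_logprob(state: HierarchyState, data=None) -> float:
    """Log joint density of a fully instantiated hierarchy and its data.

    Sums the CRP prior over item partitions (per context), the
    hierarchical-CRP prior over component assignments, the top-level
    IW/TN priors on fitted components, the IW prior of each cluster
    covariance given its component, the Gaussian prior of each cluster
    mean, and the Gaussian likelihood of every item.
    """
    state.validate()
    hyper = state.hyper
    out = 0.0
    # CRP over items, per context
    for ctx in sorted({c.context for c in state.clusters}):
        z = []
        for k in state.clusters_in_context(ctx):
            z.extend([k] * state.clusters[k].size)
        out += crp_joint_logprob(z, hyper.crp.alpha)
    out += _hcrp_sequential_logprob(state)
    for comp in state.components:
        if not comp.is_fixed:
            out += iw_logpdf(comp.scale, IWParams(hyper.top_scale, hyper.v_t))
            out += float(truncnorm_logpdf(comp.dof, hyper.v_t, hyper.v_t, hyper.dim))
    for c in state.clusters:
        comp = state.components[c.component]
        if c.cov is not None and not comp.is_fixed:
            out += iw_logpdf(c.cov, IWParams(comp.scale, comp.dof))
        if c.mean is not None:
            out += gaussian_logpdf(c.mean, hyper.omega, hyper.sigma_r2 * np.eye(hyper.dim))
            cov = c.cov if c.cov is not None else comp.cov_point_estimate()
            for i in c.members:
                out += gaussian_logpdf(state.data[i], c.mean, cov)
        else:
            cov = c.cov if c.cov is not None else comp.cov_point_estimate()
            pts = [state.data[i] for i in c.members]
            run = []
            for p in pts:          # chain rule; order-invariant in value
                out += cluster_predictive_fixed_cov(p, np.array(run) if run else None, cov, hyper)
                run.append(p)
    return out


# ---------------------------------------------------------------------------
# Assignment posterior, decision rule, sequential update
# ---------------------------------------------------------------------------

def assignment_posterior(
    x: np.ndarray,
    state: HierarchyState,
    context=0,
    label_query=None,
):
    """Posterior over where a new item would go in a context.

    Returns ``(options, log_probs)`` where each option is either
    ``("cluster", k)`` for an existing cluster in the context or
    ``("new", j)`` for a fresh cluster under component j.  When
    ``label_query`` is given, clusters with a conflicting label receive no
    mass (clusters are single-category).  Probabilities are normalized.
    """
    hyper = state.hyper
    crp = hyper.crp
    in_ctx = state.clusters_in_context(context)
    n_ctx = sum(state.clusters[k].size for k in in_ctx)
    options: list[tuple] = []
    logp: list[float] = []
    for k in in_ctx:
        c = state.clusters[k]
        if label_query is not None and c.label is not None and c.label != label_query:
            continue
        options.append(("cluster", k))
        logp.append(math.log(c.size) + _cluster_loglik(x, c, state))
    # new cluster, one option per component
    counts = state.context_component_counts(context)
    if crp.alpha_g > 0:
        usage = state.global_component_usage()
        comp_probs = hcrp_component_probs(counts, usage, crp)
    else:
        if not state.components:
            raise ValueError("no components available and alpha_g = 0")
        w = np.full(len(state.components), 1.0 / len(state.components))
        comp_probs = hcrp_component_probs(counts, w, crp)
    # a fresh cluster draws its label uniformly from the label set
    label_lp = -math.log(len(hyper.label_set)) if label_query is not None else 0.0
    for j, comp in enumerate(state.components):
        options.append(("new", j))
        logp.append(
            math.log(crp.alpha) + math.log(max(comp_probs[j], 1e-300))
            + label_lp + _new_cluster_loglik(x, comp, state)
        )
    if crp.alpha_g > 0:
        # new component drawn fresh from the top-level prior (point estimate)
        top = ComponentState(scale=hyper.top_scale.copy(), dof=hyper.v_t)
        options.append(("new", len(state.components)))
        logp.append(
            math.log(crp.alpha) + math.log(max(comp_probs[-1], 1e-300))
            + label_lp + _new_cluster_loglik(x, top, state)
        )
    logp = np.asarray(logp) - math.log(n_ctx + crp.alpha)
    logp = logp - logsumexp(logp)
    return options, logp


def classify(x: np.ndarray, state: HierarchyState, context=0, label_set=None):
    """Posterior probability of each category label for a new item.

    Sums assignment-posterior mass over the labeled clusters of the
    context; the new-cluster mass is split uniformly over the label set
    (a fresh cluster may carry any label a priori).
    """
    labels = tuple(label_set) if label_set is not None else tuple(state.hyper.label_set)
    if not labels:
        raise ValueError("a label set is required to classify")
    options, logp = assignment_posterior(x, state, context)
    p = np.exp(logp)
    out = {lab: 0.0 for lab in labels}
    for (kind, idx), pi in zip(options, p):
        if kind == "cluster":
            lab = state.clusters[idx].label
            if lab is None:
                for l in labels:
                    out[l] += pi / len(labels)
            else:
                out[lab] += pi
        else:
            for l in labels:
                out[l] += pi / len(labels)
    total = sum(out.values())
    return {l: v / total for l, v in out.items()}


def observe(
    x: np.ndarray,
    label,
    state: HierarchyState,
    context=0,
    mode: str = "map",
    rng=None,
) -> HierarchyState:
    """Assign a new labeled item to a cluster and update the state in place.

    ``map`` picks the most probable label-consistent option
    (deterministically, ties to the lowest index); ``sample`` draws from
    the assignment posterior.  A new cluster instantiates its component's
    point-estimate covariance (fixed components keep their matrix).
    """
    if mode not in ("map", "sample"):
        raise ValueError("mode must be 'map' or 'sample'")
    options, logp = assignment_posterior(x, state, context, label_query=label)
    if mode == "map":
        choice = int(np.argmax(logp))
    else:
        rng = np.random.default_rng(rng)
        choice = int(rng.choice(len(options), p=np.exp(logp)))
    i = len(state.data)
    state.data.append(np.asarray(x, float))
    state.labels.append(label)
    state.item_context.append(context)
    kind, idx = options[choice]
    if kind == "cluster":
        state.clusters[idx].members.append(i)
    else:
        if idx == len(state.components):   # brand-new component from the prior
            state.components.append(
                ComponentState(scale=state.hyper.top_scale.copy(), dof=state.hyper.v_t)
            )
        comp = state.components[idx]
        state.clusters.append(
            ClusterState(
                members=[i], label=label, context=context, component=idx,
                cov=comp.cov_point_estimate() if not comp.is_fixed else None,
            )
        )
    return state
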