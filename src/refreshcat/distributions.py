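"""Probability primitives for nonparametric family-resemblance clustering.

Chinese-restaurant-process (CRP) priors over partitions, the two-level
(hierarchical) CRP used to share cluster-covariance *components* across
learning contexts, inverse-Wishart and truncated-normal building blocks,
and exact set-partition combinatorics (restricted growth strings, Bell
numbers).  All probability arithmetic is done in log space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "CRPParams",
    "IWParams",
    "PartitionVector",
    "canonical_partition",
    "crp_assignment_probs",
    "crp_joint_logprob",
    "hcrp_component_probs",
    "hcrp_joint_logprob",
    "iw_logpdf",
    "iw_sample",
    "iw_mode",
    "iw_mean",
    "truncnorm_logpdf",
    "truncnorm_sample",
    "enumerate_partitions",
    "bell_number",
    "ensure_spd",
]

_SPD_JITTER = 1e-10


def ensure_spd(a: np.ndarray, jitter: float = _SPD_JITTER) -> np.ndarray:
    """Validate that ``a`` is symmetric positive definite.

    Returns the symmetrized matrix, adding ``jitter`` to the diagonal once
    if the Cholesky factorization fails on a near-singular input.  Raises
    ``ValueError`` for anything genuinely non-SPD.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, rtol=1e-8, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    sym = 0.5 * (a + a.T)
    try:
        np.linalg.cholesky(sym)
        return sym
    except np.linalg.LinAlgError:
        pass
    bumped = sym + jitter * np.eye(sym.shape[0])
    try:
        np.linalg.cholesky(bumped)
    except np.linalg.LinAlgError as err:
        raise ValueError("matrix is not positive definite") from err
    return bumped


@dataclass(frozen=True)
class CRPParams:
    """Dispersion parameters of the two-level clustering prior.

    ``alpha`` governs item -> cluster assignments, ``alpha_c`` the reuse of
    covariance components within a learning context, and ``alpha_g`` the
    creation of brand-new components at the global level.  ``alpha_c`` may
    be ``math.inf`` (context counts ignored, components drawn from their
    global weights).  ``alpha_g == 0`` is only legal when a finite fixed
    component set with equal prior weights is supplied.
    """

    alpha: float = 10.0
    alpha_c: float = 0.001
    alpha_g: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (self.alpha_c > 0 or math.isinf(self.alpha_c)):
            raise ValueError("alpha_c must be positive (or infinite)")
        if self.alpha_g < 0:
            raise ValueError("alpha_g must be nonnegative")


@dataclass(frozen=True)
class IWParams:
    """Inverse-Wishart parameters: SPD scale, degrees of freedom, dimension."""

    scale: np.ndarray
    dof: float
    dim: int = 0

    def __post_init__(self) -> None:
        scale = ensure_spd(self.scale)
        object.__setattr__(self, "scale", scale)
        dim = self.dim or scale.shape[0]
        object.__setattr__(self, "dim", int(dim))
        if scale.shape[0] != self.dim:
            raise ValueError("scale shape inconsistent with dim")
        if not self.dof > self.dim - 1:
            raise ValueError(f"dof must exceed dim - 1 = {self.dim - 1}")

    @property
    def mode(self) -> np.ndarray:
        """Most probable covariance matrix, scale / (dof + dim + 1)."""
        return self.scale / (self.dof + self.dim + 1)

    @property
    def mean(self) -> np.ndarray:
        """E[Sigma] = scale / (dof - dim - 1); requires dof > dim + 1."""
        if not self.dof > self.dim + 1:
            raise ValueError("mean undefined unless dof > dim + 1")
        return self.scale / (self.dof - self.dim - 1)


def canonical_partition(assignments) -> tuple[int, ...]:
    """Canonical restricted-growth-string form of a partition vector.

    Cluster ids are relabeled in order of first appearance starting at 0,
    so two assignment vectors describe the same set partition iff their
    canonical forms are equal.
    """
    relabel: dict = {}
    out = []
    for a in assignments:
        if a not in relabel:
            relabel[a] = len(relabel)
        out.append(relabel[a])
    return tuple(out)


@dataclass
class PartitionVector:
    """A set partition as a canonical assignment vector plus cluster sizes.

    Indices are 0-based and contiguous in order of first appearance.
    """

    assignments: tuple[int, ...]
    counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.assignments = canonical_partition(self.assignments)
        n_clusters = (max(self.assignments) + 1) if self.assignments else 0
        counts = [0] * n_clusters
        for a in self.assignments:
            counts[a] += 1
        counts = tuple(counts)
        if self.counts and tuple(self.counts) != counts:
            raise ValueError("counts inconsistent with assignments")
        self.counts = counts
        if any(c < 1 for c in self.counts):
            raise ValueError("all cluster counts must be >= 1")

    @property
    def n_items(self) -> int:
        return len(self.assignments)

    @property
    def n_clusters(self) -> int:
        return len(self.counts)


def crp_assignment_probs(partition, alpha: float) -> np.ndarray:
    """Seating probabilities for the next item under a CRP.

    Given current cluster sizes M_1..M_K over n existing items, returns the
    length-(K+1) vector (M_1, .., M_K, alpha) / (n + alpha): each existing
    cluster in proportion to its size, plus one new-cluster slot.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if isinstance(partition, PartitionVector):
        counts = np.asarray(partition.counts, dtype=float)
    else:
        counts = np.asarray(partition, dtype=float)
    if counts.size and counts.min() < 1:
        raise ValueError("cluster counts must be >= 1")
    n = counts.sum()
    return np.append(counts, alpha) / (n + alpha)


def crp_joint_logprob(assignments, alpha: float) -> float:
    """Log probability of a partition under the CRP (exchangeable form).

    Equals the product of sequential seating probabilities and is invariant
    to item order:  alpha^K * prod_k (M_k - 1)! * Gamma(alpha)/Gamma(alpha+n).
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    pv = assignments if isinstance(assignments, PartitionVector) else PartitionVector(tuple(assignments))
    n = pv.n_items
    k = pv.n_clusters
    if n == 0:
        return 0.0
    out = k * math.log(alpha) + gammaln(alpha) - gammaln(alpha + n)
    out += sum(gammaln(m) for m in pv.counts)
    return float(out)


def hcrp_component_probs(
    context_counts,
    global_weights,
    params: CRPParams,
) -> np.ndarray:
    """Probability that the next cluster in a context uses each component.

    Component j gets mass proportional to n_j(context) + alpha_c * w_j,
    where w_j are normalized global weights.  When ``alpha_g > 0`` a final
    new-component slot is appended whose global weight is proportional to
    alpha_g.  With ``alpha_c = inf`` the context counts are ignored and the
    global weights are returned.
    """
    counts = np.asarray(context_counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValueError("context counts must be nonnegative")
    if global_weights is None:
        if params.alpha_g == 0:
            raise ValueError(
                "alpha_g = 0 requires a fixed finite component set "
                "(supply global_weights, e.g. equal weights)"
            )
        global_weights = np.zeros(counts.size)
    w = np.asarray(global_weights, dtype=float)
    if w.shape != counts.shape:
        raise ValueError("global_weights and context_counts must align")
    if params.alpha_g > 0:
        counts = np.append(counts, 0.0)
        w = np.append(w, params.alpha_g)
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("global weights sum to zero with alpha_g = 0")
    w = w / total_w
    if math.isinf(params.alpha_c):
        return w
    unnorm = counts + params.alpha_c * w
    return unnorm / unnorm.sum()


def hcrp_joint_logprob(comp_assignments, n_components: int, alpha_c: float) -> float:
    """Log probability of a cluster -> component assignment in one context.

    For a fixed finite set of ``n_components`` equally weighted components
    (the trained approximation, alpha_g = 0), the sequential reuse rule
    P(u_k = j) = (n_j + alpha_c / J) / (k - 1 + alpha_c) is a Polya urn, so
    the joint is the exchangeable Dirichlet-multinomial closed form.
    """
    u = np.asarray(comp_assignments, dtype=int)
    if u.size == 0:
        return 0.0
    if u.min() < 0 or u.max() >= n_components:
        raise ValueError("component index out of range")
    if math.isinf(alpha_c):
        return float(-u.size * math.log(n_components))
    k = u.size
    a = alpha_c / n_components
    counts = np.bincount(u, minlength=n_components)
    out = gammaln(alpha_c) - gammaln(alpha_c + k)
    out += np.sum(gammaln(a + counts) - gammaln(a))
    return float(out)


def iw_logpdf(x: np.ndarray, params: IWParams) -> float:
    """Inverse-Wishart log density at SPD matrix ``x``."""
    x = ensure_spd(x)
    return float(stats.invwishart.logpdf(x, df=params.dof, scale=params.scale))


def iw_sample(params: IWParams, rng, size: int | None = None) -> np.ndarray:
    """Draw SPD matrices from an inverse-Wishart distribution."""
    rng = np.random.default_rng(rng)
    return stats.invwishart.rvs(
        df=params.dof, scale=params.scale, size=size or 1, random_state=rng
    )


def iw_mode(scale: np.ndarray, dof: float) -> np.ndarray:
    """Mode of IW(dof, scale): scale / (dof + D + 1)."""
    scale = np.asarray(scale, dtype=float)
    return scale / (dof + scale.shape[0] + 1)


def iw_mean(scale: np.ndarray, dof: float) -> np.ndarray:
    """Mean of IW(dof, scale): scale / (dof - D - 1), for dof > D + 1."""
    scale = np.asarray(scale, dtype=float)
    d = scale.shape[0]
    if not dof > d + 1:
        raise ValueError("mean undefined unless dof > dim + 1")
    return scale / (dof - d - 1)


def _truncnorm_ab(mean: float, sd: float, lower: float):
    a = (lower - mean) / sd
    return a, np.inf


def truncnorm_logpdf(x, mean: float, sd: float, lower: float) -> np.ndarray:
    """Log density of a normal truncated from below at ``lower``."""
    if not sd > 0:
        raise ValueError("sd must be positive")
    a, b = _truncnorm_ab(mean, sd, lower)
    return stats.truncnorm.logpdf(x, a, b, loc=mean, scale=sd)


def truncnorm_sample(mean: float, sd: float, lower: float, rng, size=None):
    """Draw from a normal truncated from below at ``lower``."""
    if not sd > 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(rng)
    a, b = _truncnorm_ab(mean, sd, lower)
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def enumerate_partitions(n: int, cap: int = 10) -> list[tuple[int, ...]]:
    """All set partitions of ``n`` items as canonical restricted growth strings.

    Generated in lexicographic restricted-growth order; the list length is
    the Bell number B(n).  Refuses n above ``cap`` (the count grows like
    B(12) = 4,213,597).
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    if n > cap:
        raise ValueError(
            f"n = {n} exceeds the enumeration cap ({cap}); "
            "raise cap explicitly if you really want Bell({}) partitions".format(n)
        )
    out: list[tuple[int, ...]] = []
    a = [0] * n

    def rec(i: int, m: int) -> None:
        if i == n:
            out.append(tuple(a))
            return
        for v in range(m + 1):
            a[i] = v
            rec(i + 1, max(m, v + 1))

    rec(0, 0)
    return out


def bell_number(n: int) -> int:
    """Exact Bell number B(n) via the Bell-triangle recurrence."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]
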