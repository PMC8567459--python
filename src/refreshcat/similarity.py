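"""Similarity fields, Minkowski-metric fitting, and metric diagnostics.

Similarity between stimuli x and x* is the posterior-averaged probability
that x* belongs to the cluster that generated x: hypotheses h (which
cluster x joined, under which covariance component) are weighted by their
posterior given x, and each contributes the predictive density of x*
under that cluster relative to its value at x, so s(x, x) = 1 and fields
live in [0, 1].  Before any training the hierarchy's covariance prior is
isotropic and iso-similarity contours are circular; training on
dimensionally aligned clusters bends the contours toward city-block and,
with enough aligned categories, nonmetric shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull
from scipy.stats import norm as _norm

from .distributions import truncnorm_sample
from .inference.gibbs import _iw_rvs

__all__ = [
    "SimilarityField",
    "MinkowskiFit",
    "hypothesis_draws",
    "similarity",
    "similarity_matrix",
    "iso_similarity_field",
    "fit_minkowski",
    "convexity_and_triangle_check",
    "dprime",
    "learning_curve",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class SimilarityField:
    """Similarity to a reference stimulus on a 2-D grid slice.

    ``values[i, j]`` is the similarity at ``(xs[i], ys[j])`` along the
    plotted dimension pair; unplotted dimensions are clamped to
    ``fixed_values``.
    """

    reference: np.ndarray
    dims: tuple[int, int]
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    fixed_values: np.ndarray | None = None

    def displacement_axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.xs - self.reference[self.dims[0]],
                self.ys - self.reference[self.dims[1]])


@dataclass
class MinkowskiFit:
    """Best-fitting weighted Minkowski metric with an exponential link."""

    r: float
    weights: np.ndarray
    decay: float
    angle_deg: float
    residual: float


# ---------------------------------------------------------------------------
# covariance draws representing the hypothesis set
# ---------------------------------------------------------------------------

def _as_matrices(components) -> np.ndarray:
    if hasattr(components, "matrices"):
        return np.stack(components.matrices)
    arr = np.asarray(components, dtype=float)
    if arr.ndim == 2 and arr.shape[0] != arr.shape[1]:
        return np.stack([np.diag(v) for v in arr])
    if arr.ndim == 2:
        return arr[None]
    return arr


def hypothesis_draws(posterior, hyper, rng, include_clusters: bool = True,
                     n_prior_samples: int = 1000) -> list[dict]:
    """Per-sample hypothesis sets for the similarity computation.

    Each entry describes the "clusters under consideration" for one
    posterior sample: the instantiated clusters of the sample (weight
    proportional to cluster size) plus one fresh-cluster option per
    covariance component (weight proportional to alpha times the
    component's share, with a new component proportional to alpha_g drawn
    from the top-level prior).  Accepts a Gibbs ``PosteriorSampleSet``, a
    ``TrainedComponentSet``/array of fixed matrices, or ``None`` for the
    untrained prior.

    Keys per sample: ``cl_w, cl_mu, cl_sig`` (may be empty) and
    ``new_w, new_sig``.
    """
    rng = np.random.default_rng(rng)
    alpha = hyper.crp.alpha
    d = hyper.dim
    empty = dict(cl_w=np.zeros(0), cl_mu=np.zeros((0, d)), cl_sig=np.zeros((0, d, d)))
    samples = getattr(posterior, "samples", None)
    if posterior is None:
        out = []
        for _ in range(n_prior_samples):
            phi = _iw_rvs(hyper.v_t, hyper.top_scale, rng)
            v = float(truncnorm_sample(hyper.v_t, hyper.v_t, d, rng))
            sigma = _iw_rvs(v, phi, rng)
            out.append(dict(empty, new_w=np.array([alpha]), new_sig=sigma[None]))
        return out
    if samples is None:
        mats = _as_matrices(posterior)
        j = mats.shape[0]
        return [dict(empty, new_w=np.full(j, alpha / j), new_sig=mats)]
    out = []
    for snap in samples:
        weights, sigmas = [], []
        for c in snap["components"]:
            if c["usage"] <= 0:
                continue
            weights.append(float(c["usage"]))
            sigmas.append(_iw_rvs(c["v"], c["phi"], rng))
        if hyper.crp.alpha_g > 0:
            phi = _iw_rvs(hyper.v_t, hyper.top_scale, rng)
            v = float(truncnorm_sample(hyper.v_t, hyper.v_t, d, rng))
            weights.append(hyper.crp.alpha_g)
            sigmas.append(_iw_rvs(v, phi, rng))
        w = np.asarray(weights, dtype=float)
        w = alpha * w / w.sum()
        entry = dict(empty, new_w=w, new_sig=np.stack(sigmas))
        if include_clusters and snap.get("clusters"):
            entry["cl_w"] = np.array([c["size"] for c in snap["clusters"]], dtype=float)
            entry["cl_mu"] = np.stack([c["mu"] for c in snap["clusters"]])
            entry["cl_sig"] = np.stack([c["sigma"] for c in snap["clusters"]])
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# similarity evaluation
# ---------------------------------------------------------------------------

def _gauss_logpdf_many(pts: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(pts; mean, cov) for (N, D) points."""
    diff = np.atleast_2d(pts) - mean
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    quad = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (quad + logdet + diff.shape[1] * LOG2PI)


def _cluster_of(points_x: np.ndarray, sigma: np.ndarray, hyper):
    """Affine posterior-mean map and predictive covariance for cluster {x}.

    Returns (A, b, C): the cluster containing the single item x has
    mean posterior N(Ax + b, V) and predictive covariance C = Sigma + V.
    """
    d = hyper.dim
    sig_inv = np.linalg.inv(sigma)
    prec = np.eye(d) / hyper.sigma_r2 + sig_inv
    v = np.linalg.inv(prec)
    a = v @ sig_inv
    b = v @ (hyper.omega / hyper.sigma_r2)
    return a, b, sigma + v


def _hypothesis_tables(targets: np.ndarray, x: np.ndarray, sample: dict, hyper):
    """Per-hypothesis log weights and per-target similarity ratios.

    Returns ``(logw_x, s_x, logw_t, s_t)``: hypothesis log masses and
    similarity ratios when the probe item is x (forward direction) and
    when the probe item is each target (reverse direction).  Hypotheses
    are the sample's clusters (mass size * density) followed by the
    fresh-cluster options (mass new_w * prior predictive).
    """
    n = targets.shape[0]
    cl_w, cl_mu, cl_sig = sample["cl_w"], sample["cl_mu"], sample["cl_sig"]
    new_w, new_sig = sample["new_w"], sample["new_sig"]
    k, j = cl_w.size, new_w.size
    logw_x = np.zeros(k + j)
    s_x = np.zeros((k + j, n))
    logw_t = np.zeros((k + j, n))
    s_t = np.zeros((k + j, n))
    for kk in range(k):
        ll_t = _gauss_logpdf_many(targets, cl_mu[kk], cl_sig[kk])
        ll_x = float(_gauss_logpdf_many(x[None], cl_mu[kk], cl_sig[kk])[0])
        logw_x[kk] = math.log(cl_w[kk]) + ll_x
        s_x[kk] = np.exp(np.minimum(0.0, ll_t - ll_x))
        logw_t[kk] = math.log(cl_w[kk]) + ll_t
        s_t[kk] = np.exp(np.minimum(0.0, ll_x - ll_t))
    eye = hyper.sigma_r2 * np.eye(hyper.dim)
    for jj in range(j):
        row = k + jj
        sig = new_sig[jj]
        lp0_t = _gauss_logpdf_many(targets, hyper.omega, sig + eye)
        lp0_x = float(_gauss_logpdf_many(x[None], hyper.omega, sig + eye)[0])
        a, b, c = _cluster_of(x, sig, hyper)
        # forward: cluster seeded at x, evaluated at targets
        mean_x = a @ x + b
        ll_t = _gauss_logpdf_many(targets, mean_x, c)
        ll_x = float(_gauss_logpdf_many(x[None], mean_x, c)[0])
        logw_x[row] = math.log(max(new_w[jj], 1e-300)) + lp0_x
        s_x[row] = np.exp(np.minimum(0.0, ll_t - ll_x))
        # reverse: cluster seeded at each target, evaluated at x
        mean_t = targets @ a.T + b
        ll_x_rev = _gauss_logpdf_many(x - mean_t, np.zeros(hyper.dim), c)
        ll_t_rev = _gauss_logpdf_many(targets - mean_t, np.zeros(hyper.dim), c)
        logw_t[row] = math.log(max(new_w[jj], 1e-300)) + lp0_t
        s_t[row] = np.exp(np.minimum(0.0, ll_x_rev - ll_t_rev))
    return logw_x, s_x, logw_t, s_t


def _similarity_points(targets: np.ndarray, x: np.ndarray, draws, hyper,
                       symmetrize: bool = True) -> np.ndarray:
    """Similarity of each target point to x, averaged over the draws."""
    targets = np.atleast_2d(targets)
    x = np.asarray(x, dtype=float)
    acc = np.zeros(targets.shape[0])
    for sample in draws:
        logw_x, s_x, logw_t, s_t = _hypothesis_tables(targets, x, sample, hyper)
        post_x = np.exp(logw_x - logw_x.max())
        post_x /= post_x.sum()
        fwd = post_x @ s_x
        if symmetrize:
            post_t = np.exp(logw_t - logw_t.max(axis=0, keepdims=True))
            post_t /= post_t.sum(axis=0, keepdims=True)
            rev = (post_t * s_t).sum(axis=0)
            acc += 0.5 * (fwd + rev)
        else:
            acc += fwd
    return acc / len(draws)


def similarity(x_star, x, posterior, hyper, rng=0, symmetrize: bool = True,
               include_clusters: bool = True) -> float:
    """Posterior-averaged probability that x* shares the cluster of x.

    ``posterior`` may be a Gibbs ``PosteriorSampleSet`` (hypotheses
    include its learned clusters), a fixed component set, or ``None`` for
    the untrained prior (1,000 prior draws).
    """
    draws = hypothesis_draws(posterior, hyper, rng, include_clusters=include_clusters)
    return float(_similarity_points(np.asarray(x_star, float)[None],
                                    np.asarray(x, float), draws, hyper,
                                    symmetrize=symmetrize)[0])


def similarity_matrix(points_a, points_b, posterior, hyper, rng=0,
                      symmetrize: bool = True, include_clusters: bool = True) -> np.ndarray:
    """Similarity of each pair (a_i, b_i); inputs must have equal length."""
    a = np.atleast_2d(np.asarray(points_a, float))
    b = np.atleast_2d(np.asarray(points_b, float))
    draws = hypothesis_draws(posterior, hyper, rng, include_clusters=include_clusters)
    out = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        out[i] = _similarity_points(b[i][None], a[i], draws, hyper,
                                    symmetrize=symmetrize)[0]
    return out


def iso_similarity_field(
    posterior,
    hyper,
    reference=None,
    dims: tuple[int, int] = (0, 1),
    extent: float = 3.0,
    n_grid: int = 41,
    fixed_values=None,
    rng=0,
    n_prior_samples: int = 1000,
    symmetrize: bool = True,
) -> SimilarityField:
    """Evaluate the similarity field around a reference on a 2-D grid slice.

    The grid spans reference +- extent along the plotted dimension pair;
    unplotted dimensions are clamped to ``fixed_values`` (default: the
    reference itself, conventionally the mean stimulus).
    """
    reference = (hyper.omega.copy() if reference is None
                 else np.asarray(reference, dtype=float))
    draws = hypothesis_draws(posterior, hyper, rng,
                             n_prior_samples=n_prior_samples)
    xs = reference[dims[0]] + np.linspace(-extent, extent, n_grid)
    ys = reference[dims[1]] + np.linspace(-extent, extent, n_grid)
    base = reference.copy()
    if fixed_values is not None:
        base = np.asarray(fixed_values, dtype=float).copy()
        base[list(dims)] = reference[list(dims)]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.tile(base, (n_grid * n_grid, 1))
    pts[:, dims[0]] = gx.ravel()
    pts[:, dims[1]] = gy.ravel()
    vals = _similarity_points(pts, reference, draws, hyper, symmetrize=symmetrize)
    return SimilarityField(
        reference=reference, dims=dims, xs=xs, ys=ys,
        values=vals.reshape(n_grid, n_grid),
        fixed_values=base,
    )


# ---------------------------------------------------------------------------
# Minkowski-metric fitting
# ---------------------------------------------------------------------------

def _minkowski_distance(dx: np.ndarray, dy: np.ndarray, r: float, w1: float,
                        theta_deg: float) -> np.ndarray:
    if theta_deg:
        t = math.radians(theta_deg)
        dx, dy = math.cos(t) * dx + math.sin(t) * dy, -math.sin(t) * dx + math.cos(t) * dy
    return (w1 * np.abs(dx) ** r + (1.0 - w1) * np.abs(dy) ** r) ** (1.0 / r)


def _fit_decay(d: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Least-squares decay rate for s ~ exp(-b d); returns (b, sse)."""

    def sse(logb):
        resid = s - np.exp(-math.exp(logb) * d)
        return float((resid**2).sum())

    res = minimize_scalar(sse, bounds=(-6, 6), method="bounded",
                          options={"xatol": 1e-3})
    return math.exp(res.x), res.fun


def _isotonic_sse(d: np.ndarray, s: np.ndarray) -> float:
    """SSE of the best monotone decreasing link s ~ g(d) (isotonic fit)."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fit = iso.fit_transform(d, s)
    return float(((s - fit) ** 2).sum())


def fit_minkowski(
    field: SimilarityField,
    fit_rotation: bool = False,
    r_bounds: tuple[float, float] = (0.25, 4.0),
) -> MinkowskiFit:
    """Fit a weighted Minkowski metric with a monotone (exponential) link.

    Grid search over the exponent r (coarse then refined), the dimension
    weight, and optionally a rotation of the fitted axes.  The link is
    nonparametric: for each candidate metric the best *monotone
    decreasing* transformation of distance is found by isotonic
    regression, so the exponent is identified purely by the shape of the
    iso-similarity contours and not by the radial decay profile.  The
    exponent diagnoses the effective metric: r near 2 for integral
    (Euclidean) behavior, near 1 for separable (city-block), below 1 for
    nonmetric fields.
    """
    dxa, dya = field.displacement_axes()
    dx, dy = np.meshgrid(dxa, dya, indexing="ij")
    s = field.values.ravel()
    if s.max() - s.min() < 1e-9:
        raise ValueError("flat similarity field; nothing to fit")
    dx = dx.ravel()
    dy = dy.ravel()
    w_grid = np.linspace(0.1, 0.9, 9)
    theta_grid = np.arange(0.0, 90.0, 7.5) if fit_rotation else np.array([0.0])

    def eval_point(r, w1, theta):
        d = _minkowski_distance(dx, dy, r, w1, theta)
        return _isotonic_sse(d, s)

    def scan(r_values, w_values, t_values):
        best = None
        for r in r_values:
            for w1 in w_values:
                for th in t_values:
                    sse = eval_point(r, w1, th)
                    if best is None or sse < best[0]:
                        best = (sse, r, w1, th)
        return best

    coarse_r = np.arange(r_bounds[0], r_bounds[1] + 1e-9, 0.25)
    sse, r, w1, th = scan(coarse_r, w_grid, theta_grid)
    fine_r = np.clip(np.arange(r - 0.25, r + 0.25 + 1e-9, 0.05), *r_bounds)
    fine_w = np.clip(np.linspace(w1 - 0.1, w1 + 0.1, 9), 0.02, 0.98)
    fine_t = (np.clip(np.arange(th - 7.5, th + 7.5 + 1e-9, 1.5), 0.0, 89.9)
              if fit_rotation else np.array([th]))
    sse, r, w1, th = scan(fine_r, fine_w, fine_t)
    decay, _ = _fit_decay(_minkowski_distance(dx, dy, r, w1, th), s)
    return MinkowskiFit(
        r=float(r), weights=np.array([w1, 1.0 - w1]), decay=float(decay),
        angle_deg=float(th), residual=float(sse),
    )


# ---------------------------------------------------------------------------
# convexity and triangle-inequality diagnostics
# ---------------------------------------------------------------------------

def _contour_convexity(field: SimilarityField, level: float) -> bool | None:
    """True if the longest level contour encloses a convex region."""
    from skimage import measure

    contours = measure.find_contours(field.values, level)
    if not contours:
        return None
    contour = max(contours, key=len)
    if len(contour) < 8:
        return None
    pts = contour
    # polygon area (shoelace) vs convex hull area
    x, y = pts[:, 0], pts[:, 1]
    poly_area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    try:
        hull = ConvexHull(pts)
    except Exception:
        return None
    if poly_area <= 0:
        return None
    return bool(hull.volume <= poly_area * 1.02)


def convexity_and_triangle_check(
    field: SimilarityField,
    level: float = 0.5,
    rel_margin: float = 1.15,
    max_witnesses: int = 20,
):
    """Diagnose whether a similarity field is consistent with a metric.

    ``level`` is a fraction of the field maximum.  The report contains a
    convexity flag for the level contour and triangle-inequality witness
    triples.  Witnesses use a link-free test: similarity values are
    converted to pseudo-distances by inverting the field along the first
    displacement axis (a valid ruler for any norm-based similarity with a
    monotone decreasing link), and a corner triple (A at the reference,
    C = (a, 0), B = (a, b)) is a witness when the calibrated direct
    distance exceeds the detour, D(a, b) > rel_margin * (D(a,0) + D(0,b)).
    Fields generated from true Minkowski metrics with exponent >= 1 yield
    no witnesses; exponents < 1 do.
    """
    vals = field.values / field.values.max()
    abs_level = level
    dxa, dya = field.displacement_axes()
    ix0 = int(np.argmin(np.abs(dxa)))
    iy0 = int(np.argmin(np.abs(dya)))
    # ruler along the +x axis through the reference
    ray_d = dxa[ix0:]
    # enforce monotone decay along the ruler (guards Monte-Carlo jitter)
    ray_s = np.minimum.accumulate(vals[ix0:, iy0])
    floor = max(ray_s.min(), 1e-6)

    def pseudo_distance(sim):
        sim = np.clip(sim, floor, 1.0)
        return np.interp(-sim, -ray_s, ray_d)  # ray_s is decreasing in d

    witnesses = []
    pos_x = np.where(dxa > 0)[0]
    pos_y = np.where(dya > 0)[0]
    for i in pos_x:
        s_a = vals[i, iy0]
        if s_a < abs_level:
            continue
        for jj in pos_y:
            s_b = vals[ix0, jj]
            if s_b < abs_level:
                continue
            s_ab = vals[i, jj]
            if s_ab <= floor * 1.5:
                continue
            d_direct = pseudo_distance(s_ab)
            d_detour = pseudo_distance(s_a) + pseudo_distance(s_b)
            if d_direct > rel_margin * d_detour and d_detour > 0:
                witnesses.append({
                    "corner": (float(dxa[i]), float(dya[jj])),
                    "direct": float(d_direct),
                    "detour": float(d_detour),
                })
                if len(witnesses) >= max_witnesses:
                    break
        if len(witnesses) >= max_witnesses:
            break
    return {
        "level": level,
        "contour_convex": _contour_convexity(field, level * field.values.max()),
        "witnesses": witnesses,
        "n_witnesses": len(witnesses),
    }


# ---------------------------------------------------------------------------
# signal detection and learning curves
# ---------------------------------------------------------------------------

def dprime(similarities, is_different, n_clip: int | None = None) -> float:
    """Sensitivity d' from pairwise similarities.

    The response model is probability matching on 1 - similarity: hits are
    "different" responses to genuinely different pairs, false alarms are
    "different" responses to identical pairs.  Rates are clipped to
    [1/(2N), 1 - 1/(2N)] so perfect separation stays finite.
    """
    sims = np.asarray(similarities, dtype=float)
    diff = np.asarray(is_different, dtype=bool)
    if diff.all() or (~diff).all():
        raise ValueError("need both same and different pairs")
    p_diff = 1.0 - sims
    hit = float(p_diff[diff].mean())
    fa = float(p_diff[~diff].mean())
    n = n_clip or min(diff.sum(), (~diff).sum())
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    hit = min(max(hit, lo), hi)
    fa = min(max(fa, lo), hi)
    return float(_norm.ppf(hit) - _norm.ppf(fa))


def learning_curve(
    structure,
    components,
    hyper,
    n_learners: int = 50,
    seed: int = 0,
    n_particles: int = 100,
    n_blocks: int | None = None,
):
    """Per-block expected error across independently seeded learners.

    Each learner runs the trained particle filter through its own random
    trial order; the error on each trial is 1 - P(correct label) before
    feedback.  Returns a dict with the (n_learners, n_blocks) error
    matrix, per-block means, and Monte-Carlo standard errors.
    """
    from .inference import ParticleFilterConfig, TrainedParticleFilter
    from .tasks import trial_stream
    from dataclasses import replace as _dc_replace

    if n_blocks is not None:
        structure = _dc_replace(structure, n_blocks=n_blocks)
    ss = np.random.SeedSequence(seed)
    block_len = len(structure.block)
    errors = np.zeros((n_learners, structure.n_blocks))
    for li, child in enumerate(ss.spawn(n_learners)):
        rng = np.random.default_rng(child)
        order = trial_stream(structure, rng)
        x = structure.stimuli[order]
        y = structure.labels[order]
        pf = TrainedParticleFilter(
            components, hyper, n_labels=structure.n_labels,
            cfg=ParticleFilterConfig(
                n_particles=n_particles,
                seed=int(rng.integers(2**31 - 1)),
            ),
            track_assignments=False,
        )
        probs = pf.run(x, y)
        p_correct = probs[np.arange(len(y)), y]
        errors[li] = (1.0 - p_correct).reshape(structure.n_blocks, block_len).mean(axis=1)
    return {
        "errors": errors,
        "block_mean": errors.mean(axis=0),
        "block_sem": errors.std(axis=0, ddof=1) / math.sqrt(max(n_learners, 2)),
        "mean_error": float(errors.mean()),
    }
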