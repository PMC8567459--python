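"""Dispersion statistics of natural-style category feature tables.

The hypothesis under test: dimension pairs whose per-category variability
is positively correlated across categories behave as integral dimensions,
while pairs with uncorrelated variability behave as separable.  This
module measures that signature on arbitrary feature tables — per-category
standard deviations, covariance ellipses, and Spearman correlations of
the standard deviations across categories — provides Hu-moment shape
descriptors for binary masks, and generates synthetic category tables
with controlled integral/separable dispersion structure in place of an
external image database.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hu_moments",
    "normalize_features",
    "dispersion_correlations",
    "synth_category_table",
]

CATEGORY_COL = "category"
MIN_OBJECTS_PER_CATEGORY = 4


def hu_moments(mask: np.ndarray) -> np.ndarray:
    """The seven Hu moment invariants of a binary mask.

    Region-based shape descriptors invariant to translation, scaling and
    rotation of the foreground.  Raises on an empty mask.
    """
    from skimage import measure

    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    binary = (mask > 0).astype(float)
    if binary.sum() == 0:
        raise ValueError("mask has no foreground pixels")
    mu = measure.moments_central(binary)
    nu = measure.moments_normalized(mu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return measure.moments_hu(nu)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != CATEGORY_COL]


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring of every feature over all objects.

    Raises on zero-variance columns (they carry no dispersion signal).
    """
    out = table.copy()
    for col in _feature_columns(table):
        sd = table[col].std(ddof=0)
        if not sd > 0:
            raise ValueError(f"feature column {col!r} has zero variance")
        out[col] = (table[col] - table[col].mean()) / sd
    return out


def dispersion_correlations(table: pd.DataFrame):
    """Cross-category correlation of per-category dispersions.

    For every category with at least four objects, the standard deviation
    along each feature is computed; dimension pairs are then scored by the
    Spearman rank correlation of those standard deviations across
    categories.  Also returns 2-D covariance-ellipse parameters per
    category and dimension pair (angle and axis lengths of the
    equiprobability ellipse).

    Returns a dict with ``sd_table`` (category x feature), ``spearman``
    (feature x feature DataFrame) and ``ellipses``.
    """
    feats = _feature_columns(table)
    groups = []
    for cat, grp in table.groupby(CATEGORY_COL):
        if len(grp) < MIN_OBJECTS_PER_CATEGORY:
            warnings.warn(
                f"category {cat!r} has fewer than {MIN_OBJECTS_PER_CATEGORY} "
                "objects and was dropped", stacklevel=2)
            continue
        groups.append((cat, grp))
    if len(groups) < 3:
        raise ValueError("need at least three usable categories")
    sd_table = pd.DataFrame(
        {cat: grp[feats].std(ddof=1) for cat, grp in groups}).T
    sd_table.index.name = CATEGORY_COL
    n_f = len(feats)
    corr = np.eye(n_f)
    for i in range(n_f):
        for j in range(i + 1, n_f):
            rho = stats.spearmanr(sd_table[feats[i]], sd_table[feats[j]]).statistic
            corr[i, j] = corr[j, i] = rho
    ellipses = {}
    for cat, grp in groups:
        per_pair = {}
        for i in range(n_f):
            for j in range(i + 1, n_f):
                cov = np.cov(grp[feats[i]], grp[feats[j]], ddof=1)
                evals, evecs = np.linalg.eigh(cov)
                angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
                per_pair[(feats[i], feats[j])] = {
                    "axes": np.sqrt(np.maximum(evals[::-1], 0.0)),
                    "angle_deg": angle,
                }
        ellipses[cat] = per_pair
    return {
        "sd_table": sd_table,
        "spearman": pd.DataFrame(corr, index=feats, columns=feats),
        "ellipses": ellipses,
    }


def synth_category_table(
    n_categories: int = 50,
    n_per_category: int = 20,
    regime: str = "separable",
    n_features: int = 4,
    seed: int = 0,
    mean_box: float = 5.0,
    narrow_sd: float = 0.1,
    wide_sd: float = 1.0,
) -> pd.DataFrame:
    """Synthetic feature table with controlled dispersion structure.

    * ``integral``: each category draws a single lognormal size scale
      shared by all features, so per-category dispersions are positively
      correlated across dimensions.
    * ``separable``: each category is singly narrow — one randomly chosen
      feature gets the narrow standard deviation, the rest the wide one,
      with independent lognormal jitter — so dispersions are uncorrelated
      across dimensions.
    * ``mixed``: the first half of the features behaves integrally (one
      shared scale), the second half separably.

    Category means are uniform in a box; objects are Gaussian around
    them.  Fully reproducible from ``seed``.
    """
    if regime not in ("separable", "integral", "mixed"):
        raise ValueError("regime must be separable, integral or mixed")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_categories):
        mean = rng.uniform(-mean_box, mean_box, size=n_features)
        jitter = rng.lognormal(0.0, 0.3, size=n_features)
        if regime == "integral":
            scale = rng.lognormal(0.0, 0.8)
            sds = wide_sd * scale * jitter
        elif regime == "separable":
            sds = np.full(n_features, wide_sd)
            sds[rng.integers(n_features)] = narrow_sd
            sds = sds * jitter
        else:
            half = n_features // 2
            scale = rng.lognormal(0.0, 0.8)
            sds = np.empty(n_features)
            sds[:half] = wide_sd * scale * jitter[:half]
            sep = np.full(n_features - half, wide_sd)
            sep[rng.integers(n_features - half)] = narrow_sd
            sds[half:] = sep * jitter[half:]
        draws = mean + sds * rng.standard_normal((n_per_category, n_features))
        for row in draws:
            rows.append({CATEGORY_COL: f"cat{c:03d}",
                         **{f"f{d}": row[d] for d in range(n_features)}})
    return pd.DataFrame(rows)
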