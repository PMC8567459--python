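"""Category-structure fixtures, trial protocols, and synthetic training sets.

Stimuli live on a unit-grid convention: the distance between neighboring
stimuli that differ on one dimension is one unit.  Fixtures whose exact
coordinates are available only graphically in the source experiments (the
condensation/filtration octagon, the six-stimulus free-classification set)
are transcribed layouts: they reproduce every property stated in the text
(balanced labels, boundary orientation, relative category separations) and
are overridable by passing explicit coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import canonical_partition

__all__ = [
    "CategoryStructure",
    "SyntheticTrainingSet",
    "shj_structure",
    "shj_truth_tables",
    "classify_balanced_split",
    "condensation_filtration_structure",
    "biconditional_structure",
    "free_classification_structure",
    "garner_tasks",
    "discrimination_grid",
    "generate_cluster_training",
    "trial_stream",
]


@dataclass(frozen=True)
class CategoryStructure:
    """A task fixture: stimuli, labels, and the block/trial protocol.

    ``block`` lists the stimulus indices shown once per block (with
    repetitions when the protocol presents copies); each block is shuffled
    independently when a trial stream is drawn.
    """

    name: str
    stimuli: np.ndarray                 # (n, D) float coordinates
    labels: np.ndarray | None           # (n,) int labels or None (free sort)
    block: tuple[int, ...]              # stimulus indices composing one block
    n_blocks: int = 1
    dims: tuple[str, ...] = ()
    label_names: tuple[str, ...] = ("A", "B")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", np.asarray(self.stimuli, dtype=float))
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
            if self.labels.shape[0] != self.stimuli.shape[0]:
                raise ValueError("labels and stimuli must align")
        if any(i < 0 or i >= self.stimuli.shape[0] for i in self.block):
            raise ValueError("block indices out of range")

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.shape[0]

    @property
    def dim(self) -> int:
        return self.stimuli.shape[1]

    @property
    def n_labels(self) -> int:
        return 1 if self.labels is None else int(self.labels.max()) + 1


def structure_to_table(structure: CategoryStructure):
    """Serialize a fixture as a plain coordinate/label table (DataFrame)."""
    import pandas as pd

    cols = {f"d{i + 1}": structure.stimuli[:, i] for i in range(structure.dim)}
    if structure.labels is not None:
        cols["label"] = structure.labels
    df = pd.DataFrame(cols)
    df.attrs["name"] = structure.name
    return df


def structure_from_table(table, name: str = "", block=None, n_blocks: int = 1,
                         **kwargs) -> CategoryStructure:
    """Rebuild a fixture from a coordinate/label table."""
    dims = [c for c in table.columns if c != "label"]
    stimuli = table[dims].to_numpy(dtype=float)
    labels = table["label"].to_numpy(dtype=int) if "label" in table.columns else None
    return CategoryStructure(
        name=name or table.attrs.get("name", "fixture"),
        stimuli=stimuli, labels=labels,
        block=tuple(block) if block is not None else tuple(range(len(stimuli))),
        n_blocks=n_blocks, dims=tuple(dims), **kwargs,
    )


def trial_stream(structure: CategoryStructure, rng) -> np.ndarray:
    """Stimulus indices for a full run: each block independently shuffled."""
    rng = np.random.default_rng(rng)
    blocks = [rng.permutation(np.asarray(structure.block)) for _ in range(structure.n_blocks)]
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# SHJ six category types on the 3-bit cube
# ---------------------------------------------------------------------------

_CUBE = np.array(list(itertools.product((0, 1), repeat=3)))


def _within_edge_graph(members: frozenset) -> tuple[int, int, int]:
    """(edge count, max degree, isolated count) of the Hamming-1 graph."""
    mem = sorted(members)
    deg = {m: 0 for m in mem}
    edges = 0
    for a, b in itertools.combinations(mem, 2):
        if bin(a ^ b).count("1") == 1:
            edges += 1
            deg[a] += 1
            deg[b] += 1
    isolated = sum(1 for m in mem if deg[m] == 0)
    return edges, max(deg.values()), isolated


def classify_balanced_split(category_a) -> str:
    """Identify which of the six canonical types a balanced 4/4 split is.

    The 70 balanced splits of the 3-bit cube fall into exactly six
    isomorphism classes under dimension permutation and reflection; the
    class is determined by the within-category Hamming-adjacency graph:

    * I   - each category is a face (4 edges)
    * II  - two disjoint edges per category (exclusive-or)
    * III - a 3-edge chain per category
    * IV  - a 3-edge star per category (linearly separable prototype)
    * V   - two edges sharing a vertex plus an isolated exception
    * VI  - no edges (parity)
    """
    a = frozenset(int(np.dot(s, (4, 2, 1))) for s in category_a)
    if len(a) != 4:
        raise ValueError("category A must contain 4 of the 8 stimuli")
    edges, maxdeg, isolated = _within_edge_graph(a)
    b = frozenset(range(8)) - a
    edges_b, maxdeg_b, _ = _within_edge_graph(b)
    sig = (edges, edges_b)
    if sig == (4, 4):
        return "I"
    if sig == (0, 0):
        return "VI"
    if sig == (3, 3):
        return "IV" if max(maxdeg, maxdeg_b) == 3 else "III"
    if sig == (2, 2):
        return "V" if isolated == 1 else "II"
    raise ValueError(f"not a recognized balanced split (edge signature {sig})")


def shj_truth_tables() -> dict[str, np.ndarray]:
    """Canonical category-A membership (bit triples) for Types I-VI."""
    tables = {
        "I": [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)],
        "II": [(0, 0, 0), (0, 0, 1), (1, 1, 0), (1, 1, 1)],
        "III": [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)],
        "IV": [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)],
        "V": [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 1, 1)],
        "VI": [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)],
    }
    return {k: np.array(v) for k, v in tables.items()}


def shj_structure(
    shj_type: str,
    mapping: tuple[int, int, int] = (0, 1, 2),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_blocks: int = 16,
    copies_per_block: int = 2,
) -> CategoryStructure:
    """One of the six SHJ category structures, embedded continuously.

    The eight binary-corner stimuli are placed at 0/spacing[d] along each
    dimension; ``mapping`` permutes which abstract category dimension maps
    to which stimulus dimension.  Each block presents ``copies_per_block``
    copies of all eight stimuli (16 trials by default).
    """
    shj_type = shj_type.upper()
    tables = shj_truth_tables()
    if shj_type not in tables:
        raise ValueError(f"unknown SHJ type {shj_type!r}; expected I..VI")
    if sorted(mapping) != [0, 1, 2]:
        raise ValueError("mapping must be a permutation of (0, 1, 2)")
    a_set = {tuple(row) for row in tables[shj_type]}
    bits = _CUBE
    # mapping[d] = which abstract dimension stimulus dimension d carries
    abstract = bits[:, list(mapping)]
    labels = np.array([0 if tuple(b) in a_set else 1 for b in abstract])
    stimuli = bits * np.asarray(spacing)
    block = tuple(range(8)) * copies_per_block
    return CategoryStructure(
        name=f"shj_{shj_type}", stimuli=stimuli, labels=labels,
        block=block, n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        meta={"shj_type": shj_type, "mapping": mapping},
    )


# ---------------------------------------------------------------------------
# Condensation versus filtration (transcribed octagon layout)
# ---------------------------------------------------------------------------

# Eight stimuli on a unit-grid octagonal ring.  Filtration boundaries are
# axis-parallel; condensation boundaries run along the diagonals, and the
# condensation category means are farther apart than the filtration means.
_OCTAGON = np.array([
    (0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2),
], dtype=float)

_CF_CONDITIONS = {
    "filtration_dim1": lambda x, y: x < 1.5,
    "filtration_dim2": lambda x, y: y < 1.5,
    "condensation_A": lambda x, y: x - y < 0,
    "condensation_B": lambda x, y: x + y < 3,
}


def condensation_filtration_structure(
    condition: str, n_blocks: int = 16, coordinates: np.ndarray | None = None
) -> CategoryStructure:
    """One condition of the condensation/filtration experiment.

    All four conditions share the same eight coordinates (transcribed from
    the published figure); only the boundary differs.  Each block presents
    all eight stimuli in random order.
    """
    if condition not in _CF_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(_CF_CONDITIONS)}"
        )
    coords = _OCTAGON if coordinates is None else np.asarray(coordinates, dtype=float)
    rule = _CF_CONDITIONS[condition]
    labels = np.array([0 if rule(x, y) else 1 for x, y in coords])
    return CategoryStructure(
        name=f"cf_{condition}", stimuli=coords, labels=labels,
        block=tuple(range(len(coords))), n_blocks=n_blocks,
        dims=("d1", "d2"), meta={"condition": condition, "transcribed": True},
    )


# ---------------------------------------------------------------------------
# Biconditional discrimination (upper half of the Type II problem)
# ---------------------------------------------------------------------------

def biconditional_structure(kind: str = "separable_pairing", n_blocks: int = 15) -> CategoryStructure:
    """Four square-corner stimuli with exclusive-or labels, embedded in 3-D.

    ``separable_pairing`` varies dimensions (1, 3) and ``integral_pairing``
    dimensions (1, 2); the unused dimension is held at zero.  Diagonal
    corners share a label.  15 blocks of all four stimuli by default.
    """
    corners = np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=float)
    labels = np.array([(int(x) ^ int(y)) for x, y in corners])
    if kind == "separable_pairing":
        dims = (0, 2)
    elif kind == "integral_pairing":
        dims = (0, 1)
    else:
        raise ValueError("kind must be 'separable_pairing' or 'integral_pairing'")
    stimuli = np.zeros((4, 3))
    stimuli[:, dims[0]] = corners[:, 0]
    stimuli[:, dims[1]] = corners[:, 1]
    return CategoryStructure(
        name=f"biconditional_{kind}", stimuli=stimuli, labels=labels,
        block=(0, 1, 2, 3), n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        meta={"kind": kind, "varying_dims": dims},
    )


# ---------------------------------------------------------------------------
# Free classification (six stimuli, three critical partitions)
# ---------------------------------------------------------------------------

# Transcribed layout: two columns of three stimuli each.  Within a column
# every stimulus shares the exact dimension-1 value (the one-dimensional
# identity grouping); columns interleave on dimension 2 so that spatially
# compact groups (overall similarity) cut across the columns.
_FREE6 = np.array([
    (1.0, 0.0),   # s0
    (1.0, 1.0),   # s1
    (1.0, 2.0),   # s2
    (2.0, 0.5),   # s3
    (2.0, 1.5),   # s4
    (2.0, 2.5),   # s5
], dtype=float)

def free_classification_structure(
    coordinates: np.ndarray | None = None,
) -> tuple[CategoryStructure, dict[str, tuple[int, ...]]]:
    """Six unlabeled stimuli plus the three critical partitions.

    Returns the structure and a mapping from partition-type name to the
    canonical partition vector: overall similarity groups the spatially
    compact triples, one-dimensional similarity groups triples with small
    (but nonzero) spread on dimension 1, and one-dimensional identity
    groups the exact dimension-1 matches.  Every other partition of the
    six stimuli is classified "other".
    """
    coords = _FREE6 if coordinates is None else np.asarray(coordinates, dtype=float)
    structure = CategoryStructure(
        name="free_classification", stimuli=coords, labels=None,
        block=tuple(range(len(coords))), n_blocks=1, dims=("d1", "d2"),
        meta={"transcribed": True},
    )
    partitions = {
        "overall_similarity": canonical_partition((0, 0, 1, 0, 1, 1)),
        "one_dimensional_similarity": canonical_partition((0, 0, 1, 1, 0, 1)),
        "one_dimensional_identity": canonical_partition((0, 0, 0, 1, 1, 1)),
    }
    return structure, partitions


def partition_type(assignments, partitions: dict[str, tuple[int, ...]]) -> str:
    """Name the partition if it is one of the critical ones, else 'other'."""
    canon = canonical_partition(assignments)
    for name, p in partitions.items():
        if canon == p:
            return name
    return "other"


# ---------------------------------------------------------------------------
# Dimensional-learning tasks: 4x4 discrimination grid and Garner tasks
# ---------------------------------------------------------------------------

def discrimination_grid(
    spacing: float = 1.0, presentations: int = 20
) -> dict[str, object]:
    """16-stimulus 4x4 grid with three training label assignments.

    Returns the grid coordinates, the three ``CategoryStructure`` training
    tasks (one-dimensional on each axis at the median, and the
    four-quadrant two-dimensional task), and the neighbor same/different
    pairs used for discrimination testing (24 adjacent pairs).
    """
    values = np.arange(4) * spacing
    grid = np.array([(x, y) for x in values for y in values])
    median = 1.5 * spacing

    def struct(name, labels):
        return CategoryStructure(
            name=name, stimuli=grid, labels=np.asarray(labels, dtype=int),
            block=tuple(range(16)), n_blocks=presentations, dims=("d1", "d2"),
            label_names=("A", "B", "C", "D")[: int(np.max(labels)) + 1],
        )

    lab1 = [0 if x < median else 1 for x, y in grid]
    lab2 = [0 if y < median else 1 for x, y in grid]
    lab2d = [2 * (x >= median) + (y >= median) for x, y in grid]
    neighbors = []
    for i, (x1, y1) in enumerate(grid):
        for j, (x2, y2) in enumerate(grid):
            if j <= i:
                continue
            dx, dy = abs(x1 - x2), abs(y1 - y2)
            if np.isclose(dx, spacing) and np.isclose(dy, 0):
                neighbors.append((i, j, 0))     # differ along dimension 1
            elif np.isclose(dy, spacing) and np.isclose(dx, 0):
                neighbors.append((i, j, 1))     # differ along dimension 2
    return {
        "grid": grid,
        "train_1d_dim1": struct("grid_1d_dim1", lab1),
        "train_1d_dim2": struct("grid_1d_dim2", lab2),
        "train_2d": struct("grid_2d", lab2d),
        "neighbor_pairs": neighbors,
        "median": median,
    }


def garner_tasks(
    train_spacing: float = 1.0, n_blocks: int = 9, test_spacing_factor: float = 2.0
) -> dict[str, CategoryStructure]:
    """Garner filtering and baseline tasks in a 3-D embedding.

    Training uses a 2 x 2 square varying dimensions (1, 2) with the
    boundary on dimension 1 (9 blocks of all four stimuli).  At test the
    relevant dimension 1 is combined with a novel dimension 3; the
    filtering task classifies all four test stimuli by dimension 1, while
    each baseline task uses the two stimuli of a single dimension-3 value.
    Test spacing is doubled relative to training.
    """
    s = train_spacing

    def embed(points2d, dims):
        out = np.zeros((len(points2d), 3))
        pts = np.asarray(points2d, dtype=float)
        out[:, dims[0]] = pts[:, 0]
        out[:, dims[1]] = pts[:, 1]
        return out

    train_pts = [(0, 0), (0, s), (s, 0), (s, s)]
    train_labels = [0, 0, 1, 1]
    t = test_spacing_factor * s
    test_pts = [(0, 0), (0, t), (t, 0), (t, t)]
    test_labels = [0, 0, 1, 1]

    tasks = {
        "training": CategoryStructure(
            name="garner_training", stimuli=embed(train_pts, (0, 1)),
            labels=np.array(train_labels), block=(0, 1, 2, 3),
            n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        ),
        "filtering": CategoryStructure(
            name="garner_filtering", stimuli=embed(test_pts, (0, 2)),
            labels=np.array(test_labels), block=(0, 1, 2, 3),
            n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        ),
        # baseline blocks match the filtering block length: each of the two
        # stimuli appears twice per block (equal trials per block, as in
        # standard Garner designs)
        "baseline_low": CategoryStructure(
            name="garner_baseline_low", stimuli=embed([test_pts[0], test_pts[2]], (0, 2)),
            labels=np.array([0, 1]), block=(0, 1, 0, 1),
            n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        ),
        "baseline_high": CategoryStructure(
            name="garner_baseline_high", stimuli=embed([test_pts[1], test_pts[3]], (0, 2)),
            labels=np.array([0, 1]), block=(0, 1, 0, 1),
            n_blocks=n_blocks, dims=("d1", "d2", "d3"),
        ),
    }
    return tasks


# ---------------------------------------------------------------------------
# Synthetic Gaussian-cluster training sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrainingSet:
    """Seeded Gaussian-cluster draws with per-cluster contexts."""

    points: np.ndarray            # (n, D)
    contexts: np.ndarray          # (n,) int, one context per generating cluster
    cluster_ids: np.ndarray       # (n,) int generating cluster
    means: np.ndarray             # (K, D)
    covariances: np.ndarray       # (K, D, D)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.points.shape[0]


def _rot(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def generate_cluster_training(
    spec=None,
    seed: int = 0,
    preset: str | None = None,
    n_per_cluster: int = 30,
    wide_sd: float = 1.0,
    axis_ratio: float = 10.0,
    extent: float = 3.0,
) -> SyntheticTrainingSet:
    """Draw a synthetic training set from Gaussian clusters.

    Either pass ``spec`` as a list of (mean, cov, n, context) tuples, or a
    named ``preset``:

    * ``six_axis_aligned`` - six clusters, three elongated horizontally and
      three vertically, axis ratio 10:1, 30 points each
    * ``ten_axis_aligned`` - ten clusters, five per orientation
    * ``six_rotated`` - the six-cluster preset rotated 45 degrees
    * ``natural_like`` - axis-aligned singly narrow categories mixed with
      isotropic ones (a synthetic stand-in for natural-image statistics)

    Each cluster is its own learning context.
    """
    rng = np.random.default_rng(seed)
    if spec is None:
        if preset is None:
            raise ValueError("pass either spec or preset")
        narrow_sd = wide_sd / axis_ratio
        h = np.diag([wide_sd**2, narrow_sd**2])
        v = np.diag([narrow_sd**2, wide_sd**2])
        iso = np.diag([wide_sd**2, wide_sd**2])
        spec = []
        if preset in ("six_axis_aligned", "six_rotated"):
            n_h, n_v = 3, 3
        elif preset == "ten_axis_aligned":
            n_h, n_v = 5, 5
        elif preset == "natural_like":
            n_h, n_v = 3, 3
        else:
            raise ValueError(f"unknown preset {preset!r}")
        covs = [h] * n_h + [v] * n_v
        if preset == "natural_like":
            covs += [iso] * 3
        k = len(covs)
        # evenly offset parallel clusters (horizontal types stacked in y,
        # vertical types in x), with a little jitter: the arrangement fills
        # the evaluation window so both orientations overlap its center
        half = extent / 2.0
        off_h = np.linspace(-half, half, n_h) if n_h > 1 else np.zeros(1)
        off_v = np.linspace(-half, half, n_v) if n_v > 1 else np.zeros(1)
        means = []
        for o in off_h:
            means.append((0.0, o))
        for o in off_v:
            means.append((o, 0.0))
        while len(means) < k:
            means.append((0.0, 0.0))
        means = np.asarray(means, dtype=float)
        means += rng.uniform(-0.25, 0.25, size=means.shape)
        if preset == "six_rotated":
            r = _rot(45.0)
            covs = [r @ c @ r.T for c in covs]
            means = means @ r.T
        spec = [(means[i], covs[i], n_per_cluster, i) for i in range(k)]

    points, contexts, cluster_ids, means, covs = [], [], [], [], []
    for ci, (mean, cov, n, context) in enumerate(spec):
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        draws = rng.multivariate_normal(mean, cov, size=n)
        points.append(draws)
        contexts.extend([context] * n)
        cluster_ids.extend([ci] * n)
        means.append(mean)
        covs.append(cov)
    return SyntheticTrainingSet(
        points=np.concatenate(points, axis=0),
        contexts=np.asarray(contexts, dtype=int),
        cluster_ids=np.asarray(cluster_ids, dtype=int),
        means=np.stack(means),
        covariances=np.stack(covs),
        seed=seed,
    )
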