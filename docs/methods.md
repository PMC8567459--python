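# Methods

## The model

`refreshcat` implements a hierarchical Bayesian nonparametric account of
perceptual categorization by pure family resemblance.  Items
x ∈ ℝᴰ are grouped into clusters; each cluster k is a multivariate
Gaussian with mean μ_k and covariance Σ_k; and clusters are themselves
grouped into *components* — higher-level mixture elements that describe
what kinds of cluster covariances occur across learning contexts.  For a
cluster assigned to component j:

    μ_k ~ N(ω, σ_r² I)
    Σ_k ~ IW_{v_j}(Φ_j)
    Φ_j ~ IW_{v_t}(I)
    v_j ~ TN(v_t, v_t²), truncated below at D

Item→cluster assignments follow a Chinese-restaurant-process prior with
dispersion α within each context; cluster→component assignments follow a
two-level (hierarchical) CRP in which a component already used in the
current context is reused with probability proportional to its context
count plus α_c times its global weight, and a brand-new component enters
with global weight proportional to α_g.  Cluster means are independent
of cluster covariances, and every cluster holds items of a single
category label.  Because the mean prior and the top-level scale are
isotropic, nothing in the untrained model distinguishes any rotation of
the coordinate axes: dimensional structure can only be *learned*, from
the covariances of experienced clusters.

Category decisions average over assignment uncertainty: P(label L | x)
sums the assignment-posterior mass of existing clusters labeled L plus
the new-cluster mass times a uniform label base rate (a fresh cluster may
carry any label a priori; see "Design choices").

Pairwise similarity (the probability that x* belongs to the cluster that
generated x) is the posterior average, over hypotheses h about which
cluster x joined, of the predictive density of x* under h *relative to
its value at x*.  The ratio form keeps similarity in [0, 1] with
s(x, x) = 1; it can be symmetrized by averaging the two role
assignments.  The hypothesis set contains the posterior's instantiated
clusters plus one fresh-cluster option per component — "the clusters
under consideration" — except in the discrimination-training analysis,
where the judged pair is a new event and only fresh-cluster hypotheses
under the learned components apply (see below).

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| α | 10 | item→cluster dispersion; high, favors many clusters |
| α_c | 0.001 | component reuse within a context; low, favors one component per experimental context (set to ∞ to remove the contextual prior) |
| α_g | 1 | global new-component dispersion (0 = fixed finite set) |
| v_t | 30 | top-level IW degrees of freedom; also mean and sd of each v_j |
| σ_r² | 1 (full model) / 0.1 (trained approximation) / 100 (free sorting) | variance of the cluster-mean prior |
| ω | mean stimulus of the task | prior mean of cluster means |

The trained approximation replaces the IW uncertainty of each component
with a single fixed diagonal covariance.  The named sets use wide
standard deviation 1/c_d on dimension d, singly narrow entries at 10% of
the wide value, and doubly narrow entries at 30% (at 10% the doubly
narrow components would dominate the singly narrow ones, and their 2-D
projections would be near-isotropic and crowd out the aligned pair).
Per-simulation regimes (component subsets and c_d values) are registered
in `refreshcat.components.regime_registry`; larger c_d mean smaller
expected clusters and faster learning.

A consequence of the top-level prior worth knowing: IW_{30}(I) confines
the diagonal entries of Φ_j near 1/33, so the *component* level cannot
represent strongly elongated unit-scale covariances — the posterior
prefers a single low-dof (vague) component over two specialized ones.
Dimensional alignment in the full model therefore lives in the learned
*clusters*, which is why the similarity hypothesis set includes them.

## Inference engines

* **Exact enumeration** (n ≤ 8, fixed components): every set partition is
  scored by the CRP prior, a Dirichlet-multinomial closed form summing
  the two-level CRP over component assignments, and per-cluster marginal
  likelihoods with the mean integrated out analytically (everything
  factorizes over dimensions for diagonal components).
* **Collapsed Gibbs** (fixed components): per-item and per-cluster
  conditionals over (z, u) only; targets the same posterior as the exact
  engine and is cross-checked against it to total variation < 0.05.
* **Full-hierarchy Gibbs**: per-item z updates use an
  auxiliary-parameter scheme (3 fresh candidate clusters/components drawn
  from the prior) for the non-conjugate new-cluster case; μ_k and Σ_k
  have conjugate updates; u_k mixes the hierarchical-CRP prior with the
  IW likelihood of Σ_k; Φ_j uses Metropolis–Hastings with a Wishart
  proposal centered on the current value (dof 60), and v_j a Gaussian
  random walk on log(v_j − D) (sd 0.4).  Chains are initialized with one
  cluster and one component per item.  Defaults are 1,050 samples with a
  50-sample burn-in; the bundled experiments use shorter chains
  (typically 250 samples, thinned by 2) as their default problem sizes.
* **Particle filter** (trained approximation): Rao-Blackwellized —
  particles carry only discrete assignments, means are collapsed.  Per
  trial the mixture label predictive is reported (with the clustering
  conditioned on the probe stimulus jointly across particles), the label
  is revealed, each particle propagates by the exact conditional
  posterior over (cluster, component) — the optimal proposal — weights
  multiply by the particle's marginal predictive, and systematic
  resampling triggers at effective sample size below half the particle
  count.  100 particles by default; one particle gives the
  limited-working-memory regime.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-learner streams are spawned from a master
`SeedSequence`.

## Synthetic data

The cluster-training generator emulates dimension-aligned category
experience: presets draw 30 points per cluster from Gaussians with a
10:1 axis ratio (three horizontal plus three vertical clusters, five
plus five, or the six-cluster layout rotated 45°), each cluster in its
own learning context, with cluster centers at evenly spaced offsets
(±jitter) so both orientations overlap the evaluation window.  The
dispersion-statistics generator draws category means uniformly in a box
and per-category feature standard deviations either from a shared
lognormal scale (integral regime) or as independent singly narrow
choices (separable regime).  These generators reproduce the *structure*
the analyses need (aligned covariance types; correlated versus
uncorrelated dispersions) but none of the photographic nuisance of real
image databases — passing tests show the machinery recovers planted
structure, not that real images contain it.

## Numerical choices

Probability arithmetic is in log space throughout; SPD checks factorize
with a 1e-10 diagonal jitter fallback; inverse-Wishart and Wishart draws
use Bartlett decompositions.  Partitions are canonicalized as restricted
growth strings (cluster ids in order of first appearance, 0-based).
Minkowski-metric fits grid-search the exponent (0.25–4, coarse then
0.05 steps), the dimension weight and optionally an axis rotation, with
the link handled nonparametrically by isotonic regression so the
exponent is identified by contour shape alone, not by the radial decay
profile.  Triangle-inequality witnesses use a link-free test: the field
is inverted along one axis to calibrate a pseudo-distance (exact for any
norm-based similarity with a monotone decreasing link), and a corner
triple is a witness when the direct pseudo-distance exceeds the detour
by ≥ 15% — forward fields with exponent ≥ 1 produce none, exponents < 1
do.  d′ clips hit and false-alarm rates to [1/(2N), 1−1/(2N)].

## Design choices made where the design was open

* **New-cluster label base rate**: uniform over the task's label set —
  the minimal symmetric assumption, required because clusters are
  single-category and the new-cluster option must carry label mass.
  The factor 1/L also multiplies new-cluster options whenever a label is
  observed, in all three engines (they are cross-validated against each
  other, so any asymmetry would surface as a total-variation gap).
* **Biconditional discrimination** runs in the 2-D space of the varying
  dimension pair with the exact projections of {Ψ_wwn, Ψ_nnw}.  In the
  full 3-D embedding the constant third dimension hands the
  narrow-on-that-dimension component a decisive density bonus and the
  integral condition flatlines at chance (its two diagonal category
  prototypes coincide); the projected comparison restores the intended
  contrast between an isotropic pair (wide + small) and the singly
  narrow pair.
* **Discrimination training (4×4 grid)**: spacing 0.06 with 10
  presentations per stimulus and α = 1, averaged over three repetitions.
  The spacing sits at the scale of the untrained prior's clusters (so
  training can both shrink expected cluster size and elongate clusters
  along the irrelevant dimension), and a spacing beyond the natural
  cluster scale requires a lower dispersion parameter, else each
  category shatters into isotropic singletons.  Similarity for the
  judged pair uses fresh-cluster hypotheses under the learned
  components: the pair is a new observation event, and this matches the
  observed pattern of a boost on both dimensions with only a small
  boundary-crossing effect.
* **Garner interference**: training square spacing 0.02 with the test
  spacing doubled, chosen so the untrained filtering condition clears a
  75% late-block accuracy criterion; baseline blocks present each of
  their two stimuli twice so every task has equal trials per block.  The
  untrained condition runs the *full* hierarchy sequentially (short
  Gibbs re-fit before each trial), because the interference mechanism is
  covariance inference during the task: irrelevant-dimension variation
  merges same-label stimuli into displaced, diffuse clusters.  The
  trained condition collapses every-10th component posterior sample to
  its modal covariance and runs the particle filter.  Accuracy is
  summarized over the final two-thirds of blocks.
* **SHJ block order**: an unconstrained random permutation per block
  (the restricted-randomization rule of the source protocol is
  unspecified); a scheduler hook exists on `trial_stream`.
* **Transcribed fixtures**: the condensation/filtration octagon and the
  six-stimulus free-sorting set are unit-grid layouts reconstructed from
  graphical sources; they satisfy every textual constraint (balanced
  4/4 labels, axis-parallel versus diagonal boundaries, condensation
  means farther apart; three critical 3+3 partitions with exact
  one-dimensional identity matches) and can be overridden by passing
  explicit coordinates.
* **The six SHJ truth tables** are derived, not transcribed: the 70
  balanced splits of the 3-bit cube form exactly six isomorphism
  classes, identified by their within-category Hamming-adjacency graphs
  (I: faces; II: two disjoint edges; III: 3-edge chains; IV: 3-edge
  stars; V: two edges sharing a vertex plus an isolated exception;
  VI: no edges).

## Problem sizes

Default Monte-Carlo budgets are reduced: typically 100 simulated
learners per condition (200 for single-particle runs), 8–16 blocks per
task, Gibbs chains of 150–250 samples for training runs, 6,050 sweeps
for the collapsed-sampler oracle checks, and 10,000 particles for the
particle-filter oracle checks.  `scripts/acceptance.py` and the test
suite use exactly these defaults; pass larger values through the
experiment functions' keyword arguments for higher-precision runs.

## Known limitations

* The component level does not learn large-scale covariance structure
  under the stated top-level prior (see above); trained-approximation
  simulations therefore take their component sets from the named
  registry rather than from Gibbs output, except in the Garner analysis
  where the learned modal covariances are small by design.
* Fixed-component engines require diagonal covariances (the trained
  sets are diagonal by construction); the full Gibbs hierarchy is
  unrestricted.
* Response times are outside the model; all accuracy-based orderings are
  qualitative and stochastic, with tolerances set for the default
  budgets.
* Exact inference caps at 8 items (Bell growth); the engines above that
  size are approximate by necessity.
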