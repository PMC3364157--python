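# Methods

## Model and procedure

All statistics operate on a symmetric distance matrix δ with zero diagonal;
no distributional assumptions are made about the underlying data. For a
partition C₁…C_k, the geometric variability V̂δ(C_j) (half the mean squared
within-group distance), the between-group squared distance Δ̂²_ij and the
proximity φ̂²(g₀, C_j) are plug-in estimators of squared distances to and
between group "centers" that exist in the Euclidean embedding of δ even
when no coordinates are available. When δ is Euclidean-embeddable, Δ̂²
equals the squared distance between group centroids and φ̂² the squared
distance from g₀ to a centroid.

The INCA statistic W(g₀) minimizes
L = Σ α_i φ̂²_i − Σ_{i<j} α_i α_j Δ̂²_ij over affine weights (Σ α_i = 1).
The weights are *not* constrained to be non-negative: the minimizer over
the affine hull is exactly the squared orthogonal height of g₀ above the
hyperplane through the k centers, which is the geometric quantity the
method uses. The stationary point solves the bordered Lagrange system

    [ Δ̂²  1 ] [ α ]   [ φ̂² ]
    [ 1ᵀ   0 ] [ λ ] = [ 1  ],

one LU factorization serving all units scored against the same partition.
On the affine constraint the objective is convex for Euclidean-embeddable
δ (−Δ̂² is conditionally positive definite there), so the stationary point
is the minimum; the test suite cross-checks it against direct numeric
minimization on random instances.

Conventions adopted where the formulas leave freedom:

- **Self-inclusion.** A unit scored against a partition it belongs to uses
  its distance row as-is, zero self-distance included; there is no
  leave-one-out. This matches interfaces in which a unit's identity is not
  carried alongside its distances.
- **k = 1** collapses to W = φ̂²₁, U = (0).
- **Numerical floor.** W within −1e−8 (relative to the largest proximity)
  of zero is clamped to 0. Larger negative values can only arise for
  non-Euclidean δ and are kept, with the result flagged; negative Δ̂²
  entries likewise warn rather than error.
- **Degeneracy.** If the number of clusters k reaches p + 1, where p is the
  Euclidean embedding dimension of δ, the centers' hyperplane fills the
  space and W ≡ 0 for every unit: the statistic carries no information.
  Singular Lagrange systems fall back to the pseudo-inverse and mark the
  result degenerate instead of failing.
- **Allocation** is argmin U_j with ties broken toward the smallest cluster
  index.

## INCA index and the number-of-clusters rule

For each cluster C_j, every unit's height W_{C_j}(g) is computed with
respect to the remaining clusters; the threshold W̄_{C_j} is the maximum
height over units outside C_j, and members strictly above it count as well
classified (ties count as poorly classified). INCA_k is the mean of
N_j / n_j. For k = 2 the reduced reference is a single cluster and the
height degenerates to the proximity to it.

Partitions for k = 2…K come from PAM (classical BUILD + SWAP on the
distance matrix, deterministic) or from agglomerative linkage trees
(average/UPGMA, single, complete, weighted/WPGMA, and Ward — the
Lance-Williams Ward recurrence applied to squared dissimilarities) cut at
each k; user-supplied label columns are also accepted.

The decision rule returns the k *before* the largest eligible decrease of
the curve. A drop at k is eligible when k lies in the initial
non-increasing run of the curve (a structure already resolved at k = 2
collapsing as it is over-split) or when the index has just risen to k (a
peak). Drops on the falling flank after a later hump are over-partitioning
artifacts — linkage cuts at large k isolate stray units, which briefly
inflates the index — and are ignored. If the whole curve stays below the
structure threshold (default 0.2, configurable) the verdict is "no cluster
structure". The threshold and the eligibility refinement are choices of
this package; the underlying heuristic ("large decrease", "low and
constant") has no canonical numeric form.

**A note on exchangeable data.** Under self-inclusion, a member's proximity
to its own group is systematically smaller than an outsider's by about
(mean δ²)/n_j. For *exactly* equidistant units (a measure-zero
configuration) this gap is the only signal and the index is driven to 1;
for any realistic exchangeable data the sampling fluctuations of the
distances dominate the gap and the index is near 0, which is the regime the
no-structure verdict relies on. Group sizes of a few dozen or more keep the
gap negligible.

### Noise units

With an integer bound L, any unit that falls — in *any* of the scanned
partitions — into a cluster of size ≤ L is flagged as noise; the remaining
units are re-clustered and a second curve reported. The inclusive
any-partition reading is used because linkage trees isolate scattered units
at different k. In module-simulation experiments (three modules plus 10%
uncorrelated genes, L = 2) the flagged set consists exclusively of true
noise genes, typically ~10% of them; flagging is conservative, so some
scattered units always survive, and the denoised curve sharpens but does
not perfectly restore the clean-data shape.

## Typicality test

The null "g₀ is typical of C₁…C_k" is assessed by comparing W(g₀) with the
bootstrap distribution of W over the reference units: each of 10·P
repetitions draws np units with replacement from the pooled clusters (all n
units, including any duplicate of g₀), and rejects when the empirical
p-value #{W_b ≥ W₀}/np falls below α. The plain proportion with the strict
≥ comparison is the default; the (1 + count)/(np + 1) estimator is
available as an option. The reported "percentage under alpha" is the share
of rejecting repetitions; the overall verdict declares g₀ atypical at ≥ 50%
(configurable), since a single summary verdict is convenient even though
the percentage is the primary output. Defaults np = 1000, α = 0.05, P = 1.
Repetition r draws from an independent RNG substream spawned from
(seed, r), so results are reproducible and independent of repetition order.

Because W is compared with the in-sample height distribution, roughly an α
fraction of genuine members — the most outlying ones — are rejected per
repetition; this is the test's designed type-I level, verified in the suite
against held-out cluster members. "Typical member" demonstrations therefore
use a representative (median-membership) unit rather than an arbitrary one.

## Distances

- **Gower** (mixed variables): similarity per Gower's coefficient —
  range-normalized agreement for continuous variables, presence matches
  for binary ones (absence–absence pairs drop out of numerator *and*
  denominator), state matches for qualitative ones — and
  d = √(2(1 − s)), which is Euclidean-embeddable, unlike 1 − s. Missing
  entries remove their term from both numerator and denominator (Gower's
  weighted coefficient); a pair with no comparable variable is an error. A
  constant continuous variable contributes full agreement (the limit of
  |Δx|/R as R → 0 for identical observed values).
- **Bhattacharyya** (frequency rows): arccos of the Bhattacharyya
  coefficient, clamped to [0, 1] before the arccos.
- **Pairwise Mahalanobis**: covariance of the pooled table;
  pseudo-inverse with relative eigenvalue cutoff 1e−10 when singular, which
  projects out collinear directions.
- **Correlation**: d = √(2(1 − r)) by default (keeps W ≥ 0); the plain
  1 − r is available via `transform="linear"`.

Binary coding is 1 = presence. Units are rows everywhere; the CLI offers
`--transpose` because expression tables conventionally store genes in rows.
Any precomputed distance matrix is accepted by every statistic.

## Synthetic data generators

`simulate_modules` emulates module-structured expression data: one latent
profile (eigengene) per module across samples, member genes
r·profile + √(1 − r²)·noise with r ~ U(cor_lo, cor_hi), noise genes pure
standard normal (signed-network convention: member correlations are
positive). Two design choices are deliberate:

- Eigengenes are mutually orthogonal unit-variance profiles (a random
  rotation frame) rather than independent Gaussian draws. Independent
  draws occasionally produce strongly correlated latent profiles, which
  makes the difficulty of the problem bimodal across seeds; orthogonality
  matches the intent that modules be distinct.
- The membership range defaults to (0.5, 0.9), calibrated once so that the
  INCA index of the true partition of a 480/360/360-gene, 100-sample
  simulation lies around 0.9 (10-seed range 0.87–0.97) — the
  operating point reported for this kind of module simulation. The
  generator does not attempt byte-level replication of any external
  simulator's RNG stream.

`simulate_time_course` draws 6-timepoint profiles around eight fixed
templates (constant; slowly increasing — deliberately the class closest to
the constant one; flat-then-rising; peak at t2; peak at t5; dip at t3;
cyclic max t2/min t5; dip at t2 then flat), plus i.i.d. Gaussian noise.
The default noise_sd = 0.15 is calibrated so that constant-profile genes
tested against the seven other classes are unambiguously atypical; at
0.2 the margin erodes. Because the profiles live in only 6 dimensions,
any distance with a 6-dimensional Euclidean embedding is degenerate for 7
reference clusters (k ≥ p: every height is exactly 0). The time-course
distance therefore defaults to the square root of the Euclidean distance —
the classical snowflake transform, whose Euclidean embedding is
high-dimensional — restoring a meaningful height statistic. This replaces
the shape-alignment distance used in the original time-course experiments,
which is out of scope here.

`simplex_fixture` places clusters at simplex vertices with a probe at a
known orthogonal height h, giving the exact oracle W = h² at zero spread.

What the generators do *not* emulate: heavy-tailed expression noise,
sample-level batch effects, gene–gene correlations beyond the one-factor
module structure, and unequal within-class time-course variances. Passing
tests demonstrate correctness of the statistics and calibrated behavior
under these idealized conditions, not performance on real arrays.

## Problem sizes

The test suite and the acceptance script run three-module simulations with
up to 1200 genes × 100 samples, time-course sets of 120 × 6, bootstrap
sizes np ≤ 1000 with 10 repetitions, and ≥ 200 randomized oracle
instances — sizes chosen to exercise every code path at full method
fidelity while keeping a complete run in the order of seconds.

## Known limitations

- The k ≥ p degeneracy is inherent to the method: with many clusters on
  low-dimensional (or low-rank, e.g. correlation-based) embeddings, W
  carries no signal. Results are flagged, not repaired.
- PAM is the classical O(k(n−k)²)-per-sweep algorithm; for n in the many
  thousands prefer a linkage method or precomputed partitions.
- The noise filter only flags units that some partition isolates; diffuse
  noise that always merges into large clusters is not detected.
- The number-of-clusters rule is a heuristic on a scalar curve; adjacent k
  with near-equal drops (differences within ~0.01 of the index) are
  genuinely ambiguous and worth inspecting via the reported curve.
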