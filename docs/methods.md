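# Methods

This note records the model, the numerical and design choices, and the
known limitations of the package.

## Signed distances

The LCDM distance of a GM voxel is the minimum Euclidean distance from
its centroid to the set of *vertices* of the triangulated GM/WM surface
(the mesh is assumed dense, so vertex distance and surface distance agree
to within the vertex sampling of the mesh).  Voxel indices are 0-based
with the centroid at `origin + (index + 0.5)·h`; all lengths are in mm.
Nearest-vertex queries go through a k-d tree whose distances are verified
(by test) to equal the exhaustive scan exactly; an accelerated structure
that changed distances even in the last bit would silently break the
"terminal censoring step equals pooled analysis" guarantee downstream.

The sign of a distance is not derivable from the distance itself, and the
convention here is: sign = sign of the dot product between
(centroid − nearest vertex) and the area-weighted average normal of the
faces incident to that vertex, with face normals oriented from WM toward
GM; a zero dot product is assigned positive.  This rule is local,
deterministic, and flips coherently when the mesh orientation is
reversed.  Other sign rules (nearest-face normal, winding number) exist;
the vertex-normal rule was chosen because it needs no well-formed closed
mesh and behaves sensibly on open phantom surfaces.

Voxels mislabeled as GM on the wrong side of the surface are *not*
specially corrected; the retention filter (closed interval, default
[−0.5, 5.5] mm) is the only guard.  The filter reports the removed
fraction; on clean data it should be well under 1%.

## Censoring

Thresholds are γ_k = k·δ for k = 0 … ⌊d_max/δ⌋ with defaults δ = 0.01 mm
and d_max = 5.5 mm.  δ should sit between the decimal precision of the
distances and the voxel resolution: finer wastes computation on redundant
steps, coarser quantizes the reported onset distances.  The censored set
keeps d ≤ γ_k (closed inequality; boundary values retained).  Censoring
commutes with pooling, censored sets are nested in k, and at the last
step the censored analysis *is* the pooled analysis — the sweep
implementation preserves input order so the last-step p-values are
bit-identical to directly computed pooled p-values.

Steps below `reliable_from` (default 1.0 mm) are flagged, never dropped:
near the surface the mislabeled-voxel problem makes results less
trustworthy, but the flag is a reporting annotation so users can make
that call per dataset.  Left and right hemispheres are always pooled and
swept separately.

## Test battery

The data regime is pooled samples with thousands of voxels, so all rank
tests use midranks with tie-corrected variance and the large-sample
normal / chi-square approximations; exact small-sample modes exist only
as oracles in the test suite.  The Wilcoxon normal approximation omits
the continuity correction so that the two one-sided p-values are exactly
complementary (p_less + p_greater = 1), which is how the one-sided
curves are plotted against both the 0.05 and the 0.95 reference lines.
"ANOVA F without homogeneity of variances" is implemented as Welch's
heteroscedastic one-way test (Welch–Satterthwaite); the homoscedastic
variant is the classical F.  The two-sample Kolmogorov–Smirnov test is
provided but documented as misleading inside a sweep: censored sets only
grow, so once the K–S statistic fires it tends to stay significant at
all later steps.

A test that cannot be computed at a step (empty censored group,
insufficient size, zero spread) yields NA at that step; the sweep never
aborts, and significance runs cannot span NA steps.  A fully degenerate
comparison in which every value is identical across groups is reported as
p = 1 (zero statistic) rather than NA, since the null is then trivially
compatible.

Multiplicity: Holm's step-down adjustment is applied across the pairwise
comparisons *within* one censoring step (when enabled).  No adjustment is
made across censoring steps: consecutive steps share almost all of their
data, the analyses are deliberately pointwise, and the quantity of
interest is the consecutive range of distances over which significance
persists, as in distance-indexed spatial statistics generally.

Run extraction reports maximal runs of consecutive steps with p < α
(and, for one-sided curves, p > 1 − α as the opposite direction).
`min_run_steps` (default 5, i.e. 0.05 mm at δ = 0.01) discards isolated
excursions; because consecutive steps are highly correlated, chance
excursions can persist for a few steps, so onset distances should be read
from the dominant persistent run, not the first excursion.  The default
is logged in the output and should be scaled with δ.

Kernel density export uses a Gaussian kernel with the normal-reference
(Scott) bandwidth, recorded in the output; the evaluation grid spans the
retention interval extended four bandwidths past the data so each density
integrates to 1 on the grid.  Degenerate groups (n < 2 or zero spread)
fall back to a fixed 0.1 mm bandwidth.

## Simulator

The generator emulates the empirical stack structure of a real cortical
region: distances partitioned into half-millimeter stacks have a
decreasing frequency profile, captured by the printed reference
probability vector over stacks 0…11.  A draw is d = (J + U)/2 with
J from the stack vector and U ~ Unif[0, r); the half-open interval makes
⌊2d⌋ recover J exactly at r = 1, which the goodness-of-fit tests rely
on.  Support is [0, (m + r)/2]; for the reference specification,
[0, 6.0] mm.

The printed three-decimal probability vectors are used directly
(renormalized) rather than reconstructing integer voxel counts: the
underlying counts are not recoverable from the rounded values (the
stated maximum count, 2059, is inconsistent with 0.177 × 11659 ≈ 2064 at
the printed precision).  The η machinery — replace counts ν_i by
|ν_i − η|, sort descending, append the removed mass as a remainder stack,
normalize — is implemented literally as stated and validated on a hand
toy example, but the alternative sample Z defaults to the printed
13-entry vector, which the η = 50 derivation does not exactly reproduce
under any resolution of the rounding.  The alternative vector has 13
entries (one more stack than the reference) and is used as given; it
sums to 1.000.  The stack-interval description
admits negative distances for stack 0, but the generator as defined
produces only non-negative values; the generator's definition wins.

Two structural consequences of the model worth knowing:

* With r > 1 (sample Y), the extra within-stack spread accumulates mass
  just past each half-millimeter stack boundary, so one-sided tests
  against Y gain power in bands *starting just above* 0.5, 1.0, 1.5, …
  mm.  At a threshold γ exactly on a stack boundary the censored
  reference and censored widened samples are the *same* truncated
  uniform mixture, so the boundary step itself has no power — the
  reported power is "around", not "at", the half-millimeter multiples.
* The tail-shifted Z is distinguishable from the reference X only at
  thresholds ≥ ~4 mm, and Z-vs-Y one-sided comparisons beyond 4 mm have
  virtually zero power because Z's tail mass and Y's overlap
  accumulation balance.

Seeding: one root `SeedSequence` per scenario replication, spawned into
one child stream per sample; the Monte Carlo harness spawns one child
per replication from its root seed.  Identical seeds give identical
samples bit-for-bit.

## Monte Carlo harness

Defaults follow the simulation design: N_mc = 1000 replications, three
samples of n = 10000, α = 0.05.  Rejection is counted as p < α
strictly; one-sided curves are additionally counted against the 1 − α
mirror.  Confidence bands are a normal-approximation binomial interval
for rejection proportions and a t-interval for mean p-values — the band
construction is this package's choice, made explicit because bands can
be drawn many ways.  Replication-level NA steps are excluded from that
step's aggregate and the effective count is reported.

The harness accepts a step subset because the size/power claims are
per-step: evaluating three or five γ values checks the same claims at a
fraction of the cost of the 551-step grid.  The shipped experiments use
n = 10000 per sample with N_mc = 1000 (null) and N_mc = 200
(alternative) at a handful of thresholds; the reduced-scale calibration
test in the suite uses n = 1000 and N_mc = 200.

## What the synthetic data does and does not show

The simulator reproduces the distance-level generative structure of a
real cortical region — the stack frequency profile and its deformations —
but not the 3D spatial correlation of neighboring voxels, the
subject-level clustering inside pooled groups, or segmentation error.
Passing the calibration tests shows the censoring-sweep machinery is
statistically sound under independent sampling from realistic marginal
distributions; it does not by itself certify behavior under the spatial
dependence of real LCDM data, whose effect must be argued separately
(robustness of pooled-distance tests to that dependence is established
in the morphometry literature).  Real-cohort onset distances (e.g., at
which depth a patient group separates from controls) depend on subject
data not shipped here and are out of scope.

## Known limitations

- Vertex-based (not exact point-to-surface) distances: on coarse meshes
  the positive bias equals the local vertex sampling; phantoms bound it
  by the mesh chord length.
- The sign rule can misclassify centroids near high-curvature saddles of
  a coarse mesh; the retention filter is the practical guard.
- NIfTI input assumes an axis-aligned affine (isotropic spacing,
  translation-only origin); oblique acquisitions must be resampled
  upstream.
- The Lilliefors p-value is table-based and bounded below at 0.001.
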