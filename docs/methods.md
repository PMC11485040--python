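# Methods

## Scope

`tractspace` implements the quantitative machinery used to generalise
protocol-constrained tractography across brain templates and to compare
brains through their white-matter connectivity patterns: probabilistic
streamline tracking under ROI protocols, protocol warping and QC,
path-distribution similarity metrics and population atlases, connectivity
blueprints, and symmetric-KL cross-brain comparison (homologue
identification and scalar-map projection). Real diffusion-MRI data,
registration estimation and fibre-model fitting are out of scope; a
synthetic phantom generator provides fully specified inputs with known
ground truth, so every downstream claim is checkable against construction.

## Streamline propagation

Tracking operates on a fixed per-voxel multi-fibre orientation field (up
to three unit orientations with volume fractions). At each step the
orientation set of the *nearest* voxel is consulted (no interpolation);
candidates are orientations with volume fraction above the subsidiary
threshold (default 1%), one is sampled with probability proportional to
its fraction, and its sign is chosen to keep the turn within 90 degrees.
If the turn still exceeds the curvature limit (default 80 degrees) the
streamline terminates without stepping. Other terminations: leaving the
brain mask, entering a stop mask, a voxel with no candidate orientation,
or the step budget (default 2000 steps of 0.2 mm per direction). Both
directions from the seed are tracked and concatenated, so an emitted
polyline has one interior joint where the two halves meet back-to-back.

Protocol semantics: a streamline is *valid* iff it intersects every
waypoint (and the target, if present) and never touches the exclusion
mask. Only valid streamlines contribute visitation counts, and a
streamline increments a voxel at most once, making counts interpretable
as "valid streamlines visiting this voxel" and the normalised
distribution (counts / n_valid) a visitation frequency.

Randomness: each streamline re-seeds the RNG with its own 31-bit seed
drawn from the run seed, so results are bit-reproducible and independent
of batching. The per-streamline oracle below re-runs the identical
streamlines from the same seeds.

## Blueprints and the exact oracle

Path distributions are block-summed to a 2 mm coarse grid, masked to the
brain and unwrapped in a fixed lexicographic voxel order, giving a
(coarse voxels × tracts) tract matrix; the (vertices × coarse voxels)
surface-seeded visitation matrix multiplied with it yields the
connectivity blueprint, whose rows are normalised to probability
profiles. Because visitation counts are integers and normalised path
distributions are rationals (counts over n_valid × block size), the
product is evaluated in int64 before a single elementwise division. This
makes the central correctness property exact: per-streamline
accumulation of tract-matrix numerators over each streamline's unique
coarse voxels equals the matrix product bit for bit, and the test suite
asserts that identity on multiple seeded phantoms. Rows with zero sum
are excluded (locations unrepresented by the tract repertoire), not
renormalised; group averages renormalise after masking over the subjects
in which a vertex is present.

## Divergence, homologues, projection

Blueprint rows are compared by symmetric Kullback–Leibler divergence:
profiles are floored at epsilon (default 1e-8, recorded in the result)
and renormalised, and the symmetric form is the arithmetic mean of the
two directed divergences, in nats. Mean vs sum and the log base only
rescale values and never reorder matches. Homologue identification takes
a source region's average (renormalised) profile and returns the target
vertices below a stated divergence percentile; scalar-map projection
transfers a per-vertex scalar through the divergence matrix either by
argmin correspondence or by softmax weights exp(−KL/τ) (default τ =
median of the matrix, a scale-adaptive choice). Ties in argmin break to
the lowest index and are flagged.

## The phantom generator

A phantom brain is an axis-aligned ellipsoid (semi-axes 0.44 × extent;
default grid 40×48×40 at 1 mm) with:

* **Hubs** — eight points on a shell at 0.92 of the brain radius, four
  per hemisphere, mirror-symmetric. Cortical parcels are the Voronoi
  cells of the hubs on the vertex shell; the default surface has 600
  vertices from a Fibonacci parametrisation (triangulated by convex
  hull), which also defines the vertex-level correspondence between
  twins.
* **Tracts** — ten tubes around quadratic Bezier curves: four bilateral
  types, each attached to its own hub and terminating subcortically at
  0.45 of the brain radius, plus two commissural tubes (thinner, 0.75×
  calibre) joining the L1–R1 and L3–R3 hubs. Tube radius defaults to
  2.5 mm; the right-hemisphere tubes are 1.15× thicker than the left.
  Inside a tube the dominant orientation is the curve tangent; where
  tubes overlap, a voxel carries up to three orientations with fractions
  proportional to a gentle Gaussian membership falloff (near-equal in
  overlaps, so junction choices stay stochastic per streamline).
* **Funnel field** — outside the tubes, a single orientation points from
  each voxel towards (0.90×) the nearest hub, standing in for
  superficial white matter: cortex-seeded streamlines are guided into
  the tube attached to their parcel's hub.
* **Scalars** — FA 0.7 inside tubes / 0.2 outside and MD 0.6/0.9 × 10⁻³
  mm²/s, plus truncated Gaussian noise (spec `noise`, default 0.05); a
  ground-truth "myelin" vertex map = bilaterally symmetric parcel
  baseline varying smoothly around the ring of hubs plus a gentle
  z-gradient (real T1w/T2w maps are roughly bilaterally symmetric, and a
  smooth baseline keeps the map recoverable under small correspondence
  scatter).
* **Protocols** — per tract: seed/target balls just inside the tube ends
  (at 15% and 85% of arc length, clear of the junction caps), a mid-curve
  waypoint ball, and an off-tract exclusion ball. Right-hemisphere
  exclusions are the mirrored left ones and ROI radii use the left
  calibre on both sides, so the default protocol set is *exactly*
  mirror-symmetric — the QC asymmetry score (1 − Dice against the
  mirrored contralateral ROI) is 0 by construction.

### Why this geometry

Connectivity-blueprint matching can only recover parcels that have
distinguishable profiles. Two findings from the generator's design
(documented because they shaped it): (i) per-streamline tube choice at a
shared hub is *not* effectively stochastic — the entry geometry decides
it — so tracts sharing a cortical hub split the parcel into profile-pure
sub-basins that are ambiguous with other parcels hosting the same tract;
private (one-hub) tracts avoid this. (ii) Mirror symmetry makes left and
right commissural-attached parcels exactly ambiguous; a modest left/right
calibre asymmetry (real hemispheres are not mirror images) breaks the
degeneracy without disturbing the protocol ROIs.

### Twins

A twin pair shares hubs, tract repertoire and vertex parametrisation
(correspondence = identity; parcel labels provably equal), while brain B
differs in geometry: thicker tubes (×1.28), a shallower funnel (0.85)
and straighter commissural curves (control pull 0.28). These differences
move B's attainable profile set *off* A's profile continuum, which is
what makes cross-brain minimum divergences an order of magnitude larger
than within-brain (re-tracking) divergences. Global scale and rotation
are also supported, but shift profiles *along* the continuum, which
degrades argmin parcel recovery; they are therefore not part of the
default twin. B's myelin map is the pull-back of A's through the
correspondence plus Gaussian noise (exact at noise 0).

## Study conditions used by tests and the acceptance script

Default phantom scale (above), tracking at the canonical constants (80°,
0.2 mm, 2000 steps, 1% fraction) with 100 seeds per seed voxel and 1000
streamlines per surface vertex; 20 twin replicates differing in tracking
seeds (phantom geometry is seed-independent by design; the seed controls
noise maps and all tracking randomness). Under these conditions the
pipeline delivers, reproducibly across seeds: retest tract correlations
> 0.99 (every tract > 0.9), blueprint/oracle equality exact, within- vs
cross-brain minimum-KL separation ≈ 13–20×, argmin parcel recovery
≈ 83–86% (the test suite requires at least 80%), homologue-mask Dice
median ≈ 0.57 at
a mask percentile equal to the parcel share (12.5%), and twin scalar-map
recovery r ≈ 0.90–0.93 with argmin projection.

## What the phantom does and does not show

Passing tests demonstrate that the *machinery* is correct and internally
consistent: constraint logic, exact normalisation and products,
divergence algebra, recovery of designed correspondences. The phantom
has no gyrification, no realistic dMRI signal or noise floor, no fibre
fanning/kissing, deterministic orientation fields (no posterior
uncertainty as fitted multi-fibre models would give), and tube-shaped
tracts far simpler than real anatomy. Numerical levels measured here
(KL medians, correlations) therefore do not transfer to real data;
relationships (within ≪ cross, retest ≈ 1) are the meaningful outputs.

## Numerical choices

Trilinear interpolation + 0.5 threshold for mask resampling (out-of-grid
samples read 0); integer-factor block downsampling with the any-voxel
rule for masks; threshold ties use ≥ (a value exactly at 0.1% survives);
Pearson correlations use thresholded values inside the reference mask by
default (flag to disable); KL epsilon 1e-8; argmin ties break to the
lowest index and are flagged; all generators and trackers are pure
functions of (spec, seed) with 31-bit derived seeds.
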