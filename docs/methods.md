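# Methods

## Problem

Saccular intracranial aneurysms (IAs) are monitored by measuring the dome
diameter on consecutive angiographic scans; a size increase of at least
1 mm classifies the aneurysm as growing and raises its rupture-risk
assessment. Manual caliper measurements on a chosen 2D viewing plane carry
intra- and inter-rater variability of the same order as that 1 mm
threshold, so `aneumorph` implements (i) a computerized, mesh-based 3D
measurement of the dome diameter from a binary vascular segmentation and
(ii) the statistical machinery to quantify measurement agreement and its
consequences for growth monitoring.

## Sizing pipeline

1. **Surface reconstruction.** The binary mask (NIfTI; voxel-to-world
   mapping taken from the file affine, everything in mm) is padded by one
   voxel and isosurfaced with marching cubes at level 0.5. Face
   orientation is normalized outward with a signed-volume check. The raw
   isosurface of a binary volume carries staircase artefacts (≈ +9% excess
   area on a digitized sphere), so reconstruction always continues with
   **two-step non-shrinking (Taubin λ|μ) smoothing**: each iteration
   applies a uniform-Laplacian step with positive factor λ followed by a
   negative step μ with |μ| > λ. Defaults: 10 iterations, λ = 0.5,
   μ = −0.53 — the customary regime for this filter; all three are
   config-exposed. On a digitized ball this changes enclosed volume by
   < 2% after 10 iterations, whereas pure Laplacian smoothing at the same
   settings visibly contracts the surface; both properties are tested.

2. **Geodesic ROI.** The vertex nearest (Euclidean) to the annotated IA
   centre seeds a geodesic ball; the 5000 geodesically closest vertices
   (default; soft bound that should be raised for giant aneurysms) induce
   the region-of-interest submesh. Geodesic distance is the shortest path
   on the mesh edge graph with Euclidean edge weights (Dijkstra,
   `scipy.sparse.csgraph`). This overestimates the exact polyhedral
   geodesic by a bounded lattice-stretch factor (measured ≤ 1.2 on a
   triangulated strip fixture); since distances are used only for
   *ranking* neighbours, the approximation is immaterial for selection and
   is the standard choice at this mesh density. Ties at the cutoff
   distance break by vertex index (stable sort) for determinism.

3. **Dome isolation.** The neck is an ordered list of anchor vertices;
   consecutive anchors (last wrapping to first) are joined by shortest
   edge-graph paths, taking the lexicographically smallest vertex sequence
   among ties. Removing the realized closed curve must split the ROI edge
   graph into ≥ 2 components — any separating cycle is accepted, no neck
   shape is assumed; a non-separating curve is an error. The component
   with the smallest mean geodesic distance to the IA-centre vertex is the
   dome; ties go to the larger component (logged). **Curve vertices are
   assigned to the dome side**, so the diameter can never be truncated
   below the neck by the partition itself; for a convex dome the diameter
   endpoints are not neck vertices, and a one-edge-step perturbation of
   all anchors moves the phantom MaxLen by less than twice the mean edge
   length (tested). For unattended runs on phantoms,
   `auto_neck_curve_from_plane` synthesizes the annotation from the
   analytic neck plane: per angular sector about the plane normal
   (12 sectors by default) the vertex closest to the plane becomes an
   anchor. No learned point classifier is involved: isolation always
   consumes an explicit curve.

4. **MaxLen.** The computerized size is the maximum pairwise Euclidean
   distance over the dome-mesh vertices. Two backends must agree exactly:
   an exhaustive O(n²) scan and a convex-hull reduction (the diameter of a
   finite point set is attained between extreme points); the hull backend
   falls back to the exhaustive scan on degenerate (coplanar) input.
   Endpoint ties break by the lowest index pair. The vertex set is the
   measurement domain — for the convex domes of interest the maximum over
   the continuous surface is attained at hull vertices anyway.

The companion `in_plane_diameter` measures the largest distance within a
plane/surface cross-section (triangle–plane intersection segments). It is
bounded above by MaxLen for every plane — the geometric reason manual
single-plane measurements systematically undersize relative to the 3D
measurement — and this bound is asserted over randomized planes.

## Agreement statistics

* **Bland-Altman**: differences are *second − first* (the caller names
  which series is first); mean = systematic error, SD (n−1
  denominator) = random error, limits of agreement mean ± 1.96 SD with no
  small-sample correction.
* **ICC** from two-way ANOVA mean squares of a complete targets × raters
  matrix (MSR rows, MSC columns, MSE residual). Default variant is the
  two-way random-effects absolute-agreement single-rater form
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n); the two-way mixed
  consistency form (MSR − MSE)/(MSR + (k−1)MSE), which eliminates mean
  differences among a fixed rater panel while retaining sensitivity to
  target × rater interaction, is also implemented. The description of the
  intended estimator is ambiguous between the two, so the variant is
  always carried in the result and both are validated against pingouin's
  ICC(A,1)/ICC(C,1). Missing cells are rejected, never imputed; zero total
  variance is an explicit undefined-result error.
* **Cohen's d** with the pooled SD; rater-pair tables report |d| with a
  zero diagonal. Anchors 0.2/0.5/0.8 for small/medium/large effects.
* Reliability labels (left-closed bins): < 0.5 poor, 0.5–0.75 moderate,
  0.75–0.9 good, > 0.9 excellent.
* `pairwise_agreement_report` assembles these per rater pair (inter),
  per session pair (intra), or against a reference series, stratified by
  rupture status, with deterministic row order. Bland-Altman and
  connected-box figures are convenience output without numeric contracts.

## Growth monitoring

`classify_interval` applies the clinical rule with the boundary read
literally: Δ ≥ threshold (default 1.0 mm) is growing, Δ ≤ −threshold is
shrinking (the mirrored criterion is this package's choice; the clinical
literature names the status but no cut-off), otherwise stable. Trajectory
aggregation: any growing interval makes the trajectory growing, else any
shrinking makes it shrinking, else stable — growth dominates because it is
the actionable finding; the rule is config-overridable. The rule acts on
the single dome-diameter scalar; multi-axis growth criteria are out of
scope.

For a truly stable aneurysm measured twice with independent
Normal(0, σ²) errors the false-change probability is

    P(|Δ| ≥ t) = 2 Φ(−t / (σ√2)),

monotone in σ and t; a Monte-Carlo companion estimator is used to verify
the closed form. At t = 1 mm this gives 0.565 for σ = 1.23 mm (a careful
senior rater) and 0.792 for σ = 2.68 mm (the noisiest junior profile):
even expert-level variability makes the 1 mm rule unreliable on a single
comparison, which is the quantitative case for low-variability
computerized measurement.

## Synthetic data

The generator emulates two things the statistics need and real data cannot
supply here (the motivating clinical CTA cohort is private):

* **Phantoms**: voxel union of a cylinder (parent vessel, default radius
  1.5 mm, length 20 mm) and a sphere (dome, default radius 3 mm)
  overlapping by a 1 mm neck offset, at 0.3 mm isotropic spacing (≥ 4
  voxels across the dome is enforced). True maximum diameter is 2r by
  construction; the ground-truth neck plane lies halfway between the tube
  top and the sphere centre, so the dome cap stays larger than a
  hemisphere and still realizes the full diameter. An optional
  perpendicular side branch at the far tube end provides a geodesically
  remote structure for ROI-exclusion tests. Phantoms are binary and
  noise-free: they validate geometry, not segmentation robustness —
  passing tests say nothing about CTA intensity artefacts, touching
  vessels, or segmentation error.

* **Rater simulator**: m = s_true + bias_r + ε with
  ε ~ Normal(0, (sd_r · κ^[ruptured])²), truncated below at 0.1 mm (the
  truncation is negligible at realistic parameters; recovery tests use
  sizes ≥ 8 mm where it is provably inactive). The additive-Gaussian form
  is this package's modelling choice. Undersizing of manual vs 3D
  measurement is modelled as a negative bias (default −3.0 mm, the order
  of observed manual-vs-computerized mean differences); a geometric
  alternative via `in_plane_diameter` on random planes exists but is not
  the default. Shipped profile calibrations (senior SD 1.23 mm unruptured
  with ruptured multiplier 1.73/1.23; juniors 1.67/3.80, 1.65/3.07,
  2.68/5.12, 1.87/2.72) are simulation defaults, never test oracles. The
  longitudinal simulator draws baseline sizes log-normally around a
  3.38 mm median (log-SD 0.5, a realistic incidental-aneurysm spread) with
  a ruptured fraction of 201/358, grows them linearly per interval, and
  derives true statuses from the noiseless sizes.

Randomness: one root seed per simulation, with per-rater (and
per-timepoint) independent streams derived via `numpy.random.SeedSequence`
spawning, so adding a rater does not perturb the draws of another.

## Numerical choices and problem sizes

* Binarization threshold 0.5 for float masks; CSV dialect fixed
  (comma, header, UTF-8); all coordinates mm.
* Shortest-path tie-break tolerances 1e-9 (relative) in curve projection;
  plane-section tolerance 1e-9 mm; nearest-vertex ties break at the lowest
  index.
* Default verification sizes: phantom at 0.3 mm spacing (≈ 9000 surface
  vertices for a 50 mm vessel), diameter backend cross-checks on 100 × 500
  points, ICC recovery at 1000 targets × 5 raters × 20 replicates,
  Bland-Altman recovery at n = 2000, Monte-Carlo probability checks at
  10⁶ draws — sizes at which every Monte-Carlo tolerance (3 SE) is tight
  while the whole suite runs in seconds.

## Limitations

* Segmentation is out of scope: the pipeline starts from a binary mask and
  inherits its errors.
* Edge-graph geodesics, not exact polyhedral geodesics (ranking-equivalent
  here, but distances are biased upward).
* Neck annotation is manual (or plane-derived on phantoms); no automatic
  neck detection or learned dome classification.
* The agreement module reports descriptive statistics only — no confidence
  intervals or hypothesis tests.
* Simulated raters have exchangeable Gaussian errors; real raters show
  size-dependent and case-dependent error structure the simulator does not
  attempt.
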