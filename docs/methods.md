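# Methods

`somaspat` analyzes the three-dimensional spatial organization of neuronal
cell bodies (somata) from their centroid coordinates.  It was built around
the forebrain cholinergic system of the mouse — five subcortical structures
(caudate-putamen CPu, nucleus basalis NB, globus pallidus GP, nucleus
accumbens NA, septum S), two hemispheres, ~14,000 cells — but every
estimator is generic over a bounded 3D region and a point pattern.

All coordinates and lengths are micrometers; volumes are reported in mm³;
densities in mm⁻³.  The coordinate frame puts X = 0 at the most lateral
point of the right side, Y = 0 most anterior, Z = 0 most dorsal.

## Region geometry

A region is a bounded domain with a volume, a deterministic membership test
(boundary points count as inside), and optional *exclusion zones* —
sub-volumes somata cannot occupy, modeling the myelinated axonal bundles
that traverse the CPu.  Concrete representations:

* analytic shapes (box, ball, axis-aligned ellipsoid) with closed-form
  volume, membership and boundary clearance;
* tetrahedral complexes built from a point cloud: the convex hull, or for
  finite `alpha_um` the **alpha complex** (Delaunay tetrahedra with
  circumradius ≤ α), which generalizes the hull to non-convex outlines.
  Volume is the sum of kept-tetrahedron volumes; membership is location in
  a kept tetrahedron;
* voxel masks (boolean grid + voxel size + origin), the interchange format
  for traced bundle volumes.

Uniform sampling under exclusion constraints is rejection sampling from the
bounding box; it aborts if the admissible fraction falls below 10⁻⁶ of the
bounding box so it cannot loop forever.  `extract_ball_subregion` places an
interior ball (default radius 1 mm) at the grid point (0.1 mm spacing, grid
nodes at integer multiples of the spacing from the box corner) with maximal
boundary clearance; it exists to keep edge-affected points out of
intensity-weighted statistics.

## Ripley's K, uncorrected, with CSR envelopes

The estimator is `K(r) = |V| · Σ_i Σ_{j≠i} 1[D(i,j) ≤ r] / n²` with `|V|`
the (constant) region volume and exact Euclidean distances; ties `D = r`
count as within.  No edge correction is applied anywhere.  The rationale:
all inference compares the observed curve against curves simulated in the
same region at the same n, which carry identical boundary bias, so the bias
cancels in hypothesis testing (it does *not* cancel against the theoretical
CSR value (4/3)πr³, where the estimator is negatively biased by roughly
(9/8)·r/L for a cube of side L — a property the tests assert).

Envelopes are pointwise 2.5–97.5 percentiles of `n_sims` CSR simulations
(default 1000), each conditioned on the observed n, honoring exclusion
zones when requested.  Per-simulation random streams are spawned from one
master seed, so runs are reproducible and order-independent.  The paired
t-test across the radii grid (default 100 radii ⇒ df = 99) is provided as a
descriptive effect summary; its p-value ignores the strong autocorrelation
of K across radii and should not be read as an exact test — the Monte Carlo
envelopes and rank test carry the inferential weight.

## Kernel intensity and the inhomogeneous K

The local intensity λ(x) (points per mm³) is an isotropic Gaussian kernel
sum over the pattern with two corrections:

* **Boundary correction.**  Near the region boundary a kernel loses part of
  its mass outside the region, so the raw estimate dips within ~2h of the
  edge.  Each evaluation is divided by the retained-mass fraction,
  approximated for a locally flat boundary as Φ(clearance/h) (floored at
  1/2).  The correction is applied for regions with closed-form clearance
  (box, ball, ellipsoid).  Without it, reciprocal-intensity weights of
  points near the boundary are inflated and the inhomogeneous-K test
  rejects pure gradients.
* **Global renormalization.**  The field is rescaled so its Monte Carlo
  integral over the region equals n (the integral uses a fixed internal
  stream, keeping the field deterministic).

The default bandwidth is Silverman's rule in d = 3,
`(4/(d+2))^(1/(d+4)) · n^(−1/(d+4)) · σ̂`, with σ̂ the geometric mean of the
per-axis sample standard deviations; a scalar override is accepted.

The inhomogeneous K is the per-pair reciprocal-intensity sum
`K_inhom(r) = Σ_i Σ_{j≠i} 1[D(i,j) ≤ r] / (λ_i λ_j)`, uncorrected for
edges, with no |V| prefactor; with constant λ = n/|V| it equals |V|·K(r)
identically (asserted to 1e-9 relative).  When the evaluation points are
the kernel sources themselves, λ is evaluated **leave-one-out** — each
point's own kernel peak, O(1/(n h³)), is removed and the remaining mass
rescaled by n/(n−1).  Without this the observed K_inhom is deflated by the
self-peak (≈20% at n = 100) and the Monte Carlo test rejects everything.

## The Monte Carlo rank test and its calibration

Significance of K_inhom comes from the standard Monte Carlo rank test: the
observed curve and (by default) 99 null realizations are reduced to a
one-dimensional criterion — the integrated absolute deviation from the null
mean (a maximum-deviation variant is available) — and
`p = (1 + #{null ≥ observed}) / (n_null + 1)`; with 99 nulls the smallest
attainable p is 0.01.

Nulls are conditional (fixed-count) inhomogeneous-Poisson samples obtained
by thinning uniform proposals, with three design choices that the type-I
simulations showed to be load-bearing:

1. **Per-null intensity re-estimation** (parametric bootstrap).  Testing
   every realization against the single intensity fitted to the observed
   data is strongly anticonservative: the fit tracks the chance clumps of
   the data, deflating the observed curve relative to nulls.  Each null
   therefore gets its own kernel refit — for subregion analyses, from the
   simulated window points plus the untouched points outside the window —
   and its K_inhom uses its own leave-one-out weights.
2. **Generator smoothing.**  The observed data arise from a smooth
   underlying intensity and are fitted at bandwidth h; nulls generated
   directly from the (sampling-rough) h-estimate and refitted at h carry an
   extra layer of roughness and over-disperse the null criteria, making the
   test conservative.  Nulls are therefore simulated from the kernel
   estimate at bandwidth h·√2 — i.e. the fitted field smoothed once more by
   its own kernel — restoring the data-vs-fit roughness relation.
3. **Shared normalization probes.**  All fields in one analysis are
   renormalized with the same probe set, making Monte Carlo normalization
   error a common scale factor instead of independent curve noise.

With these choices the type-I error of the full pipeline on
inhomogeneous-Poisson data — a rate the test suite and the acceptance
computation measure on every run (200 replicates) — sits a few percent
below the nominal 5%, within the accepted [1%, 12%] band.

For the CPu the tested points are restricted to the interior 1 mm ball
(intensity still estimated from the whole structure) to keep
boundary-affected points out of the comparison; the NB is analyzed without
subregion extraction, its density declining gradually toward the boundary.
Nulls are conditioned on the observed in-window count, so only the relative
shape of the fitted intensity matters and overall level bias cancels.

## Density homogeneity F-test

For counts n₁, n₂ in windows of volume v₁, v₂ under a homogeneous Poisson
model, `F = v₂(2n₁+1) / (v₁(2n₂+1))` is approximately F-distributed with
df = (2n₁+1, 2n₂+1); F > 1 means window 1 denser.  One- and two-sided
p-values and the swapped orientation are both returned.  The default
anterior/posterior split is the plane bisecting the region volume along Y
(closed-form for ellipsoids, Monte Carlo bisection otherwise); the split
plane is configurable because anatomically defined sub-windows are equally
legitimate.  Type-I error on equal-intensity windows (measured by the test
suite over 1000 replicates) is at its nominal 5%.

## Nearest neighbors and cluster graphs

k-NN distances are exact (k-d tree).  The cluster graph joins every point
to its single nearest neighbor (exact ties broken toward the lowest index,
making lattice fixtures deterministic) and symmetrizes; consequently every
node has degree ≥ 1 and every connected component has ≥ 2 members.
Component sizes are the cluster sizes.  A mutual-NN graph is deliberately
*not* used: it can only produce size-2 components and could not represent a
modal cluster size of 3.  Mean k-NN distances are compared against the CSR
band (same region, same n): below ⇒ clustering, above ⇒ regularity.  The
interior-point mean 1-NN distance of CSR matches the Poisson closed form
Γ(4/3)(4πλ/3)^(−1/3) within 5%.  Cluster-histogram robustness to coordinate
noise is measured as total-variation distance between size distributions.

## Voronoi volumetrics

Cell volumes come in two conventions, both reported because boundary
handling changes the mean materially: **clip** intersects every cell with
the region (halfspace intersection for box/convex-hull regions, with
boundary generators' feasible points nudged inward by ≤1e-6 of the span;
nearest-generator voxel assignment, default 20 µm, for other shapes) and
conserves total volume, so mean = V/n exactly; **interior_only** drops
boundary-touching cells, which biases the mean low — the convention that
can push a reported mean below V/n.  A voxel nearest-generator oracle backs
the exact path in tests (agreement within 3% of the mean cell volume at
10 µm voxels).  Coplanar degenerate inputs raise; a deterministic jitter
(fixed seed) is available.

## Synthetic data: what it emulates and what it does not

Each structure × hemisphere is an axis-aligned ellipsoid with 1:2:1
(X:Y:Z) semi-axes — elongated along the anterior–posterior axis — whose
volume matches the reported structural volume to 0.5%; hemispheres and
structures are laid out disjointly.  Generators:

* **CSR**: exactly n uniform points (conditional simulation, matching the
  fixed observed counts used in the null simulations).
* **Gradient**: linear intensity along an axis with anterior:posterior
  *endpoint* ratio ρ, conditioned on n.  Defaults ρ = 2.1 for CPu and 1.7
  for NB, chosen from the reported anterior/posterior count ratios of the
  two structures (their sub-window definitions are not recoverable, so the
  endpoint ratio is pinned to the end-window density ratio; the NB value is
  the geometric middle of its two hemispheres).  Note that a linear
  endpoint-ratio-2.1 gradient in an ellipsoid puts ≈56.7% of points in the
  anterior half (closed form in `gradient_anterior_fraction`), not 2.1× —
  central mass dominates half-counts.
* **Thomas clusters**: fixed parent count, Poisson offspring, isotropic
  Gaussian displacement; out-of-region children get their displacement
  redrawn so the count keeps the parents × Poisson structure.
* **Bundles**: unions of anterior–posterior tubes (default radius 100 µm)
  added until the Monte Carlo excluded fraction is within ±1% of the target
  26.8% of CPu volume.
* **Bilateral dataset**: all ten structure × hemisphere fixtures at the
  reported counts {GP 308/200, NA 638/619, S 638/827, NB 1130/1078,
  CPu 4002/4549}; CPu and NB get gradients, the rest CSR; CPu gets bundle
  exclusions; somal diameters are Normal(per-structure mean, 2 µm)
  truncated at 10 µm (the reported dispersions are standard errors, so a
  plausible cell-level SD was chosen once).

The fixtures reproduce counts, volumes, densities, gradients, exclusion
fractions and the resulting K/NN/Voronoi behaviour.  They do **not**
emulate: real (atlas-shaped, non-convex) region boundaries, anisotropic or
curved gradients, section-alignment artifacts, somal shapes, or the true
fine-scale interaction structure of cholinergic neurons.  Passing tests
therefore validate the estimators and the inferential machinery under
controlled truth, not anatomical conclusions about real tissue.

## Problem sizes for the replicated experiments

The calibration and power experiments run at reduced scale chosen to give
stable rates on a single core in minutes: envelope coverage at n = 300 with
199 simulations × 200 replicates; rank-test type-I at n = 100 with 99 nulls
× 200 replicates; F-test type-I over 1000 replicates; the
gradient-vs-clustering contrast over 50 replicates — the homogeneous route
at the full CPu-left count (n = 4002, radii 75–750 µm, where a smooth
gradient inflates K most relative to the envelope width) drawing from a
pool of ten independent 99-simulation envelopes, the inhomogeneous route at
n = 500.  The test suite asserts envelope coverage within [90, 99]% and
both contrast rates ≥ 0.80; the acceptance computation reports the exact
rates for its seed.

## Known limitations

* The paired-t comparison of K curves inherits radii-grid autocorrelation;
  treat its p as descriptive.
* The flat-wall Φ(clearance/h) boundary correction under-corrects at
  strongly curved boundary patches (clearance is a lower bound for
  ellipsoids).
* The rank test's calibration was verified for smooth gradients at the
  scales above; residual conservatism (rejection slightly below nominal)
  remains, and test power for weak clustering is correspondingly modest.
* Voronoi "interior_only" summaries depend on how many cells touch the
  boundary, i.e. on n and region shape; clip-mode summaries are the
  conserved reference.
* Mesh-file regions use generalized winding numbers for membership; meshes
  must be watertight.
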