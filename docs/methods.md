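# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic study design implemented in `scalpfit`, in the spirit of the
model-documentation pages of packages like statsmodels or msprime.

## Problem setting

Neuronavigation procedures (TMS coil placement, EEG electrode
localization) need the subject's scalp surface and a registration of that
surface to a reference model. `scalpfit` reconstructs a complete scalp
surface from a sparse, unordered set of surface samples — the kind of
point stream a tracked pointer produces when swept over the head — by
fitting a linear statistical shape model (a 3D morphable model, 3DMM)
jointly with a non-uniform similarity transform.

## The shape model

A morphable model is a mean mesh `S_mean` with `k` deformation modes in
dense vertex correspondence.  An instance is

    S_w = S_mean + sum_i w_i * e_i * v_i

where `v_i` are unit eigenvectors of the flattened-vertex covariance of
the (similarity-aligned) training population, and `e_i` is stored as the
mode's standard deviation (the square root of the covariance eigenvalue).
Under this convention weights are dimensionless and `w_i ~ N(0, 1)`
reproduces the training spread, which makes the weight-norm regularizer of
the fitting objective a penalty in population-SD units.  Construction is
PCA (scikit-learn, full SVD); modes with SD below `1e-8` of the leading
one are dropped; eigenvector sign is fixed by making the
largest-magnitude entry positive, so builds are reproducible.

## The joint objective

Given samples `S_sampled` and the current reconstruction (the posed model
instance), the data term is the one-sided Chamfer distance — one-sided
because the samples are orders of magnitude sparser than the model
surface, and a symmetric Chamfer would be dominated by the unsampled
regions:

    cd = (1/|S|) * sum_x min_y d(x, y),        d = squared Euclidean

(squared by default; a plain-Euclidean mode is available and recorded in
the fit result).  Optionally a normal-consistency term `cn` compares each
sample's normal with its correspondent's, via `1 - |cos|`, which is
orientation-sign invariant.  The regularizers are Frobenius norms (not
squared): `lam3 * ||w||_F` discourages unlikely shapes, and
`lam4 * ||T - T0||_F` tethers the 4x4 homogeneous transform to the coarse
initialization `T0`.  The total is

    loss = lam1*cd + lam2*cn + lam3*||w||_F + lam4*||T - T0||_F

Distances enter the loss in centimeters (the default coefficient set
lam1=10, lam2=1, lam3=1, lam4=1 assumes cm); all package I/O is in
millimeters.

Because the norm penalties are not squared they exert a constant-magnitude
pull.  Balancing that pull against the quadratic data term gives an
equilibrium shrinkage of the fitted weights of about
`lam3 / (2 * lam1 * sigma_pv)` in population-SD units, where `sigma_pv`
is the per-vertex mode SD in cm.  This formula is used below to choose
experiment-appropriate `lam3` values.

## Optimization

The pose is parameterized unconstrained: axis-angle rotation, log per-axis
scale (so scales cannot cross zero), translation.  Every iteration
recomputes nearest-neighbor correspondences (cKDTree) against the current
reconstruction and takes one Adam step (beta1=0.9, beta2=0.999) on
`(w, rotation, log-scale, translation)` with the correspondences held
fixed — the standard envelope treatment of the `min` in the Chamfer term.
Gradients are analytic, including the exponential-map derivative for the
rotation block, and are validated against central finite differences in
the test suite (relative error < 1e-4; typically ~1e-10).  Early stopping
triggers when the loss fails to improve by `min_delta` for `patience`
iterations (defaults 1e-6 and 50).

Coarse initialization uses first and second moments: translation from
centroids, per-axis scale from principal-axis SD ratios, rotation from
principal-axes alignment.  Principal axes are ambiguous up to ordering
(for close spectra) and sign, so all 24 proper axis assignments are
scored by the one-sided Chamfer distance of the samples to the transformed
subsampled mean, best first.

### Landscape structure and the fitting harnesses

Point-to-point Chamfer descent on a discretized surface is multi-modal:

- misalignments of about one vertex spacing create *lattice-aliased*
  minima (the classic ICP trap);
- coarse per-axis scale errors absorb part of a mode's amplitude, leaving
  a *compensated* minimum with shrunken weights;
- Adam's terminal oscillation around any optimum is of order the learning
  rate, and it travels roughly `lr` per iteration, so schedules must be
  matched to the distance the parameters need to move.

The package therefore layers cheap global probes around the gradient
core.  The dense-sample recovery harness (`recover_subject`) runs:
coarse-pose screening by a Chamfer grid over the leading mode weight
(±4 population SDs); progressive per-mode fitting (grid scan plus Adam
with the pose pinned by a large `lam4`); joint fits seeded at the
progressive weights and at 1.5x those weights (to jump past
scale-compensated minima); an orientation re-grid (±9 degrees,
1.5-degree steps, about the sample centroid) using the fitted weights
with a joint refit; weight-space escape probes — uniform rescalings
(1.5x, 2x) plus single-mode and mode-pair offsets of 1.5 SD pushing each
weight away from zero (compensated minima hold shrunken or even zeroed
versions of individual mode weights; near-zero modes are probed in both
directions), each probe run through a pose-anchored then free refit, and
skipped entirely when the Chamfer term is already below (1 mm)^2; and a
final polish at `lr = 1e-4`.  Candidates are always compared by
their Chamfer term alone: the regularizers penalize exactly the large
weights and pose corrections a basin escape must propose, so total-loss
comparison would veto valid escapes.  The sparse-trajectory study fit
(`sparse_fit`) is the screening + progressive portion of the same
strategy at lighter budgets.  All stages are deterministic, so fits are
bitwise reproducible.

## Landmark benchmark

The comparison method mirrors conventional neuronavigation registration:
a least-squares similarity transform (Umeyama closed form, reflections
disallowed; isotropic scale) mapping template fiducials to subject
fiducials — either the classic 3 (nasion, left/right preauricular) or 7
(adding the topmost/backmost/leftmost/rightmost extremities).  The
benchmark reconstruction is the posed template mean with no per-subject
morphing, which is why a morphing method can beat it.  An
anisotropic-scale variant exists for sensitivity analysis.  Template
fiducials are stored as vertex indices in the model manifest; subject
extremities are picked exactly along the subject's frame axes.

## Evaluation

Accuracy is position-displacement RMSE: the root mean square of each
ground-truth point's distance to its nearest neighbor in the
reconstruction (one-sided, vertex-to-vertex; a point-to-surface variant
is deliberately out of scope).  The virtual study evaluates it over the
scalp region — ground-truth vertices above the preauricular height in
the subject frame — for the joint fit and both benchmarks alike, since
the base of a closed synthetic head is never sampled and corresponds to
no part of the acquired shapes this study emulates.  The lab-style protocol cuts the pooled
trajectory samples into 20 contiguous equal-count segments and repeatedly
holds out 25% of them (stratified so held-out segments span both
hemispheres and several front-to-back strata, with an unstratified
fallback that is flagged), fitting on the rest.

Error predictability is modeled by regressing RMSE on trajectory length
with an exponential decay `a*exp(b*x) + c` (nonlinear least squares,
multi-start) or polynomials of degree 3–7 (least squares on a rescaled
abscissa for conditioning).  Goodness of fit is Pearson's chi-squared over
200 mm length bins: observed = binned mean RMSE, expected = model value at
the bin's mean observed length.  Evaluating at the bin's mean length
rather than its nominal center avoids forcing the model to extrapolate
into the empty part of partially filled edge bins.  Note the statistic is
computed on binned means while the models are fit to raw points, so it is
not exactly nested in the polynomial degree; on noisy data small
inversions between adjacent degrees are expected (and occur), while on
smooth summary-style data (one value per bin at the bin abscissa) the
nested ordering holds.

Binned 95% confidence intervals use the normal approximation
`1.96 * SD / sqrt(n)`; single-point bins get a zero half-width and are
flagged.

## Sampling simulators

Walks live on the mesh-edge graph with Euclidean edge weights.  The head
is divided into `n_steps + 1` sections of equal angle along the arc from
the frontmost point over the vertex to the back and on towards the neck;
each section splits into 3 equal-angle elevation bands (near-ear, mid,
top).  A step is a Dijkstra shortest path between seeded-random endpoint
vertices in consecutive sections, restricted to those two sections;
endpoints alternate between the top and near-ear bands, which produces
the characteristic zigzag.  `side_to_top` runs one such pass per
hemisphere ("two continuous walks"); `half_side_to_top` one pass;
`side_to_side` one pass whose endpoints alternate hemispheres, with paths
restricted to stay above the endpoints' height so the walk crosses the
vertex rather than the chin; `random_walk` takes uniform random
adjacent-vertex moves (revisits allowed) until a target Euclidean length
is reached.  Sample normals are estimated from the samples alone: the
smallest-variance direction of each point's k-nearest-neighbor
covariance, oriented away from the head center, with a flagged radial
fallback for collinear neighborhoods.

## Synthetic data and the virtual study

The generator stands in for MRI-derived cohorts and licensed head models.
The template is a superellipsoid (exponent 2.5) with smoothly blended
semi-axes — occipital elongation, flattened base — plus smooth nose, brow
and ear bumps.  The features matter: a featureless ellipsoid is nearly
rotation-symmetric, which makes orientation unidentifiable from surface
geometry; real heads are not.  The template is exactly mirror-symmetric,
has an adult head circumference (~560–590 mm at ear level, matching the
~0.56 m adult average), and carries nasion/preauricular landmark vertices
and a canonical frame.

Shape variation is low-rank: orthonormalized radial displacement fields
with low-order polynomial profiles (tall/flat, long/short, broad/narrow,
...), applied as `template + sum_j z_j * (amp_j * sqrt(n)) * mode_j` with
`z ~ N(0,1)`.  Amplitudes are per-vertex RMS displacements; the defaults
(4, 2.5, 1.5 mm) give a total population spread of ~5 mm RMS, consistent
with the scale of published template-to-head registration errors for
landmark-based methods (~4–6 mm).  A uniform-inflation mode is
deliberately absent: shape models are conventionally built on
similarity-aligned scans, so global size is carried by the registration
pose — held-out subjects instead receive random per-axis scale
(0.97–1.03), rotation (up to ~8.6 degrees) and translation (±15 mm),
modest because samples are recorded relative to a head tracker.

The virtual study draws a 200-subject training population at mesh
resolution 4 (2562 vertices), builds the PCA model, then evaluates 20
held-out subjects with 5 side-to-top walks each, steps drawn uniformly
from 1–16 (a desk-scale stand-in for 1152 subjects x 5 walks).  Each walk
is fit with `sparse_fit`; each subject also gets 3- and 7-landmark
benchmark registrations.  The study's optimizer settings adapt the
reference operating point to this model scale: learning rate 5e-3 with
600 iterations (Adam travel must cover ~2.5 SD weight moves), and
`lam3 = lam4 = 0.1` (at `lam3 = 1` the shrinkage formula above gives
~1.25 mm of systematic bias, larger than the plateau differences under
study).  The dense-recovery experiment uses `lam3 = 0.1`,
`lam4 = 0.01`: with dense noise-free samples the prior is hardly needed,
and the tether must not anchor the pose to the imperfect coarse estimate.

### What the generator does and does not emulate

It emulates: dense correspondence, low-rank smooth anatomy-scale
variation, known ground-truth weights/pose, contiguous sparse sampling
covering a few percent of the surface, and optional isotropic pointer
jitter.  It does not emulate: fine anatomical detail (ears with pinnae,
eyes, hair), correspondence error in model building, hair-induced
occlusion or systematic pointer bias, head-tracker slippage, or
non-Gaussian population structure.  Passing tests therefore demonstrate
the correctness and the qualitative behavior of the machinery (error
decreasing with trajectory length to a plateau below the landmark
benchmark), not clinical-grade accuracy on real heads.

## Numerical choices and degenerate inputs

- 0-based vertex indexing internally; OBJ's 1-based indices converted at
  I/O.  Mesh I/O preserves vertex order exactly (correspondence-critical);
  the model container stores full-precision vertex arrays beside the PLY.
- Nearest-neighbor ties are broken toward the lowest target index (exact
  tie handling via a brute-force rescan of tied queries).
- Outward normal orientation is decided by a majority vote of
  `dot(normal, vertex - centroid)`; all-degenerate meshes are an error,
  isolated vertices fall back to the centroid ray.
- `coarse_init` falls back to isotropic scale for rank-deficient sample
  spreads and flags it.
- Non-finite losses abort with the offending term values; log-scale
  parameterization makes non-positive scales unrepresentable.
- The 1.5x weight-seed factor probes outside the shrinkage of a
  scale-compensated minimum without leaving the mode prior's plausible
  range (seeds stay within the grid's ±3 SD span for typical draws).

## Known limitations

- Point-to-point (not point-to-surface) distances throughout; at mesh
  resolution 4 the ~6.6 mm vertex spacing sets the scale of the aliased
  minima the harnesses work around, and the discretization floor of
  Chamfer values for off-lattice samples.
- The benchmark is pose-only (no template morphing), an interpretation of
  vendor behavior that is documented rather than reverse-engineered.
- Global exploration (grids, multi-seeding) is affordable because the
  synthetic models have few modes; with many-component models those
  stages would need smarter proposals.
- The error-model chi-squared is a descriptive statistic, not a
  calibrated test; no degrees-of-freedom correction is applied.
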