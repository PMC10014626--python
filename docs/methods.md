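# Methods

`femfall` evaluates how well a degraded, reconstruction-like density image of
the proximal femur reproduces the geometry, densitometry and finite-element
(FE) strength of its reference QCT-like counterpart.  Because no public
paired dataset of this kind exists, the package ships a synthetic-phantom
generator whose ground truth (axes, densities, region labels, calibration
law) is known by construction; every downstream stage is validated against
that truth.

## Synthetic phantoms

A phantom femur is the union of five solids: a head sphere, a neck frustum
(flaring 25% at its base), a shaft cylinder, and two ellipsoidal bosses for
the greater (GT) and lesser (LT) trochanter.  The neck axis meets the shaft
axis at the configured neck-shaft angle; both axes, the head sphere and the
LT apex are recorded as ground truth.  Voxelisation uses 3x3x3 supersampling
per voxel: the voxel density is the subsample average, so surface voxels
carry partial-volume fractions and the total mineral content is a proper
quadrature of the constructive geometry (verified against an independent
finer-grid quadrature to 1%).  A cortical shell of configurable thickness
(cortical density inside the shell, trabecular elsewhere) produces realistic
surface gradients.

Defaults: head radius 27 mm, neck radius 16 mm / length 40 mm, neck-shaft
angle 125 deg, shaft radius 23 mm / length 110 mm, cortical thickness 3 mm,
trabecular 250 mg/cm3, cortical 900 mg/cm3, voxel spacing 1.5 mm, image
noise 5 HU.  These proportions were chosen so the resulting side-fall FE
model lands in the 8,500-15,500-element range typical of 3 mm voxel models
of cadaver femora; the phantom is deliberately not anatomically accurate
(no anteversion, no shaft curvature, idealised trochanters).

Six insert cylinders (radius 7 mm; reference densities 0-800 mg/cm3) run
below the femur through every slice.  The per-slice HU law
`HU = a(z) * BMD + b(z)` varies sinusoidally along the scan (5% slope
modulation, 10 HU intercept swing) to emulate tube-current modulation, which
is what makes slice-wise calibration necessary.

The degradation operator emulates the *reported summary discrepancies* of
shape/density-model reconstructions, not their mechanism: isotropic volume
scaling about the bone centroid (default 0.93), Gaussian density smoothing
(default 4 mm FWHM), a uniform mean-BMD offset (default -64 mg/cm3), and
correlated vertex noise on the marching-cubes surface (default 1 mm).  After
scaling and smoothing the field is re-centred so the configured mean offset
holds exactly; this is a deliberate contract (the offset *is* the quantity
being emulated) rather than a physical model.  Cohorts perturb lengths and
densities log-normally (fractional SD, default 6%) and the neck-shaft angle
additively, with per-case seeds derived from one master seed.

What passing tests on these phantoms do **not** show: robustness to soft
tissue (segmentation here is threshold+morphology, valid only for phantoms),
to anatomical shape variation beyond the parameterised family, or to real
reconstruction error structure, which is spatially correlated in ways the
summary operator does not reproduce.

## Calibration

Insert HU is sampled on a disc of 60% of the insert radius (avoiding
partial-volume rims), averaged per slice, then smoothed with a five-slice
centred moving average that shrinks symmetrically at the scan ends rather
than padding.  Each valid slice gets an ordinary-least-squares line
`density = slope * HU + intercept`.  Slices where the phantom is invisible
are filled by regressing each insert's HU on the slice-mean HU (a surrogate
for the mass in the slice) over the valid slices, predicting the missing
insert values, and fitting those slices like ordinary ones; they are flagged
`extrapolated`.  Noiseless end-to-end recovery is sub-1 mg/cm3 RMS inside
the bone.

## Registration

Rigid alignment runs in two stages — binary masks first (robust to density
differences), then densities — both maximising Mattes mutual information
(32 bins) over a four-level pyramid (shrink 8/4/2/1, Gaussian smoothing
4/2/1/0 mm) with a six-parameter Euler transform and regular-step gradient
descent.  Linear interpolation is used while optimising; the final density
resampling is cubic B-spline.  On phantom pairs a known 7-degree/5-mm motion
is recovered to ~0.05 mm / 0.05 deg.  The non-rigid stage is a cubic
B-spline free-form deformation (control spacing 10 mm, two levels, L-BFGS-B,
mean-squares metric on smoothed binary masks); it reports pre/post Dice and
the folding fraction (voxels with non-positive Jacobian determinant).
Non-rigid registration is used only to map difference and damage fields onto
a template femur at 3 mm resolution, where these settings converge in
seconds.

## Implicit coordinate system

The shaft axis is estimated from thin cross-section centroids (thin planar
sections of a cylinder are ellipses centred on its axis, so the fit is
robust to an oblique initial direction); the initial band sits well above
the distal cut so oblique slabs are not clipped.  The femoral head is an
algebraic least-squares sphere fit with residual trimming; the head end of
the bone is identified as the end whose terminal surface fits a sphere best.
The LT peak is the surface point of maximal medial protrusion relative to
the shaft axis, excluding a rim near the distal cut face and requiring a 5%
protrusion over the local shaft radius.  The shaft band is then re-anchored
at a height defined by the LT and the head radius (just below the future
distal cut), kept clear of the LT boss, with a median-radius trim against
boss contamination.  The neck axis is a fixed-point iteration of trimmed
cross-section centroids along the head-to-shaft corridor, anchored at the
head centre.  Finally the definition is reduced to three points: both axes
are re-anchored through the midpoint of their common perpendicular, so the
returned neck and shaft axes intersect exactly; the pre-snap gap is kept as
a diagnostic.  On default phantoms the neck-shaft angle is recovered to
better than 1 degree; across a cohort spanning 112-142 deg the correlation
with the configured angle exceeds r^2 = 0.97.

## FE model

Pose: the mask is rotated rigidly so the shaft makes 10 deg with the
horizontal and the neck-shaft plane is vertical with the head
medial-superior (fall on the greater trochanter).  Phantoms carry no
anteversion, so the internal-rotation parameter defaults to 0 (it is
configurable).  The distal cut is a vertical (transverse) plane one head
radius distal of the LT peak along the shaft axis, applied in the posed
frame so the fully-constrained distal face is flat and grid-aligned.
Voxels at 3 mm become 8-node bricks; per-element BMD is the average of the
source image over an equivalent-volume sphere (radius 1.861 mm for 3 mm
elements) pulled back through the inverse pose, restricted to in-mask (bone)
voxels so surface elements carry bone-like density; this keeps the element
model's total mineral content within about 1% of the image integral.  Embedding caps (3-4 voxel
layers, i.e. 9-12 mm, default 4) are boxes over the bone footprint at the
lowest (GT contact) and highest (head contact) layers; cap material is
linear elastic, E = 2.5 GPa, nu = 0.3 (polyurethane-like potting).  Boundary
conditions: distal face fully fixed; GT-cap bottom surface fixed vertically,
free laterally; head-cap top surface tied vertically to a driving node at
the head centre (lateral translations free, emulating sliding between head
and embedding).  Elements with BV/TV below 0.01 keep a floor stiffness of
1e-4 x E(0.01) instead of being removed, avoiding mesh disconnection.

## Material

BV/TV = BMD / rho_ref with rho_ref = 1100/0.907 mg/cm3, so dense cortex
(1,100 mg/cm3) maps to the typical cortical volume fraction 0.907.  The
modulus follows two power branches meeting with value continuity at
BV/TV = 0.5: the upper exponent is solved from the two anchors
E(1) = 24 GPa and E(0.907) = 15.9 GPa (exponent 4.218); the lower branch
uses a trabecular exponent of 1.88 with its coefficient set by continuity.
Yield stresses scale with the modulus at constant yield strains
(199/24,000 = 0.83% tension, 264/24,000 = 1.1% compression), giving
199/264 MPa at BV/TV = 1.  Yielding is the isotropic quadric
`f = sqrt(sigma:F4:sigma) + chi*tr(sigma) - 1`, with the quadratic form
split into deviatoric and hydrostatic parts by one interaction parameter
(default 0: a Drucker-Prager-like quadric) and calibrated so uniaxial
tension/compression yield at +sigma_t / -sigma_c.  Poisson's ratio is 0.3
throughout.

Damage is isotropic, `D = D_max (1 - exp(-k_d kappa))`, driven by the
cumulative plastic strain kappa and applied to the whole stiffness tensor
(nominal stress = (1-D) x effective stress).  D_max = 0.9 keeps the damaged
stiffness positive.  The rate k_d is not fixed by any printed constant; the
default k_d = 2 was chosen so that whole-femur force-displacement curves
show the expected behaviour — yield followed by a plateau with no clear
maximum — while still accumulating informative damage fields (local D up to
~0.5 at the strength point).  Larger rates make contact-zone damage dominate
and the global curve soften sharply.  Both constants are configurable and
should be treated as assumptions.

## Solver

Small-strain kinematics (displacements at the 4% criterion are a few mm on a
~100 mm structure), 2x2x2 Gauss-integrated bricks, sparse direct linear
solves.  The stress update is a vectorised closest-point projection onto the
quadric surface (Newton on the 7-dimensional stress/multiplier system);
near-hydrostatic tensile states, which have no regular projection on the
cone, return to the apex with the plastic strain taking the full elastic
correction.  Damage is updated in a staggered fashion: within an increment
the nominal stress uses the damage committed at the previous increment, and
the update takes effect on commit.  This keeps the incremental problem
elastoplastic with a symmetric consistent tangent and makes Newton converge
in a handful of iterations; with 10-20 displacement increments the damage
lag is below the increment-refinement sensitivity (halving the increment
count moves the strength by well under 2%).

The factorised tangent is reused across iterations and increments (modified
Newton with a stale operator) because the sparse factorisation dominates the
cost at ~40,000 degrees of freedom; it is refreshed when the iteration
stalls, and each Newton step is safeguarded by a backtracking line search.
Load stepping is adaptive: a diverged increment is retried at half the step
(down to 1/8 of the nominal step).  Default tolerances: relative residual
1e-4 (of the total constrained force), return-map tolerance 1e-10.

Strength is the reaction at the driving node, linearly interpolated at a
displacement of 4% of the head-centre-to-GT distance (GT endpoint: the
lowest bone element centre in the posed frame, i.e. the impact point).  The
reaction equals the sum of vertical internal forces over the coupled
head-cap surface; vertical equilibrium against the supports is verified to
0.5%.

## Corrections and statistics

Mesh BMC is the volume integral of element BMD over bone elements.  The
collective correction regresses reference BMC on reconstruction BMC over the
cohort and scales each reconstruction model's densities by (predicted
reference BMC)/(own BMC); the individual correction scales by the exact
per-case ratio, making the corrected BMC match the reference to floating
point.  Both corrections trigger a full FE re-run.  Agreement statistics:
OLS regression (slope, intercept, r^2), SEE with the n-2 denominator, MAE
of the paired values, both also as coefficients of variation relative to
the reference mean, and Lin's concordance correlation coefficient computed
with ddof = 1 sample moments.  Confidence intervals are percentile
bootstrap over resampled pairs (default 2,000 replicates, seeded).

Damage maps place per-element damage (Gauss-point mean) on the model's 3 mm
grid; cohort averaging warps each map onto a template femur (the case whose
shape parameters are closest to the cohort median) using the mask-driven
non-rigid registration, then averages voxel-wise.  Difference maps downsample
each pair to 3 mm by mass-preserving mean pooling ("avoid local density
outliers" implies averaging, not spline interpolation), warp to the template,
crop to the voxels reached by every pair, and average |BMD_a - BMD_b|.

## Problem sizes used by the shipped analyses

The default phantom produces an ~11,000-element model solved with 8-12
increments (about 1.5 minutes per run).  The test suite's cohort study uses ten
phantoms at 55% linear scale (~3,000-element models, 10 increments) with the
standard degradation; these sizes are the package's reference configuration
for the paired-cohort analyses and are stated here so results can be
reproduced exactly.  All randomness is seeded; identical seeds give
bit-identical phantoms, cohorts and bootstrap intervals.

## Known limitations

- The segmentation is valid only for phantom-like images (no soft tissue).
- The stance-configuration load case is a hook only (pose and cut are
  parameterised but no stance boundary conditions are defined).
- Cortical thickness is not measured anywhere in the pipeline.
- The degradation operator reproduces summary discrepancies, not the error
  mechanism of an actual shape/density reconstruction, so cohort agreement
  statistics quantify the pipeline's sensitivity to *configured* bias, not
  the expected clinical agreement.
- The damage constants (k_d, D_max) and the BMD-to-BV/TV reference density
  are assumptions; conclusions that depend on absolute strength values
  should be read accordingly.
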