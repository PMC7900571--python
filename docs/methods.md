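# Methods

## The measurement problem

Articular cartilage thickness is a local quantity on a thin curved shell
sandwiched between a bone and the joint space. Given integer label volumes
for the three knee bones (femur, tibia, patella) and their cartilages —
from any segmentation source — the pipeline measures per-point thickness,
averages it over the 14 WORMS regions, and analyses region thickness across
a cohort by age, sex and knee side.

## Thickness algorithm

For one bone `B` and its cartilage `C` on a grid with per-axis physical
spacing `s = (s0, s1, s2)` mm:

1. **Signed distance fields.** `d_B` and `d_C` are exact Euclidean distance
   transforms with anisotropic sampling, signed negative inside the
   structure and positive outside. The magnitude at a voxel centre is the
   distance to the nearest voxel centre of the opposite class; this is the
   definition the brute-force all-pairs oracle in the tests reproduces
   exactly.
2. **Gradient fields.** First-order gradients of both fields (central
   differences interiorly, one-sided at grid edges, each axis divided by
   its spacing). Before differencing the fields are Gaussian-smoothed with
   σ = 1 voxel per axis (default, switchable off): raw EDT gradients are
   noisy at voxel scale, and only the *sign* of the dot product is
   consumed, so smoothing changes no well-determined classification.
3. **Boundary classification.** Cartilage boundary voxels (cartilage voxels
   with a face-adjacent non-cartilage neighbour, 6-connectivity) are split
   by `sign(∇d_B · ∇d_C)`: negative → *inner* (facing the bone), positive →
   *outer* (the articular surface). A zero dot product goes to outer if any
   face neighbour is background (neither cartilage nor bone), else inner —
   deterministic, and favouring the geometrically unambiguous case. Note
   the rule classifies by *facing*, not adjacency: a shell separated from
   the bone by a gap still has its bone-facing ring classified inner.
4. **Thickness.** A distance map seeded at the outer points is read at
   every inner point. Voxel centres sit half a voxel inside each surface,
   so the raw centre-to-centre reading under-measures the shell by roughly
   one voxel. By default the half-voxel extent of the end voxels along the
   measurement direction (the support function `Σ_i (s_i/2)|u_i|` of the
   voxel box, with `u` the unit vector to the nearest outer point) is added
   at both ends. On 0.5 mm in-plane calibration annuli this reduces the
   mean error from ≈ 0.6 mm to below 0.1 mm across shells of 1.5–4 mm;
   `surface_correction=False` restores the literal centre-to-centre
   reading, which the brute-force nearest-outer-point oracle checks.

Computation is fully 3-D by default. A `2d-slice` mode processes each slice
along the ML axis independently with in-plane distances, for sensitivity
analysis: physical thickness is a 3-D quantity, and with 3 mm slices the
out-of-plane error of a per-slice measurement can be severe, which is why
3-D is the default.

Axis convention: axis 0 superior→inferior, axis 1 anterior→posterior,
axis 2 medial→lateral (the coarse slice direction). All distances are mm;
spacing is read from the NIfTI header.

## Region parcellation

The geometric atlas partitions the whole grid: each voxel is assigned its
nearest bone (physical EDT), femur/tibia voxels split medial/lateral at the
parasagittal plane through the tibial centroid and anterior/central/
posterior by fractions (default equal thirds) of the AP extent of that
bone's cartilage; patella voxels split medial/lateral at the patellar
centroid only. This yields exactly 14 codes. WORMS defines the regions
anatomically; the published quantitative boundaries of the load-bearing
"central" region are not available, so equal thirds is a reproducible,
config-overridable convention — not an anatomical reproduction.

Deformable registration of a labelled atlas to each subject is out of
scope; a pluggable alignment hook (identity or 4×4 affine in world mm,
nearest-label resampling) covers rigid/affine use and keeps the interface a
full registration could plug into. Interface voxels keep whichever code
occupies them (no probabilistic assignment), for determinism. Inner points
falling under another bone's code are treated as unassigned rather than
contaminating a different bone's region.

## Cohort statistics

- **Tukey pairwise comparisons.** One-way, per factor (region, sex, side),
  classic pooled-variance intervals from the studentized-range quantile at
  the ANOVA residual degrees of freedom; α = 0.05 two-tailed, simultaneous
  at family level. A pair is significant iff its interval excludes zero.
  For k = 2 the interval reduces to the pooled two-sample t interval
  (q = √2·t), which the tests exploit as an oracle; an unequal-variance
  (Welch/Games–Howell-style) option exists but pooled is the default. The
  factors are analysed in separate one-way comparisons, not a joint
  multi-way model.
- **Interaction regression.** OLS of thickness on age, a two-level
  condition (sex or laterality) and their product. The interaction
  coefficient equals the difference of condition-specific age slopes
  (verified against stratified fits to 1e-10); interaction p < 0.05
  declares the age trend *inconsistent* between the levels. Age enters
  uncentered: over a 15–64-year support the design is well-conditioned in
  double precision, and uncentered fitting avoids covariance transforms
  when reporting coefficients on the natural scale.
- **CI bands.** Pointwise 95% CIs of the conditional mean over an age grid
  per condition level; narrowest near the age centroid by the OLS leverage
  property, which the tests check.

## Synthetic data

**Phantoms.** Bones are cylinders along the slice axis (plus spheres as an
option); cartilage is the set of voxels at distance `(0, t]` from the bone
over an angular facet, restricted to voxels strictly nearest their own
bone, so shells of different bones are disjoint and the true thickness `t`
is known analytically per voxel (returned as a ground-truth map, exact
where defined). The default knee phantom uses 160×160×30 voxels at
0.5×0.5×3 mm — sub-millimetre in-plane with 3 mm slices, the resolution
regime of routine sagittal knee MR. The patella is modelled as a cylinder
like the other bones: a patella-sized sphere changes cross-section between
3 mm slices faster than the shell width and is destroyed by slice
quantisation. What phantoms do *not* emulate: realistic bone shape,
segmentation noise, partial-volume effects at real tissue interfaces —
passing phantom tests validates the geometry of the measurement, not
robustness to segmentation error (the perturbation fixture probes that
separately via Dice).

**Cohorts.** One row per subject; exact stratum counts (1,355 M / 1,126 F;
1,228 L / 1,253 R of n = 2,481), truncated-normal ages (mean 35, SD 10,
support 15–64), and per-region thickness drawn as Normal with mean
`baseline + slope·(age−35) + sex_offset·I(M) + side_offset·I(L)` plus
optional slope-difference terms for sex/side, truncated at zero by redraw
(clipping would deflate the SD). The 13 published region means/SDs are the
default baselines; PL is not published and defaults to PM − 0.1 mm with
PM's SD, flagged `calibrated=False` so nothing treats it as truth. Age
slopes default to zero because only slope signs/significance are published,
not magnitudes; tests that need slopes set them explicitly. The cohort
generator reproduces the *marginal* structure the statistics consume; it
does not model between-region correlation within a subject, so it cannot
validate analyses that depend on that correlation (none of the shipped ones
do).

## Numerical and design notes

- Boundary voxels use 6-connectivity (26-connectivity inflates boundaries
  on anisotropic grids); out-of-grid neighbours do not create boundary.
- Empty∩empty Dice = 1 by convention (perfect agreement on absence, avoids
  0/0). DSC is computed volumetrically per subject, not slice-averaged.
- The nearest-outer-point EDT is the production path; a brute-force
  nearest-point search is kept as a test oracle only.
- Degenerate inputs raise typed errors (`InputError` → CLI exit 2,
  `DegenerateGeometryError` → exit 3): empty or grid-filling masks, empty
  outer point set, missing bones (named), single-level conditions,
  zero residual variance.
- Simulation sizes in the test suite are design choices: the family-error
  check uses k = 3 groups of 15 over 5,000 replicates (Monte-Carlo SE
  ≈ 0.003); interaction recovery uses 100 replicates of n = 600.

## Limitations

- The thickness definition is nearest-outer-point distance, not
  normal-ray or mesh-based thickness; on strongly curved thin shells the
  two differ at the sub-voxel level.
- The geometric atlas is a convention; region means on real knees depend on
  the atlas/registration actually used, and the affine hook is not a
  substitute for deformable registration accuracy.
- With 3 mm slices, structures whose geometry varies faster than the slice
  spacing (small, strongly curved shells) are under-sampled out-of-plane;
  the in-plane cylinder phantoms deliberately avoid this regime, real
  patellar cartilage may not.
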