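# Methods

This package is a desk-scale reconstruction of the measurement and
analysis chain used to study posterior scleral deformation when the optic
nerve (ON) tethers the globe in adduction: stereo digital image
correlation (3D-DIC) of a speckled posterior sclera, surface-area-ratio
deformation metrics, bench kinematics of the tether geometry, and
tensile-curve analysis feeding hyperelastic material models. Every stage
runs on synthetic data with exact ground truth, so the pipeline's accuracy
claims are verifiable rather than asserted.

## Synthetic scenes (`tetherdic.synthgen`)

The posterior sclera is modeled as a sphere (globe radius 12 mm by
default) with the imaged pole on +z; the ON sheath meets the surface in a
circle of chord radius `sheath_outer_radius` (default 3.2 mm, the middle
of the 2.81-3.65 mm range of adult specimens). Azimuth 0/90/180 deg in the
surface frame are the nasal/superior/temporal directions. Speckles emulate
iron-dust applied to the scleral surface: Poisson-distributed dark dots
(default 40 per mm^2, mean radius 50 um, lognormal size scatter) rendered
as anti-aliased Gaussian splats through ideal pinhole cameras, plus
Gaussian intensity noise. Dot size and density are not dictated by any
measurement; they were chosen once so that a 21 px correlation subset
contains of order ten dots, which is what makes subset matching stable.
All randomness derives from one integer seed; identical specs produce
bit-identical images.

Three deformations with analytic ground truth are provided:

* **rigid translation** - every face area ratio is exactly 1;
* **inflation** about the globe center by scale k (an IOP-elevation
  surrogate) - every ratio is exactly k^2;
* **tether** - a meridional displacement away from the sheath margin,
  Gaussian in arc distance s with kernel sigma = `decay_mm / 2` and a
  Gaussian azimuth window (sigma 30 deg) around the nasal direction. With
  amplitude decaying in s, material points bunch together meridionally,
  compressing an annulus adjacent to the margin while conserving area in
  the far field (< 0.1% beyond 2 x `decay_mm`; the half-width kernel is
  what makes this hold at realistic amplitudes). The amplitude is not a
  free parameter: it is calibrated by scalar root finding so that the mean
  face ratio over the nasal 30 deg sector, 0-1 mm annulus, equals
  `nasal_ratio` (default 0.977, the compression observed next to the
  sheath under incremental adduction). Typical calibrated amplitudes are
  ~0.03 mm.

The default rig is two converging cameras 10 mm apart, 48 mm above the
pole, 1600 px focal length, 512 px images (about 30 um per pixel on the
surface). This is a scaled-down twin of a DSLR bench: it keeps a full
scene round-trip in tens of seconds while preserving the geometry that
matters (convergence angle, depth range, speckle scale in pixels).

What the generator does **not** emulate: lens distortion (a real 55 mm
lens shows ~0.2% pincushion, ignored there too), depth-of-field and
specular effects, dehydration drift, physiological surface texture, and
any mechanics - the tether field is a prescribed displacement, not a
solution of equilibrium. Passing tests therefore demonstrate that the
*measurement chain* is unbiased and precise on known deformations, not
that any particular tissue deforms this way.

## Calibration and triangulation (`tetherdic.calib`)

Each camera is an 11-parameter direct linear transformation (DLT),
estimated from >= 6 non-coplanar 3D-2D correspondences by homogeneous
least squares with Hartley-style normalization of both coordinate sets
(this keeps the design matrix conditioned; a coplanar target raises an
error carrying the condition number). The synthetic calibration standard
is a 25.4 mm diameter cylinder - eye-sized, so the calibrated volume
matches the measurement volume - with a grid of features projected
exactly and perturbed by 0.05 px Gaussian noise emulating subpixel target
localization. Two-view triangulation is the linear least-squares
intersection of the DLT rays; no bundle adjustment, matching the classic
DLT workflow. With the default rig this yields a 3D reconstruction RMS
error of roughly 10 um; because a displacement is the difference of two
independent equally-noisy positions, the displacement RMS error is
sqrt(2) times that (~14 um), which the package verifies both analytically
and by sampling. The pair-level "3D error" is reported as the
root-mean-square Euclidean distance in mm (an RMS length, the natural
reading of a micrometre-scale figure).

The translation standard - a randomly patterned plane on a vernier stage,
translated normally or tangentially by up to 2 mm - is run through the
*entire* pipeline. Acceptance is that measured displacement tracks the
stage setting with no trend in error versus magnitude and that the mean
area ratio stays within 0.005 of unity.

## Subset DIC (`tetherdic.dic`)

Zero-normalized cross-correlation (ZNCC) subset matching: integer search
by normalized cross-correlation over a window, then subpixel refinement by
maximizing ZNCC of the reference subset against a cubic-spline-interpolated
deformed subset (Nelder-Mead over the continuous shift, bounded to +-1.5 px
around the integer peak). Defaults - subset 21 px, grid step 5-10 px,
score cutoff 0.8, contrast floor 0.01 - are artifact choices, configurable
and documented as such; the matching model is pure translation per subset,
adequate because subset-scale strains here are below ~1%. Matches are
rejected with reason codes (low contrast, search-border peak, low score,
out of bounds; for stereo additionally a > 1 px triangulation residual).
Large bulk motions are seeded by whole-image phase correlation, guarded by
a whole-image ZNCC check so a spurious peak (e.g. under pure scale change)
falls back to a zero seed. On the default speckle the subpixel error is
~0.005 px mean absolute, comfortably below the 0.05 px design target.

A full scene measurement stereo-matches the two reference images, tracks
reference -> deformed in each camera at the matched (subpixel) centers,
triangulates both states with the shared correspondence, and meshes the
reference points by Delaunay triangulation on their two principal axes,
applying the same connectivity to the deformed points. Before meshing, a
displacement-field consistency filter drops points whose displacement
deviates from the median of their 8 nearest neighbors by more than
max(0.02 mm, 10 x the median deviation): a match can clear the score
cutoff yet be spurious (typically when its true counterpart left the
frame), and a single such point would otherwise contaminate every
adjacent face ratio. The ROI accepts exclusion polygons for occluded or
textureless patches; subsets straddling the speckle boundary at the
sheath margin acquire a small view-dependent matching bias (tens of um in
absolute position). That bias largely cancels in the area *ratio* because
both states share it, which is why margin-adjacent subsets are kept for
deformation measurement but excluded when absolute surface accuracy is
being assessed.

## Area-ratio fields and regions (`tetherdic.surface`)

The deformation metric is the per-triangle loaded/reference area ratio.
Surface strain is deliberately not computed: adduction tethering changes
scleral thickness, which invalidates the thin-membrane assumption that
strain-from-surface methods need. The ratio obeys exact laws (1 under
rigid motion, k^2 under uniform scaling) used as machine-precision
oracles, and the identity "total area ratio = area-weighted mean of face
ratios" holds by construction.

Delaunay meshing of an irregular point cloud produces boundary slivers
whose tiny reference areas amplify noise in the ratio; `build_mesh`
therefore drops faces with minimum angle < 5 deg or area < 5% of the
median (both thresholds configurable, and set to zero in the exactness
tests, which use well-shaped meshes).

Regions follow the standard layout: three 30 deg sectors centered on the
nasal, superior and temporal azimuths (the inferior sclera is occluded by
the gripper on a real bench, and is likewise absent here), each split into
0-1 mm and 1-2 mm annuli of distance from the sheath margin, plus narrow
strips along each direction for distance profiles. Distances are geodesic
arc lengths evaluated on a least-squares sphere fitted to the reference
mesh - on a 12 mm globe the chord/geodesic difference at 1-2 mm is second
order, and the sphere fit avoids mesh-graph shortest-path artifacts.
Region means are unweighted across faces (the area-weighted mean is
reported alongside, since the convention is genuinely ambiguous); the
summary also carries the mean absolute difference of ratios from unity,
the scalar used to compare loading modes. Strip binning is 0.1 mm by
default with bin centers at multiples of the width and edge ties falling
to the lower bin; for meshes coarser than 0.1 mm a wider strip is passed
explicitly. Heat maps are rendered per face with a configurable colormap;
repeat-run agreement is quantified as the mean absolute difference of two
runs' fields binned on a common (distance, azimuth) grid.

FEM surface exports (node/connectivity CSV tables per state) are read
into the same mesh type, so surface-area post-processing of simulation
output is literally the same operation as for DIC meshes.

## Kinematics (`tetherdic.kinematics`)

Geometry lives in a right-handed globe-centered frame (nasal +x, superior
+y, anterior +z for a right eye; left eyes mirror x). The straight ON
length between the junction (posterior pole rotated nasally by the 17 deg
fovea-disc angle) and a gripper at distance R and offset angle chi is
sqrt(r^2 + R^2 - 2 r R cos(chi + angle)); rotating the eye by theta or
moving the gripper by psi = theta are kinematically equivalent, which the
package checks by explicit construction of both configurations rather
than by reusing the closed form. The virtual orbital apex sits 41 mm from
the globe center, 22 deg off the sagittal plane (average adult orbit);
the initial gripper tip lies on the junction -> apex line at the measured
ON length (a longer ON than that distance means a slack nerve and raises
rather than clamping). The extension proportion of the apex-junction
distance under incremental adduction 26 -> 32 deg is computed with the
apex fixed and the eye rotating about its center; globe translation is
set to zero (measured translation over this range is near zero, and the
bench prohibits it), which is why elongations computed from central gaze
here exceed in-vivo figures that include translation - the elongation is
therefore an *input* to the strain computation, not derived internally.
ON strain from elongation uses the chord-referenced convention
(elongation% - sinuosity%, floored at zero; 6.6% and 3% give 3.6%); the
ratio convention ((1+e)/(1+s) - 1, giving 3.5% for the same inputs) is
available via an option.

## Tensile analysis (`tetherdic.tensile`)

Engineering strain references the grip separation at the 0.02 N preload -
this choice shifts every derived modulus and is therefore explicit in the
record type; the preload stress itself is documented in the curve
metadata, not subtracted. Samples after peak force are truncated as
post-rupture. Tangent moduli come from differentiating a polynomial of
order 3-5 fitted to the curve; the order is chosen by adjusted R^2 (with
a manual override), and the estimator is exact on polynomial data of
order <= 5. Moduli are evaluated at arbitrary strain points so both the
3%/6% (sclera) and 3%/7% (ON, sheath) conventions are available.

Toe-region detection: both axes are log-transformed (natural logs; the
base cancels in slopes and transition), every interior breakpoint leaving
at least 4 samples per segment is tried, two independent OLS lines are
fitted (no continuity constraint - the intersection of the two lines *is*
the transition; a continuity-constrained variant can be built from the
same pieces but is not the default because the two-line intersection is
the published definition), and the split minimizing total SSE wins. Equal
slopes within 1e-2 flag the fit as degenerate (single power law). On
generated sheath curves (exponents 1.2 -> 2.5 at a 3.4% strain breakpoint,
2% multiplicative stress noise, 160 samples) the transition is recovered
within 0.05 pp on average and well inside +-0.4 pp for every tested seed.
Pooled fitting of one record is the default mode; per-specimen fits can be
averaged by the caller.

## Hyperelastic models (`tetherdic.materials`)

Incompressible reduced-polynomial strain energy W = sum C_i0 (I1bar - 3)^i
with uniaxial nominal stress P = 2 (lam - lam^-2) sum i C_i0 (I1bar-3)^(i-1),
I1bar = lam^2 + 2/lam. P is linear in the coefficients, so fitting is an
ordinary least-squares solve - deterministic, with R^2 reported and a
non-positive C_10 treated as failure. Default orders are 2 for scleral
regions and 1 for ON/sheath (configurable; the appropriate order is
tissue- and dataset-dependent). The Poisson ratio 0.495 is carried as
metadata for downstream nearly-incompressible FEM use. Pre-stretch (the
baseline ON/sheath tension at the 26 deg threshold) is a 5% translation
of the curve along the strain axis, applied to curves *before* fitting by
default (the order of operations is a genuine ambiguity; before-fitting
matches feeding translated curves to a solver). The lamina cribrosa curve
is the pointwise stress average of ON and peripapillary sclera on a
200-point common strain grid, and is always bounded by its inputs.

## Problem sizes and numerical choices

Scenes are rendered at 512 px with DIC grids of step 8-10 px (~2000
subsets), chosen so a full end-to-end scene measurement completes in about
a minute on one core while the nasal-annulus recovery error stays several
times below its 0.01 acceptance band. The Monte-Carlo error-propagation
check uses 1e5 position pairs; breakpoint and coefficient recovery use 100
seeds. Tie-breaks and degenerate inputs are handled explicitly: zero
reference-area faces are excluded from ratio fields, empty regions are
flagged rather than dropped, equal bilinear slopes are flagged degenerate,
a slack ON raises, and near-parallel triangulation rays warn.

## Known limitations

Subset matching is translation-only (no affine subset shape functions),
adequate below ~1% subset-scale strain but biased for strong gradients;
the geodesic machinery assumes near-spherical surfaces; the tether field
is kinematic, so the package cannot test constitutive inferences - only
measurement fidelity; no GEE/ANOVA statistics are provided (descriptive
summaries only); and the FEM itself is out of scope - only exported
surfaces are post-processed.
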