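# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order the pipeline runs.

## Volumes and preprocessing

All volumes are 3D arrays in `(z, y, x)` order with an isotropic voxel
size in µm (default 10.5 µm, the common in vivo micro-CT resolution for
murine vertebrae); readers for NIfTI, MetaImage and TIFF stacks convert to
this convention on load.  Grayscale density images are preprocessed with a
Gaussian filter (sigma 1.2 voxels, kernel truncated at 1 sigma, reflect
padding) and binarized at 580 mgHA/cm³.  Two conventions are ours where
the protocol leaves them open: binarization is inclusive (`filtered ≥
threshold`), and reflect padding avoids edge darkening on cropped volumes.
Out-of-bounds voxels count as background for surface definitions and
distance transforms — a conservative choice on cropped fields of view.

## Surface (re)modeling distances

Voxel set algebra on a registered pair splits bone into formed
(follow-up only), resorbed (baseline only) and quiescent (both) clusters.
Connectivity is 6-neighborhood (von Neumann) throughout — clusters,
surfaces, dilations and the taxicab metric all use the same neighborhood,
so no operation can couple voxels the others consider disconnected.

Baseline surface voxels (bone with ≥1 background face-neighbor) are
partitioned into events: formation where the surface touches a dilated
formed cluster, resorption where the surface voxel itself was resorbed,
quiescence otherwise.  A voxel qualifying as both is labeled resorption —
the voxel itself changed — and counted in the QC report.

Distances: the city-block distance transform of the follow-up image gives
each formed voxel its depth within the formed cluster; formation surface
voxels receive the maximum transform value among their formed
face-neighbors (gray dilation, the conventional maximum aggregator; ties
between clusters resolve to the smallest cluster id).  Resorption surface
voxels take their own value from the transform of the inverted follow-up.
Raw distances are then rescaled cluster by cluster so that each cluster's
distance sum equals its voxel volume exactly; this makes the surface
representation volume-conserving, which the test suite asserts to 1e-9
relative.  Clusters with no surface voxel to carry them (free-floating
islands, or clusters whose only support was relabeled by the collision
rule) cannot be represented on the surface; their volumes are reported in
the QC dictionary rather than being smeared over other clusters, and the
signed distance total equals the net voxel change minus those orphan
volumes.

A known property of this measurement: rescaling is per cluster, so within
a cluster that spans a signal gradient the distance profile follows the
raw gray-dilated projections.  This mildly flattens within-cluster
velocity gradients — in synthetic studies the plateau of the recovered
velocity curve sits a few percent below the generating saturation level
while cluster volumes and totals are exact.

## Mechanical signal

Three descriptors of the local environment derive from a strain energy
density field U (MPa):

* SED itself, sampled on the bone side (the surface voxel's own value);
* effective strain `sqrt(2U/E)` in µε, bone side — the standard
  SED-derived scalar strain that accounts for tissue modulus;
* ‖∇U‖ by central differences (one-sided at boundaries), a proxy for
  interstitial fluid flow, sampled on the marrow side as the mean over the
  voxel's in-bounds marrow face-neighbors (the voxel-to-surface mapping is
  not prescribed by the protocol; the mean over adjacent marrow voxels is
  the least-committal choice).

Material maps: homogeneous (bone 14800 MPa, marrow 2 MPa, ν 0.3) or a
linear density→modulus relation clamped below at 2 MPa; the calibration
constants of the linear relation are configuration inputs with no
defaults.  Rescaling a solved field to the in vivo force is linear in
displacement, hence linear for effective strain and quadratic for SED and
its gradient — the physically consistent reading of linear-elastic
rescaling.  Because the mechanoregulation statistics normalize the signal
by its 99th percentile, none of them depend on the unit or force scale,
which the tests assert as an invariance.

### Voxel finite elements

The bundled solver meshes each voxel as an 8-node hexahedron (2×2×2 Gauss
quadrature), assembles nothing, and runs Jacobi-preconditioned conjugate
gradients matrix-free to a relative residual of 1e-8 (grid cap 64³ —
intended for phantoms and validation, not whole bones).  Boundary modes:
`paper` (proximal face fixed, distal face displaced axially by 1% of the
length, lateral faces free) and `affine` (all boundary nodes carry the
uniform uniaxial strain field with lateral contraction −νε), whose exact
solution on a homogeneous block is the affine field itself — giving the
analytic checks SED = ½Eε² and reaction force EεA to 1e-6.  Element SED
is computed from the element energy, `½ uᵀKu / V`.

## Conditional probabilities and CCR

Signals of all surface voxels are normalized by their pooled 99th
percentile (linear interpolation; values above the cap enter the top bin)
and binned at 1%.  Counts are normalized per event before conversion to
probabilities, removing the dependence on the global imbalance between
formation, quiescence and resorption; in every populated bin the three
probabilities sum to 1, and 1/3 means the signal is uninformative there.
Empty bins are flagged and excluded from both the confusion sums and the
denominator of the CCR, so the confusion matrix totals the number of
populated bins.  The threshold sweep is exhaustive over all bin-boundary
pairs t_r ≤ t_f (finer granularity cannot change sums of binned data);
ties resolve to the smallest thresholds, making the output deterministic.
By construction the optimal CCR is ≥ 1/3 whenever all bins are populated.

## Velocity curves and mechanostat fits

The velocity curve bins signal at 1% of the 99th-percentile cap and signed
distances at 1% of the maximum magnitude (sign restored; the raw-value
option exists behind a flag), then takes the per-bin count-weighted mean
with quiescent voxels entering as 0, scaled by voxel size / interval to
µm/day.  Group curves share a cap pooled over the group's animals, average
per-sample values unweighted, and mask bins with fewer than 3 contributing
animals.

Both fits are unweighted bounded least squares over unmasked bins
(count-weighting available behind a flag), with deterministic multi-start
to escape local minima, and report the RMSE against the curve.

* The piecewise fit is parametrized internally by its knots (plateau
  onsets and thresholds) rather than by the moduli, which keeps the
  problem well conditioned; moduli are recovered as RVM = −RSL/d₀,
  FVM = FSL/d₁.  Saturation levels are bounded to ±50 µm/day, thresholds
  to the observed signal range.  A branch with no data of its sign is
  flagged unidentifiable and reported as NaN.  A plateau whose onset falls
  outside the observed signal range is not identified by the data (any
  more extreme level fits equally well); the fit collapses this ridge by
  reporting the curve value at the range edge, mirroring the hyperbola's
  RSL convention.
* The hyperbola fit constrains RmT so the pole stays outside the data
  range; RSL is defined post hoc as the fitted value at the minimum
  observed signal.  RmT is reported strictly as the function parameter;
  the zero crossing of the curve, RmVM/FSL − RmT, is exposed separately
  because the two differ whenever FSL ≠ 0.

## Bootstrap and frequency regression

Balanced bootstrap: the group's ids are tiled n_rep times (default 2500),
permuted once with a seeded generator and split into n_rep groups of the
original size, so every animal appears exactly n_rep times overall.  Each
replicate rebuilds the group curve from the resampled animals' surface
tables — including the pooled cap — and refits; distributions are
summarized by median and IQR, and runs abort if more than 20% of replicate
fits fail.  Per-group random streams derive deterministically from the
study seed.

The frequency regression fits parameter medians with y = y0 + a·ln f by
ordinary least squares; pseudo-R² = 1 − SS_res/SS_tot makes fit quality
comparable across parameters of different magnitude.  Only cyclic groups
(f > 0) can enter — sham and static loading have no frequency to take the
logarithm of.

## Synthetic data

Phantoms are smoothed seeded Gaussian noise thresholded at the quantile
that yields the target bone volume fraction (default 0.2, the order
observed in murine trabecular bone), keeping the largest 6-connected
component; because component filtering makes the achieved fraction
piecewise-discontinuous in the threshold, the bisection accepts the
closest candidate within twice the tolerance when the exact window is
jumped.  The compartment mask is the domain interior minus a 2-voxel
margin.

Surface advection: per baseline surface voxel the signal is sampled with
the same side conventions as the analysis, converted to a displacement
`RmV(signal)·interval/voxel_size` plus optional Gaussian velocity noise,
and voxelized by probabilistic rounding (expected applied volume equals
the displacement exactly; floor/round modes exist for deterministic
tests).  Fronts advance in rounds — every front claims its t-th layer
before any claims its (t+1)-th — walking into marrow along their heading
and turning toward the largest free pocket when blocked; a front whose
local neighborhood is exhausted merges with the already-advanced front and
deposits beyond it (breadth-first through the flipped voxels), so the
applied volume is conserved even on voxel-rough surfaces where adjacent
fronts compete.  Resorption mirrors this inward.  The applied per-voxel
distances are emitted as the ground-truth table.

The default generative mechanostat (FSL 2 µm/day, RT 150 µε, FT 300 µε,
RSL −3 µm/day, RVM 0.04, FVM 0.02 µm/day/µε, velocity noise 0.1 µm/day,
weekly interval) places both plateaus and the lazy zone inside the sampled
strain range of the default radial field (peak 700 µε at the domain
center, so high-velocity formation stays away from the cropped boundary).
Synthetic studies in the test suite use 6 animals per group on 36³ grids
and 250 bootstrap replicates — sizes at which the recovery tolerances
(saturation level within 10%, thresholds within two signal bins) are
comfortably resolved.

What the phantoms do not emulate: plate/rod architecture, curvature-driven
smoothing, image noise, registration error, or partial-volume effects.
Passing recovery tests on them validates the measurement chain —
classification, distances, scaling, binning, fitting, bootstrap — not
robustness to those real-data effects.

## Known limitations

* Surface velocity is measured along face-neighbor normals on the voxel
  grid; oblique interfaces are represented by stair-steps, and sub-voxel
  surface motion is only captured in expectation.
* Per-cluster volume scaling conserves totals but redistributes distances
  within clusters that span signal gradients (see above).
* The pipeline analyzes registered pairs; it does not link (re)modeling
  patches across more than two time points.
* The FE solver is for desk-scale validation; whole-bone meshes need an
  external solver, whose SED field the pipeline accepts as input.
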