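# Methods

## Problem and approach

Abdominal aortic aneurysms (AAAs) are monitored by serial imaging; growth
status (fast, ≥ 5 mm/year, versus slow, < 5 mm/year) drives surveillance
and intervention decisions.  Disturbed intra-aneurysmal hemodynamics —
recirculating flow and reversed wall shear stress (WSS) — is believed to
track vascular remodeling, but hemodynamic fields live on unstructured CFD
meshes where conventional summary statistics (WSS extrema, vortex-core
counts) discard their spatial organization.

This package converts peak-systole hemodynamic vector fields into
image-like data and applies gray-level texture analysis to them:

1. **Direction quantization.** The unit sphere is partitioned into N
   equal-area regions (default N = 360) by the recursive zonal
   construction: polar caps sized so each holds exactly 4π/N of area,
   intermediate collars split into whole numbers of equal-azimuth cells,
   and collar boundaries recomputed so every region's area is exactly
   4π/N.  Each region is represented by the unit vector to its area
   centroid (closed form for colatitude–azimuth rectangles).  A field
   vector is assigned the index of the regional vector with the largest
   dot product (smallest angle); ties break to the smallest index and
   vectors with norm < 1e−12 become background (level 0).  Regions are
   numbered from the upstream pole to the downstream pole, so *high gray
   levels mean downstream-aligned vectors and low gray levels mean
   reversed (upstream) vectors* — the semantics both direction-sensitive
   statistics below rely on.

2. **Velocity imaging (3D).**  The sac-ROI velocity field is resampled to
   a uniform voxel grid (default: longest ROI axis spans 64 voxels;
   cohort runs in this repository use 24 — see *Problem sizes*).
   Interpolation is barycentric-linear on supplied tetrahedra, or
   Delaunay-based linear scattered interpolation for point clouds; voxels
   outside the interpolatable support are masked.  A cheap KD-tree
   prefilter skips voxels farther from every ROI point than the local
   point spacing plus two voxels; this only trims the support boundary.
   The speed image (MVelocity) is clipped to its 5–95th percentiles and
   rescaled to [0, 1] (linear-interpolation percentiles; windows that are
   constant up to rounding map to all zeros).  The direction image
   (DVelocity) stores the sphere-region index per voxel.

3. **WSS imaging (2D).**  The lumen surface with per-vertex WSS is cut
   into a topological disk along the shortest edge path between its two
   boundary rims (tube topology), flattened by a cotangent-weight
   harmonic map whose boundary goes to a rectangle by arc length (corners
   = the four seam-endpoint copies; for generic disks, sharp boundary
   corners when exactly four exist, else arc-length quarters), and
   rasterized on a uniform pixel grid (default: long side 256 pixels;
   cohort runs use 96).  Direction labels are computed from the original
   3D WSS vectors *before* flattening and rasterized by nearest vertex
   (categorical); magnitudes are rasterized barycentrically and 5–95%
   normalized over ROI vertices.  Per-triangle angle distortion is
   reported as a conformality diagnostic; flipped triangles are an error,
   never silently repaired.  On a cylinder the map reproduces the
   analytic unrolling (θ·r, z) to machine precision away from the
   boundary ring.

4. **Texture features.**  Magnitude images are quantized into 32
   equal-width bins on [0, 1] (interior bins left-closed, top bin
   right-closed); direction images keep their native 1..N levels.
   Features: first-order statistics (Pearson, non-excess kurtosis;
   entropy/uniformity on a 32-bin histogram), GLCM (symmetric, merged
   over all 13 3D / 4 2D offset directions), GLRLM (runs merged over
   directions), and GLSZM (zones by 26/8-connectivity), all per the
   standard IBSI-style formulas from the direction-merged matrix.  Two
   statistics get special treatment because their directional reading is
   central:

   * **Large-area low-gray-level emphasis (LALGLE)** of the DWSS size-zone
     matrix, in two variants: the conventional
     `[Σ m_ij · j²/i²]/Nz` (`.standard`) and a variant that squares the
     raw count and omits the zone-size weight, `[Σ m_ij²/i²]/Nz`
     (`.printed`).  Both are emitted because the field's literature is
     inconsistent on this statistic; low gray levels in DWSS are reversed
     WSS, so both emphasize recirculation footprints.
   * **Gray-level non-uniformity (GLN)** `[Σ_i (Σ_j m_ij)²]/Nz` of the
     DVelocity run-length (and size-zone) matrix.  Note that at fixed Nz
     this is *maximized* when all runs share one level (verified
     exhaustively in the tests), i.e. large GLN means concentrated
     direction structure with many short runs spread over few levels —
     the statistic responds to direction heterogeneity through Nz and the
     level marginal jointly.

   Higher-order variants: single-level stationary (undecimated) wavelet
   sub-bands (coif1; tags L/H per axis) and Laplacian-of-Gaussian filters
   with physical sigma (mm, converted per-axis by spacing, mirror
   boundaries), each followed by first-order statistics.  Filters apply
   to magnitude images only by default; filtering categorical direction
   labels is mathematically dubious and is available only behind a flag
   that treats labels as ordinal integers.

5. **Selection and modeling.**  A Wilcoxon rank-sum screen removes
   features with two-sided p > 0.8 (deliberately permissive: it drops
   only near-exact nulls and constants; exact enumeration when both
   groups have ≤ 10 tie-free cases, normal approximation with tie
   correction otherwise).  Importance ranking repeats stratified 10-fold
   CV over 100 fold-reshuffling realizations; a feature's importance is
   its out-of-fold univariate AUROC folded to ≥ 0.5, features are ranked
   per realization (ties by name), and mean rank picks the top 15.
   Evaluation repeats a stratified 90/10 hold-out 100 times:
   standardization fit on training only, hyperparameters by inner
   stratified 10-fold CV maximizing AUROC (C grids descending so ties
   resolve toward the less-regularized model), AUROC from decision
   scores, per-class accuracies at the default threshold, and the
   2.5–97.5 percentile interval of the repeat AUROCs.  Six classifiers
   are available (linear/poly SVM, L1 logistic, KNN, random forest,
   GBM); no class weighting by default, so weak models drift toward the
   majority (slow) class.

## Synthetic cohort

No patient data ships with the package, so a synthetic phantom generator
provides cohorts with the statistical structure the method detects.  Each
case is a straight vessel (length 80 mm, radius ~N(10, 1) mm) with a
Gaussian bulge (amplitude ~N(8, 1.5) mm, width ~N(8, 1) mm) as the sac:

* **Velocity**: Poiseuille axial profile u_z = U(1 − (r/R(z))²) with peak
  speed U ~ N(0.6, 0.05) m/s, plus a recirculation cell from the
  axisymmetric stream function ψ = κU r²(1 − r/R(z)) sin(π(z−z₁)/(2w))
  inside the bulge (u_z += (1/r)∂ψ/∂r, u_r = −(1/r)∂ψ/∂z), plus
  isotropic Gaussian noise of 0.05·U per component.  κ = 0 gives strictly
  forward flow; large κ reverses flow near the sac wall.
* **WSS**: downstream surface tangent with magnitude 4μU/R(z)
  (μ = 0.004 Pa·s) under multiplicative noise; within seeded elliptical
  patches covering a fraction φ of the bulge the tangent is reversed.
* **Classes**: slow-growing cases draw κ ~ N(0.5+Δκ, 0.1) and
  φ ~ N(0.25+Δφ, 0.05); fast-growing mirror with the deltas subtracted
  (slow = stronger recirculation / more reversed-WSS area).  All geometry
  and speed parameters are drawn identically for both classes, so the
  class signal is purely hemodynamic.  Default cohort: 48 slow / 22 fast.

What the phantom does **not** emulate: real lumen geometry variation,
pulsatile dynamics, turbulence-like fine structure, intraluminal
thrombus, or any coupling between geometry and flow.  Passing tests
therefore demonstrate that the pipeline *recovers planted
recirculation/reversed-WSS signatures at realistic noise*, not that it
predicts growth in patients.

A consequence worth stating plainly: the recirculation cell perturbs the
*speed* field as well as the direction field (that is its physics), so a
strong class effect (Δκ = 0.3 separates the class means by ~4 latent
standard deviations) makes magnitude-texture features alone already
sufficient for near-perfect discrimination in this phantom.  Additive
gains from direction features can only appear against a non-saturated
baseline; the end-to-end tests measure and report this rather than
assuming it.

## Problem sizes and numerical choices

* Cohort runs (tests, acceptance script) use velocity grids of 24 voxels
  along the longest ROI axis and WSS rasters of 96 pixels; texture
  statistics are resolution-controlled, and these sizes keep a 70-case
  cohort's featurization within a few minutes on one CPU.  Single-case
  defaults remain 64/256.
* Percentiles: linear interpolation between order statistics.
* Degenerate magnitude windows (q95 − q5 ≤ 1e−12 relative) map to zero.
* Zero/near-zero vectors (norm < 1e−12) are background, excluded from
  masks.
* GLCM is accumulated symmetrically and merged (summed) over directions
  before feature computation; the merge is recorded in matrix metadata.
* Harmonic flattening solves one sparse SPD system per coordinate; the
  rectangle aspect is the mean opposite-side arc-length ratio.
* All randomness flows from one integer seed via SHA-256 stable hashing
  into per-stage seeds (below 2³¹); reruns are bitwise identical.

## Known limitations

* The harmonic map with a fixed rectangular boundary is conformal only up
  to boundary distortion; free-boundary conformal parameterization is
  future work (angle-distortion diagnostics quantify the gap per case).
* GLSZM zone enumeration loops over present gray levels; with N = 360
  direction levels this is the slowest texture step on large images.
* The Wilcoxon screen at p > 0.8 retains ~80% of pure-noise features by
  construction; it is a fidelity choice, not a recommendation.
* Feature selection is performed once on the full cohort before repeated
  hold-out evaluation (matching the staged design this package mirrors);
  selection is therefore not nested inside the evaluation splits, and
  null-cohort AUROC estimates include that selection bias.  The
  null-calibration test bounds the combined effect empirically.
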