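# Methods

## The model

A kinetochore is represented as two "molecule" layers — inner (green) and
outer (red) — each a fixed number of points drawn uniformly from a 3D volume.
Two plate shapes are supported:

* **flat prism**: each layer is a `plate_length × plate_width ×
  layer_thickness` box; layer centres sit `layer_separation` apart along the
  inner–outer axis.
* **curved shell**: the layers are concentric shell segments around a common
  curvature centre.  `curvature_radius` is the radius of the mid-surface
  between the two layer centres; the layers sit at `radius ± separation/2`
  and share the plate's angular extent (half-angle
  `α = plate_length / (2·radius)`).  Two curvature modes exist:
  `cap-3d` (rotationally symmetric spherical cap, the default) and `arc-2d`
  (cylindrical shell curved in one plane).  The plate is concave towards the
  outside: the outer (red) layer is the one closer to the curvature centre,
  matching the outward-facing concave plates seen in EM.

Sister pairs place two plates with the inner-layer centroids separated by the
inter-kinetochore distance (IKD) along a pair axis; `antiparallel=True`
(default) makes the outer layers face away from each other, and per-sister
swivel angles rotate each plate about its inner centroid away from the pair
axis.  All generated objects carry analytic ground truth (layer centroids,
IKD, warning flags), so every downstream measurement can be validated.

Imaging is an effective-PSF model: each molecule contributes a unit-mass 3D
Gaussian with per-channel lateral/axial widths, and a voxel's value is the
*integral* of the resulting mixture over the voxel (products of erf
differences per axis).  This is the exact limit of "render on a fine grid,
then integrate intensity into LM voxels"; a fine-grid render plus a
`downsample` operation is also provided and agrees with the direct route to
machine precision (this dual route is exercised in the tests).  Flux is
conserved exactly, convolution and voxel integration both preserve centres
of mass, and the image is linear in the molecule cloud.  The sub-voxel
position of the grid relative to the scene is randomized within one voxel
per rendering (seedable), mimicking arbitrary kinetochore placement on the
camera raster.  No photon or camera noise is added by default; the model is
deliberately noiseless so that residual variability isolates molecule-
sampling and discretization effects.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| lateral PSF FWHM | 155 nm green, 172 nm red | bead-calibrated widths of the target optical system (post-deconvolution effective values; deconvolution itself is not modelled) |
| axial PSF FWHM | 3 × lateral | typical widefield anisotropy; not independently calibrated, and only lateral quantities feed the headline measurements — override if you care about Z |
| voxel size | 43 × 43 × 200 nm (40 nm XY available) | camera pixel and Z-step of the target system |
| molecules per layer | 1000 | keeps Monte-Carlo centroid error below ~2 nm at plate scale; the real copy number is unknown |
| layer thickness | 50 nm | fluorescent layer widths measured in cells are far wider than the ~25 nm EM-dense layers; 50 nm matches the simulated-kinetochore convention |
| layer separation | 140 nm (human CenpA–Hec1 map), ~100 nm for IM scenes | the IM value reproduces the ~95–113 nm deltas measured there |
| IM plate | 1000 × 250 nm | length from EM; the second lateral extent is not separately reported, so the human plate's 250 nm is reused |
| human plate | 300 × 250 nm prism | EM plate dimensions |
| untreated / Taxol plate geometry | arc 301 nm, R 287 nm / arc 418 nm, R 239 nm | averaged EM morphometry of the two conditions |
| EM trace spacing | 1.88 nm/px | tracing calibration |

The layer separation used in the geometry predictor is a modelling choice
(the true separation is only known to a few tens of nm); `geometry_report`
can sweep it (e.g. 90–140 nm) to show the sensitivity of the predicted
change.

## Measurement procedures

**Line-scan (plate-shaped kinetochores).**  A single line within one focal
plane is sampled across both sister plates by cubic-spline interpolation at
half-voxel steps.  Cubic (not linear) sampling matters: bilinear
interpolation at 43 nm pixels convolves the profile with a triangular kernel
that adds ~300 nm² of variance and visibly inflates fitted FWHMs.  Each
channel is fitted independently with two Gaussians plus one shared constant
baseline (`scipy.optimize.curve_fit`; initial guesses from smoothed peak
detection).  The relative fit error is the RMS residual divided by the mean
fitted amplitude; measurements where any of the four peak fits exceeds 3%
are flagged `qc_pass=False`, reproducing the experimental screening gate.
Delta is signed, `(IKD_red − IKD_green)/2`, and is by construction the same
for both sisters; a uniform chromatic shift of one channel cancels exactly.
`skew_sweep` repeats the measurement with the line rotated in-plane about
its midpoint and reports the maximum relative deviation from the orthogonal
scan.

**Spots (point-like kinetochores).**  Per channel: Gaussian smoothing (1
voxel), Otsu threshold (overridable), connected components with a 5-voxel
minimum size.  Each region's XY centroid comes from an axis-aligned 2D
Gaussian fit of its maximum-intensity XY projection (FWHM reported for the
longer axis); Z is fitted separately on the Z-profile of the XZ projection,
falling back to an intensity centroid when fewer than four planes are
available.  Spots with relative residual above 10% are flagged not-fittable.
Chromatic registration translates one channel so the global mean centroids
coincide; green–red pairing is by mutual nearest neighbour within 500 nm,
and delta is the 3D Euclidean distance within each pair.  Unlike the
pairwise line-scan delta, this 3D distance is swivel-invariant but relies on
registration; `projected_delta` exposes the 1D variant whose swivel bias is
`1 − cos(swivel)`.

**EM morphometry.**  Contour length is the polyline length of the trace.
Curvature is the radius of the Pratt algebraic circle fit (generalized
eigenproblem with the Pratt constraint, data centred for conditioning);
collinear input returns an infinite-radius sentinel rather than an error.
For plate averaging each trace is rotated so its termini are horizontal,
reflected if needed so the apex (the point of maximal perpendicular distance
from the terminus chord) lies above the chord, and translated to pin the
apex at the origin; the apex is located on a lightly smoothed deviation
series because pinning to the raw extremum of a jittered trace
systematically overshoots outward and inflates shallow-arc radii.  Aligned
traces are rasterized as unit-intensity single-pixel strokes at 1.88 nm/px
and averaged in 32-bit.  The averaged plate's chord is the per-column argmax
with parabolic sub-pixel refinement, restricted to columns carrying ≥70% of
the peak column mass with three columns trimmed at each arm tip (tip columns
are covered only by the longest plates and would lift the chord); the chord
is then fitted with the same Pratt routine.  Population summaries report
medians alongside means because short, nearly straight plates produce
strongly right-skewed radius distributions; the group-comparison helper is
the textbook pooled-variance two-tailed Student's t.

## Geometry predictions

For a thin shell layer of radius *r* and half-angle *α* the centroid lies at
`r·f(α)` from the curvature centre along the symmetry axis, with
`f = (1+cos α)/2` (spherical cap) or `sin α / α` (cylindrical arc); finite
thickness enters through the radial moment of the uniform density
(`effective_radius`).  The analytic delta of a curved plate is the
difference of the two layers' axial centroid offsets; the flat limit returns
the layer separation for any plate length.  The simulated route builds the
same plate from molecules, renders it, and measures the separation of the
channel centres of mass projected on the symmetry axis (a 4σ rendering
margin keeps truncation bias negligible); analytic and simulated routes are
required to agree within 3 Monte-Carlo standard errors across a 3×3
radius × arc-length grid.  Scan-line tilt errors use the cosine model —
`1 − cos θ` (projection) or `1/cos θ − 1` (along-line elongation), both
exposed; the projection convention is the reported one, giving 1.5% at 10°
and 6% at 20°.

## Synthetic data: what it does and does not emulate

The generator reproduces the *geometry* of the study conditions: plate
dimensions and curvature of untreated vs Taxol-treated cells, antiparallel
sister arrangements, bead and microtubule calibration targets, and EM-style
traced contours (circular arcs with smooth radial jitter — a 15 nm
correlation length, because white per-point jitter at 1.88 nm spacing would
make polyline lengths diverge; real freehand traces are smooth).  It does
not emulate photon/camera noise, deconvolution artefacts, fixation-dependent
layer broadening, spindle-scale crowding, chromatin background, or the
undulations/protrusions of real plates (only smooth radial jitter).  Passing
tests therefore demonstrate correctness of the measurement chain and the
geometric claims, not robustness to every nuisance of real microscopy; the
optional Poisson stage and the configurable thresholds are the entry points
for such robustness studies.

## Numerical choices and degenerate inputs

Gaussian fits are bounded (positive amplitudes and widths, centres inside
the sampled window) with at most 20k function evaluations; non-convergence
returns results flagged `converged=False` rather than raising, while
profiles with the wrong number of discernible maxima raise distinct
`SinglePeakError`/`MultiPeakError` types.  Rendering refuses clouds outside
an explicit grid (naming the offending axis and extents) and chromatic
shifts beyond the recorded margin.  Flat plates are the `radius → ∞` limit
throughout and are handled without special-casing by the factor `f → 1`.
Every stochastic stage takes a seed or Generator; the experiment runner
derives per-stage, per-replicate streams from a master seed (CRC-32 of the
stage name in the spawn key), so re-running any stage alone reproduces its
stream.

## Problem sizes

Default study-condition runs are deliberately modest: 50 replicate sister
pairs for skew sweeps, 30 Monte-Carlo replicates per geometry for the
predictor, 1000 molecules per layer, and ~115-plate EM populations.  At
these sizes the Monte-Carlo standard error of a predicted delta change is
~0.2 nm and the whole acceptance computation takes seconds on one core.

## Known limitations

* The axial PSF is an uncalibrated 3× anisotropy assumption; Z-dependent
  quantities (the separate Z fit, 3D deltas of axially tilted scenes) are
  correspondingly approximate.
* The per-kinetochore spot delta is a Euclidean norm of a noisy vector and
  therefore inflates small true separations (the classic positive bias of
  distance estimators); the pairwise line-scan delta does not share this
  bias but requires resolvable plate orientation.
* Layer density is uniform and per-molecule brightness equal; real layers
  are likely neither.
* The averaged-plate radius of shallow arcs is extremely sensitive to
  few-nanometre chord errors (radius ∝ L²/8·sagitta); with ~100-plate
  populations expect a few percent of spread, which is a property of the
  averaging procedure itself.
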