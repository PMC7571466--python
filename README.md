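# kinetosim

Forward simulation and measurement of **intrakinetochore delta** — the
distance between the fluorescence centroids of two differently labelled
kinetochore proteins (for instance the inner protein CenpA in green and the
outer microtubule-binding protein Hec1 in red).  Delta is widely read as a
proxy for intrakinetochore tension, but because a kinetochore is an extended,
malleable object, its *shape* contributes to the measured centroid distance
too.  This package lets you separate the two contributions on synthetic data
with exact ground truth.

It is aimed at people analysing two-colour kinetochore (or other sub-
diffraction colocalization) data who want to know what their measurement
pipeline actually reports when the underlying object is not a point.

## What it does

* **Scene generation** (`kinetosim.scene`) — "molecule clouds" for kinetochore
  plates modelled as two uniformly filled layers (flat rectangular prisms or
  curved shell segments), antiparallel sister-kinetochore pairs with
  controllable inter-kinetochore distance (IKD) and swivel, microtubule line
  sources, bead point sources, and EM-style traced plate contours.
* **Optics** (`kinetosim.optics`) — per-channel 3D Gaussian PSFs
  (bead-calibrated defaults: 155 nm green / 172 nm red lateral FWHM) rendered
  onto a light-microscope voxel grid (43 nm XY / 200 nm Z) by exact per-voxel
  integration, with randomized sub-voxel placement and optional chromatic
  shifts.
* **Line-scan measurement** (`kinetosim.linescan`) — the measurement enabled
  by micrometre-long Indian muntjac (IM) kinetochore plates: two-Gaussian fits
  of intensity profiles, per-channel IKD, and the pairwise delta

  `delta = (IKD_red − IKD_green) / 2`

  which cancels uniform chromatic shifts by construction, plus layer-width
  FWHM estimation and skewed-scan sweeps.
* **Spot measurement** (`kinetosim.spotfit`) — the kSHREC-style pipeline for
  human-sized (~300 nm) kinetochores: segmentation, 2D-Gaussian sub-voxel
  centroids, global-centroid chromatic registration, per-kinetochore 3D delta.
* **EM plate morphometry** (`kinetosim.plate_geometry`) — contour length,
  Pratt algebraic circle fits (curvature radius), rotational alignment and
  32-bit average-plate compositing, population statistics.
* **Geometry effects** (`kinetosim.geometry_effect`) — closed forms and
  simulations for how plate curvature, length, swivel and scan-line tilt
  change delta.  A thin shell layer of radius *r* spanning half-angle *α*
  has its centroid at *r·f(α)* from the curvature centre, with
  *f(α) = (1 + cos α)/2* for a rotationally symmetric cap; two layers
  separated radially by *s* therefore appear only *≈ s·f(α)* apart.

## Worked example

```python
from kinetosim import optics, scene, linescan
from kinetosim.geometry_effect import (UNTREATED_GEOMETRY, TAXOL_GEOMETRY,
                                       predict_delta_change, skew_error,
                                       taxol_geometry_share)

# How much of the Taxol-induced delta decrease is pure geometry?
# Plates: untreated 301 nm arc, radius 287 nm; Taxol 418 nm arc, radius 239 nm;
# layers 140 nm apart in both.
analytic = predict_delta_change(UNTREATED_GEOMETRY, TAXOL_GEOMETRY)
simulated = predict_delta_change(UNTREATED_GEOMETRY, TAXOL_GEOMETRY,
                                 method="simulated", n_replicates=30, seed=0)
print(f"analytic:  delta {analytic.delta_a.value:.1f} -> {analytic.delta_b.value:.1f} nm, "
      f"change {analytic.change:.1f} nm")
print(f"simulated: delta {simulated.delta_a.value:.1f} -> {simulated.delta_b.value:.1f} nm, "
      f"change {simulated.change:.1f} +- {simulated.mc_sd:.1f} nm")
print(f"share of the 30 nm Taxol effect: {100 * taxol_geometry_share(analytic.change):.0f}%")

# Pairwise line-scan delta on a simulated IM sister pair, with skewed scans
print(f"tilt error: {100 * skew_error(10):.1f}% at 10 deg, {100 * skew_error(20):.1f}% at 20 deg")
cloud = scene.build_sister_pair(scene.im_sister_pair(), seed=11)
volume = optics.render(cloud, optics.psf_from_fwhm(), seed=12)
line = linescan.pair_scan_line(cloud.ground_truth, optics.psf_from_fwhm())
sweep = linescan.skew_sweep(volume, line, [-10, 0, 10])
m = sweep.measurements[0.0]
print(f"IKD_green {m.ikd_green:.0f} nm, IKD_red {m.ikd_red:.0f} nm, delta {m.delta:.1f} nm")
print(f"delta fluctuation over +-10 deg skews: {100 * sweep.fluctuation:.1f}%")
```

Output:

```
analytic:  delta 129.9 -> 114.0 nm, change 15.9 nm
simulated: delta 129.8 -> 114.0 nm, change 15.8 +- 0.2 nm
share of the 30 nm Taxol effect: 53%
tilt error: 1.5% at 10 deg, 6.0% at 20 deg
IKD_green 998 nm, IKD_red 1200 nm, delta 100.9 nm
delta fluctuation over +-10 deg skews: 1.9%
```

Reading this: bending the plate from the untreated to the Taxol geometry
removes ~16 nm of delta *with the molecular layer separation held fixed* —
about half of the ~30 nm delta decrease reported for Taxol-treated human
cells.  And the pairwise line-scan delta on plate-shaped kinetochores is
robust: a ±10° scan skew changes the measured value by only a few percent
(the cosine model predicts 1.5% at 10°), with the true 100 nm layer
separation recovered to within a nanometre or two.

A command-line interface mirrors the library
(`kinetosim simulate / measure-linescan / measure-spots / plate-geometry /
predict-geometry / run`); see `kinetosim --help`.

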