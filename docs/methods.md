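# Methods

This note documents the models, conventions and numerical choices behind
`octoquant`, in the order the pipeline applies them, and states what the
synthetic benchmark does and does not establish about real microscope data.

## Cell model and morphology

A cell is represented by a single closed polygon drawn on the mid-section
plane of its z-stack (plane N/2 for even N, (N+1)/2 for odd N, 1-based). The
polygon is extruded through all planes: the 3D mask is the 2D mask replicated
per plane. This matches a workflow in which one manual ROI is drawn per cell
and deliberately ignores the cell's true 3D envelope — voxels near the top
and bottom of the stack that fall outside the cell dilute region APVs
equally in all octants, so *contrasts* between regions are preserved even
though absolute APVs are not.

Rasterization uses a fixed convention: 0-based pixel coordinates with
x = column and y = row, polygon vertices at pixel centers, and
boundary-inclusive point-in-polygon membership (via `shapely.covers`). The
convention is arbitrary but must be fixed for masks to be reproducible.

**Circularity** is computed on the outline polygon — shoelace area and
vertex-to-vertex perimeter — not on the rasterized mask, because raster
perimeter estimators are biased high and the ≥ 0.8 symmetric / < 0.8
asymmetric threshold descends from a shape-factor convention defined on
outlines. Closed forms anchor the implementation: a square gives π/4, a 2:1
rectangle 2π/9, a fine regular polygon → 1. Note that a *pure* 2:1 ellipse
has circularity ≈ 0.841 (Ramanujan perimeter) and therefore classifies as
symmetric; elongation alone crosses the 0.8 threshold only near axis ratio
2.2. Real asymmetric cells are both elongated and boundary-irregular, which
is why the synthetic asymmetric class combines axis ratio ≥ 2 with a Fourier
boundary wobble (below).

**Centroid** is the unweighted mean of mask voxel coordinates (the ROI's
centroid, not an intensity-weighted one), and **TPN** is the voxel count of
the 3D mask.

## Spatial partition

Octants are defined by coordinate sign relative to the centroid, not by
physical distance, so voxel anisotropy (dz ≠ dxy) does not enter the
partition. Conventions the source workflow leaves open are fixed and
configurable:

* apical = z ≥ centroid-z with plane index increasing away from the
  coverslip (`z_orientation` flips this);
* within the apical half, quadrants 1–4 run counterclockwise from
  (x ≥ cx, y ≥ cy); octant k+4 lies below octant k — only the 1–4 apical /
  5–8 basolateral split is externally mandated;
* ties at the centroid coordinate go to the progressive/apical side, so the
  eight octants partition the mask exactly and their counts sum to TPN;
* "progressive" = increasing pixel coordinate.

Axis slabs (0.4 µm along z per the acquisition spacing, 0.4 µm along x/y at
0.1 µm pixels) are provided for profile plots; the conflicting step-size
statements in the source material are resolved by making both spacings
configuration with defaults dz = 0.4 µm, dxy = 0.1 µm.

## Intensity metrics

Region APVs are arithmetic means in float64. Normalization is per field
*and* per channel: the highest octant APV among all cells of that
field/channel is equated to exactly 1. Pooling channels would be wrong
because each channel has its own laser/gain settings; pooling fields would
reintroduce the acquisition variation normalization exists to cancel. All
downstream quantities are ratios of NAPVs and are therefore invariant under
global intensity scaling.

Polarity calls use the two-tailed unpaired equal-variance Student's t-test at
α = 0.05 with no multiple-testing correction, reproducing the source
statistical protocol (a Holm option exists behind a config flag). Magnitude
is always reported — also for nil calls — as the percent difference of
population mean half-NAPVs, i.e. means of per-cell values, not means of
per-cell ratios, matching the mean ± SE reporting convention. SE = sample
SD/√n throughout.

Frequency distributions of octant NAPVs use bin width 0.1 over [0, 1]
(decile granularity, matching how NAPV "bands" at 0.7/0.8 are discussed) and
sum-to-1 normalization; max-to-1 is implemented as an option but the common
area under two curves is bounded by 1 only under sum-to-1, where it equals
1 − total-variation distance. An octant is *contributing* when its overlap
with the cell-count-weighted pool of the other seven falls below θ. θ has no
external definition ("careful analysis" in the source); 0.8 is the default,
it is exposed in configuration and echoed in the output table. Because the
pool dilutes as more octants deviate, the flag is reliable for one or two
deviating octants and conservative beyond that.

## Neighbor census

Contact is mask adjacency within a 1-pixel Chebyshev tolerance (full 3×3
dilation, so diagonal touches count) — the tightest digital analogue of
"boundaries observed to be in contact". Overlapping ROIs are reported with a
warning but still count as contact. Cells clipped by the frame border have
incompletely observed neighborhoods and are excluded from the census by
default. The census reports, per focal shape class, pie fractions over
{asymmetric-neighbor links, symmetric-neighbor links, isolated cells}, the
per-cell count distribution and the maximum observed counts.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes, with exact ground truth:

* **Shapes.** Ellipses with a low-order Fourier boundary wobble
  `r(θ) ∝ 1 + ε·cos(mθ + φ)`. The symmetric class uses a = b and ε ≤ 0.03
  (circularity ≈ 0.97); the asymmetric class uses axis ratio 2–2.6 with
  ε ∈ [0.10, 0.14], m ∈ {5, 6, 7}, which drives circularity well below 0.8
  (the wobble inflates the perimeter by ≈ m²ε²/4 while barely changing
  area).
* **Intensity.** `base × pattern(x, y) × Π_axis(1 + k_axis·s_axis) + noise`,
  a multiplicative linear ramp over the normalized signed coordinate
  relative to the cell center, with additive Gaussian noise clipped at 0.
  The user-facing gradient `g` is the *target half-contrast* (g_z = −0.2 ⇒
  basolateral half-APV 20% above apical). Because the voxel grid is discrete
  — and for odd plane counts the two z-halves are unequal — the slope k is
  calibrated per cell from the actual mean of s over each half, making the
  imposed contrast exact in expectation rather than approximate. A fixed
  slope of g itself would yield roughly half the nominal contrast; the
  calibration is what lets recovery tests compare measured magnitudes
  against the imposed value directly. Patterns (uniform, membrane-like
  shell, nucleus-like central blob, punctate spots) are 2D and identical on
  every plane, which keeps the z-calibration exact for every pattern; x/y
  calibration is exact for axis-aligned symmetric masks and approximate
  under wobble.
* **Treatments.** `osmotic_transform` scales linear dimensions by 0.9
  (hypertonic) / 1.1 (hypotonic) — so TPN shifts by ≈ ±21% in-plane — and
  applies per-channel gradient presets dominated by basolateral (g_z < 0)
  polarity with nil-polarity controls, so end-to-end runs can reproduce a
  polarity table of the expected shape.
* **Fields.** Sparse packing guarantees zero contacts; touching packing lays
  chains whose centers sit at 95% of the summed guaranteed inner radii
  (min(a, b)·(1 − ε)), so designed contacts survive any wobble phase;
  `rosette_specs` builds a 5-neighbor star for maximum-count scenarios.
  Stacks are written as float32 TIFFs so imposed contrasts are not quantized
  away.

What the generator does *not* model: optics (PSF, depth attenuation,
shot/Poisson noise), true 3D cell envelopes, background fluorescence and
touching-cell intensity bleed-through. Passing recovery tests therefore
demonstrates that the measurement chain is unbiased and correctly calibrated
for data satisfying its own assumptions — not that those assumptions hold
for any particular microscope or stain.

## Problem sizes and determinism

The default synthetic geometry is a 512×512 frame with 21 planes at
dz = 0.4 µm, dxy = 0.1 µm, mirroring the acquisition geometry; tests and the
acceptance script run reduced frames (64–300 px, 4–15 planes) and moderate
populations (50-cell gradient recovery, 500-cell shape recovery, 1000-repeat
t-test null calibration on simulated half-NAPV samples), sizes chosen so the
whole benchmark completes in seconds while keeping Monte-Carlo standard
errors far below the effects being measured. All randomness flows from
explicit seeds through `numpy.random.default_rng`; rows are sorted and CSV
floats fixed-formatted, so identical config + seed reproduces outputs byte
for byte.

## Known limitations

* The per-field normalization makes NAPVs comparable within a field but
  compresses between-field effects; absolute intensity differences between
  treatments are not interpretable after normalization.
* The replicated-2D-mask model overstates TPN for rounded cells and is blind
  to z-dependent footprint changes.
* The contributing-octant threshold θ is a heuristic; its output should be
  read together with the octant overlap table, not alone.
* The equal-variance t-test is exact under its assumptions; with heavy
  variance imbalance between halves a Welch variant would be preferable
  (not provided, by fidelity to the source protocol).
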