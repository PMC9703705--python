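# Methods

This note records the models, parameter choices, and numerical decisions
behind `panicle3d`, and what the synthetic-data tests do and do not
demonstrate about real reconstructions.

## Input model

The unit of analysis is a colored point cloud: N points with XYZ coordinates
in reconstruction units and RGB intensities on 0–255. Clouds come from
multi-view stereo reconstruction of rotating-camera image sequences; that
reconstruction (and its camera calibration) is upstream of this package —
the PLY file is the input boundary. Reconstruction units carry no metric
scale; an optional `units_per_cm` factor, supplied by the user from an
external calibration, converts projected areas to cm². Without it all areas
are in squared reconstruction units, which is sufficient for within-scale
comparisons and for normalization ratios.

PLY reading accepts ASCII and binary-little-endian vertex elements, the
`red/green/blue` and `r/g/b` property spellings, and float colors on a 0–1
scale (rescaled to 0–255 on read). ASCII columns are cast through their
declared storage type so both dialects yield bit-identical clouds.

## Image pre-masking

Background removal operates in HSV with inclusive per-channel ranges,
default H ∈ [0,1], S ∈ [0,1], V ∈ [0.15,1]. Value is max(R,G,B)/255; with
the full hue and saturation ranges the default reduces to a value floor that
removes near-black chamber background. Bounds are inclusive at both ends —
the full [0,1] hue range must retain every hue, which forces that choice.
Retained pixels are unchanged; removed pixels are set to black.

## Segmentation

- **VARI** = (G−R)/(G+R−B) per point. When the denominator is zero the point
  is colorimetrically degenerate; it is assigned 0 and flagged. Zero fails
  the strict `VARI > 0.1` test, which matches the intent that such points are
  not green evidence.
- **Connectivity** is voxel-grid 26-adjacency at a configurable `voxel_size`.
  Components are computed on the occupied-voxel adjacency graph (hash lookup
  of the 26 neighbor offsets + sparse connected components), so cost scales
  with the number of occupied voxels, not with the scene bounding box. Two
  guarantees bound the construction against a metric closure: any pair of
  points closer than one voxel size is always linked, and 26-adjacency never
  links points farther apart than 2√3 voxel sizes. The test suite asserts
  both nestings against an O(N²) brute-force oracle.
- **Default voxel size** is 2× the median nearest-neighbor spacing of the
  cloud. This adapts to reconstruction density but assumes the object of
  interest is sampled contiguously at that spacing; for sparse or blobby
  clouds an explicit `voxel_size` on the scale of the gap between panicle
  and clutter is the more reliable setting, and the examples use 1.0
  reconstruction unit.
- **Selection**: the cluster with the largest count of points with
  VARI > 0.1 wins; ties break to the larger cluster, then the lowest label.
  If no cluster has a qualifying point a no-panicle error is raised rather
  than returning an arbitrary component.
- An optional **residual filter** (off by default) drops points inside the
  selected cluster that are simultaneously non-green (VARI ≤ threshold) and
  spatial outliers (medoid distance > 5 MAD) — the signature of plant labels
  or ties riding along in the panicle component.

## Whole-panicle traits

- **Frame**: eigen-decomposition of the coordinate covariance. Z is the
  first principal direction with its sign set by an up-hint (default world
  +Z, the capture-rig vertical; PCA alone cannot distinguish up from down).
  The X-axis sign is set by the third moment of the X projections, making
  the frame fully intrinsic: a rigidly moved cloud gets the rigidly moved
  frame, and all traits are invariant to machine precision (the acceptance
  suite verifies ≤1% over 20 random rigid motions; observed drift is
  ~1e-13). Collinear or coincident clouds raise a geometry error.
- **Projection sweep**: the plane contains Z; its normal is Y rotated by the
  sweep angle about Z. Angles run over [0°, 180°) because orthogonal
  projection is 180°-periodic; the default 5° step gives exactly 36 areas.
  Max, min, and mean are taken over the sweep, and the mean is the PPA used
  for normalization. The two axis-perpendicular areas (normals X and Y)
  correspond to sweep angles 90° and 0°.
- **Silhouette area**: area of the region enclosed by the boundary of the
  projected 2D points. Default is the classical alpha shape (Delaunay
  triangulation, keep triangles with circumradius ≤ α, sum their areas),
  with convex hull and occupancy raster as alternatives; a concave boundary
  is truer for branched silhouettes, and the alpha shape is never larger
  than the convex hull. The automatic α is 3× the median Delaunay **edge
  length** of the projected points. Nearest-neighbor spacing is deliberately
  not used here: a silhouette stacks the front and back of the organ into
  near-coincident 2D points, which deflates NN statistics by an order of
  magnitude while leaving triangle sizes unchanged; on a 5×10⁴-point sphere
  shell the edge-length rule recovers the disc area within 0.1%, while an
  NN-based α of the same multiplier loses a third of the area. Degenerate
  projections (<3 points, or collinear) return area 0 with a warning.
- **Voxel count**: occupied cells of a regular grid anchored at the cloud's
  minimum corner, default resolution 2× median NN spacing. In
  `extract_traits` the grid is laid out in frame-local coordinates, so the
  count is a property of the panicle rather than of its pose.
- **Color proportions**: default sums channel intensities,
  green = ΣG/(ΣR+ΣG). A point-classification mode (green if G > R) is
  available; whether published "pixel proportions" sum intensities or count
  classified points is ambiguous in general, so both are exposed and the
  choice is a parameter, not a hidden constant.

## Slicing

Equal Z-extent partition (not equal-count quantiles) of [z_min, z_max] in
the panicle frame into n = 10 intervals, half-open at interior cuts so a
boundary point joins the upper slice; slice 1 is top-most. Empty slices
carry count 0 and flagged NaN proportions, and replicate averaging in
`profile_matrix` skips them. Conservation is exact by construction: slice
point counts and per-channel sums partition the whole-cloud totals, and the
whole-cloud green proportion equals the ratio of summed per-slice channel
sums. Slicing defaults to the PCA frame; passing an explicit frame slices
along any chosen axis (e.g., the world vertical).

## Physiology

Fluxes are normalized per m²: flux / (area_cm2 / 10⁴), with PPA as the
panicle's area and the chamber aperture as the leaf's. The cm²→m²
conversion is applied exactly once, at normalization. WUE = A/E with E = 0
rejected. Percent change is 100·(treated − control)/control — signed, and
asymmetric in its arguments by definition. Percent fertility is
100·filled/(filled + completely sterile). The Pearson panel computes
pairwise r and two-sided p-values (t transform, n−2 df) per
genotype × treatment × timepoint stratum; zero-variance traits and pairs
with <3 complete replicates are flagged NaN rather than zeroed, and no
multiple-testing correction is applied. A `pre_normalized` flag accepts
instrument output that is already per-area, since leaf chambers commonly
report per-area fluxes directly.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure the pipeline depends on: a curved
rachis (quadratic bend, so the PCA axis and the chord differ and frame
robustness is exercised), ~10 primary branches with axial points and
Gaussian spikelet blobs, apical spikelets at the tip, a linear top-to-bottom
green→red gradient standing in for the chlorophyll/ripening gradient, and
gray clutter clusters with VARI ≈ 0. Default sizes (15-unit rachis, 6–10
branches, ~13,000 points) approximate a reconstructed primary panicle at
moderate density. Colors are drawn green-dominant with probability
interpolated linearly along height; green-dominant points sample
RGB ≈ (N(60,15), N(180,20), N(50,15)), red-dominant swap R and G, clutter is
gray N(120,10). Under this model the intensity ratio G/(R+G) of a cloud with
green-dominant fraction f is 0.25 + 0.5·f in expectation, so gradient
recovery is checked in classification mode, which estimates f directly.

What passing these tests shows: the segmentation rule, the projection sweep,
the slicing partition, and the normalization algebra are implemented
correctly and are invariant where they should be. What it does not show:
robustness to reconstruction artifacts absent from the generator —
non-Gaussian color noise, specular highlights, density falloff inside the
canopy, holes, ghost points, or clutter that is both green and touching the
panicle. The gas-exchange cohort likewise draws Gaussian noise around
programmed cell means (default 2 genotypes × 2 treatments × 2 timepoints,
n = 4, 5% relative noise; control means A = 20/3.0 µmol m⁻² s⁻¹ and
E = 4×10⁻³/1×10⁻³ mol m⁻² s⁻¹ for leaf/panicle, plausible mid-day values for
rice) and says nothing about instrument drift or leak artifacts.

## Problem sizes and tolerances

Analytic projection oracles use 5×10⁴-point primitives (sphere within 3% of
πr² at every angle, axial cylinder within 5% of 2rh — the cylinder's caps
and sparse rim sampling dominate its ~3.7% error). Segmentation recovery is
measured on 200 seeded reduced scenes (~2,000 panicle + 800 clutter points;
Jaccard ≥ 0.99 required, 1.0 observed). Rigid invariance uses 20 random
rotations with a 1% band. Gradient recovery uses ≥10⁴ points with a 0.05
per-slice band; percent-change recovery at n = 4 allows 15% of the
programmed effect, the scale of the sampling error of a ratio of cell means
at 5% noise. These sizes keep the full suite and the acceptance script each
within a couple of minutes on one CPU while leaving every tolerance
comfortably cleared.

## Known limitations

- Connected-component selection assumes the panicle is one component at the
  chosen voxel size; a panicle touching green foliage would merge with it
  (semantic separation is out of scope).
- The alpha-shape area treats the silhouette as filled at the α scale; true
  see-through gaps smaller than α are counted as area.
- Metric scale must come from the user; no checkerboard recovery.
- The voxel count depends on grid resolution; only counts at the same
  resolution (and in the same frame convention) are comparable.
- Percent-change and correlation utilities operate on cell means and small
  n; they are descriptive, not inferential — no hypothesis tests on real
  plant material are reproduced here.
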