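# Methods

This note documents the models, numerical choices and open design decisions
behind `smfishquant`, and what the synthetic benchmark does and does not
establish about behaviour on real microscope data.

## Image model and stack layout

A field of view is a multi-page TIFF holding four interleaved channels per
focal plane, in acquisition order TMR, CY5, DAPI, widefield (configurable).
With 25 or 26 z-positions spaced 200 nm apart this gives 100 or 104 pages.
Internally every channel is a `(n_z, height, width)` array; coordinates are
0-based with x = column, y = row, z = plane index, everywhere including the
exports. Stack metadata (z-step, channel order, source id) travels in the
TIFF image description as JSON, so round trips are lossless.

## Nuclear segmentation

Detection happens in 2D on the maximum-intensity projection of the DAPI
stack. The global threshold defaults to Otsu's method on the projection;
a manual value always overrides it (the original workflow chose this
threshold by eye, and automation is needed for unattended runs — both paths
share all downstream code). Connected regions outside `[min_area,
max_area]` (defaults 20 and 2000 px, calibrated on the synthetic
generator's geometry) are discarded.

Each surviving 2D nucleus is then grown into 3D with a cell-specific
threshold: background + 50% of (brightest DAPI voxel in the nucleus column −
background). The *background* is defined here as the median projection
intensity outside all detected nuclei — the source workflow never defines
it, and the median is insensitive to the nuclei themselves. Growth keeps the
26-connected component containing the brightest voxel, restricted to the
nucleus footprint's column; 26-connectivity is the permissive standard for
blob-like nuclei. Whether the original 3D step used connectivity-constrained
growth or pure per-column thresholding is not documented; this choice is
recorded here as ours. The threshold rule is affine-equivariant: scaling
intensities and background together leaves the segmentation unchanged.

## Cell segmentation

The cell outline image is the maximum projection of the last `n_last = 5`
widefield planes. Background is removed by subtracting a disk-mean-smoothed
copy (radius 15 px by default); the local mean is normalized by the
in-bounds kernel mass so that a constant offset subtracts to exactly zero
at the borders too. Nucleus seeds are imposed as the only regional minima
of the inverted contrast image by greyscale reconstruction-by-erosion (the
classic minima-imposition recipe), and a marker-based watershed floods each
basin from its seed. Foreground is `contrast > Otsu(contrast)` union the
seeds; basins without a seed remain background. Whether the original
watershed ran on a gradient or on inverted intensity is unstated; inverted
intensity is our recorded choice. Cells outside `[50, 5000]` px or within
20 px of the border are removed and survivors are renumbered with their
nuclei in lockstep, so cell k ↔ nucleus k is a bijection. Morphology per
cell: area, centroid, and the major/minor axes of the ellipse with matching
second-order moments.

## Spot detection

Each dye stack is Gaussian-smoothed (σ = 1 voxel) and filtered with a
negated Laplacian of Gaussian at σ = (1.4 lateral, 1.2 axial) voxels;
per-axis sigmas absorb the anisotropic sampling (200 nm axially vs ~65 nm
laterally at this magnification). Spots are the 26-connected regional
maxima of the filtered volume at or above the detection threshold; a flat
plateau maximum is reported once, at its rounded centroid, which makes the
output deterministic.

Thresholds follow the one-mean-per-dye-per-sample scheme: a per-image
threshold is derived from one representative image of each stack and the
arithmetic mean over all images of the sample is applied everywhere. The
representative image defaults to the maximum projection of the filtered
stack rather than a single z-plane: a single plane only sees the spots
within ~2σ axially, which makes sparse images unusable for thresholding,
and the projection's noise ceiling automatically matches the full volume's.
(`threshold_plane` can still be set to `middle`, `brightest`, or a plane
index.)

The automatic per-image threshold exploits the plateau in the
spot-count-versus-threshold curve: regional-maxima intensities are
collected, a noise floor is extrapolated as median + 5 × (90th percentile −
median), and the threshold is the midpoint of the gap between the brightest
sub-floor maximum and the dimmest supra-floor maximum. At least 5 maxima
must clear the floor; otherwise the image is declared spot-free and either
contributes nothing to the sample mean or (stand-alone) returns a ceiling
above all maxima so that detection yields zero spots. Whether the original
manual thresholds were set on raw or filtered planes is not documented;
this implementation thresholds the filtered image. A manual threshold
always wins.

## Compartment assignment

Nuclear membership is evaluated in 3D at the spot voxel; cytoplasmic
membership in 2D on the cell footprint, mirroring the dimensionality of the
segmentation products (3D nucleus masks, 2D cell masks). Nuclear assignment
takes precedence, so no spot is double-counted; spots outside all cells are
tallied as unassigned, and spots in cells that the filter removed are
discarded as segmentation failures rather than reassigned. Counts are
regional maxima within masks (not above-threshold voxel clusters); the
alternative reading is noted but not implemented.

## Population statistics

* **Mean** molecules per cell, per gene/timepoint.
* **Fano factor** = variance / mean, with population variance (÷N) by
  default (`ddof` switchable); undefined (NaN, not 0) when the mean is 0.
* **ON threshold** T = smallest integer such that ≥ a coverage fraction
  (default 95%) of the pre-stress (t = 0) cells have count ≤ T; a cell is
  ON iff count > T. The boundary convention (≥ at the coverage point) is a
  recorded choice. The published cutoffs for the original data (>2 *STL1*,
  >8 *CTT1*) ship as documented defaults for reuse.
* **Marginal / joint distributions** are empirical masses over integer
  counts; joint marginals equal the marginal distributions exactly in
  counting space (float summation order can differ in the last ulp).
* **Replicate aggregation**: across-replica mean and sample SD (÷(n−1));
  a single replica reports NaN SD.
* **KS test**: two-sample, asymptotic p-value, no continuity correction.
  Count data are discrete and tied, which makes the asymptotic p-value
  conservative; the D statistic itself is exact. Which pairing (replicas,
  conditions, timepoints) to compare is left to the caller.

## Synthetic benchmark

The generator emulates the acquisition geometry (full scale: 25 z × 2048 ×
2048 at 200 nm; default test scale: 12 z × 256 × 256 to keep the suite
fast — all sizes configurable) and the statistical structure of the data:

* cells are non-overlapping ellipses (default semi-axes 9–12 px) clear of
  the border margin, with optional deliberately planted border cells;
* each cell holds one ellipsoidal nucleus; its DAPI rendering is a smooth
  blob whose half-maximum surface coincides with the true boundary, so the
  50%-of-range rule recovers the planted geometry;
* widefield renders flat-topped cell interiors that meet at intensity
  valleys, which is what the background-subtracted projection of real
  transmitted-light images looks like to the watershed;
* molecule counts per cell are Poisson(λ) or a two-state mixture
  (ON-probability p, OFF/ON means λ₀/λ₁), split nuclear/cytoplasmic by a
  fraction f_nuc; spots are 3D Gaussians at the PSF scale (σ = 1.4/1.2
  voxels lateral/axial);
* spot placement enforces a minimum pairwise separation (default 6 voxels
  laterally, scaled by the lateral/axial PSF ratio along z) so "resolvable"
  scenes really are resolvable. A nuclear spot that cannot be placed
  resolvably in the small nucleus is placed in the cytoplasm and recorded
  there — the ground truth is always what was rendered. Only genuinely
  crowded cells fall back to the best-separated candidate;
* noise: the spot amplitude is snr × √(offset + read²); sparse signal
  voxels receive exact Poisson shot noise, while the dense background term
  (offset ≈ 100 counts, deep in the Gaussian regime) is drawn as its normal
  limit folded with the read noise. Everything is deterministic given the
  scene seed; experiment seeds derive from (base seed, replicate, timepoint,
  field).

What passing the synthetic suite does **not** show: robustness to optical
aberrations, photobleaching, hybridization background, transcription-site
spot clusters brighter than single molecules, or cell-shape classes the
ellipse model lacks (buds, chains). Those require validation on real data.

## Recovery experiment sizing

The end-to-end recovery benchmark runs two replicate experiments of five
timepoints: t = 0 is a pure pre-stress basal sample (no ON cells,
OFF mean 0.1 molecules), and the ON probability then steps 0.05 → 0.6 over
the four stress timepoints (ON mean 12, f_nuc 0.25, 2000 cells per
timepoint per replicate). Two sizing facts drove this design:

* Deriving T from a basal sample whose ON mass equals exactly 1 − coverage
  puts the coverage point on the OFF/ON cluster boundary: T then jumps deep
  into the ON cluster in about half of all realizations, for any ON mean —
  the estimator is ill-posed there. A genuine basal reference (as in the
  real experiment, where pre-stress expression is very low) makes T stable.
* The invariant being tested presumes well-separated spots. In the
  downscaled geometry an ON mean of 15 in default-size cells exceeds the
  resolvable packing capacity (every missed detection in a diagnostic run
  had a planted neighbour within 4.6 voxels); ON mean 12 with 10–13 px
  cells keeps induced cells inside capacity. At full acquisition scale the
  same molecule numbers are far below capacity.

## Degenerate inputs and tie-breaks

Empty stacks, blank projections, flat planes, zero-spot fields, zero-cell
scenes and single-replica aggregations all return well-defined results or
raise instructive errors (flat planes instruct manual thresholding; missing
basal samples instruct an explicit T). Plateau maxima collapse to rounded
centroids; filtering is idempotent; merging count tables from disjoint
fields is exact concatenation.

## Known limitations

* The 2D cell mask means a spot above or below a neighbouring cell's
  footprint at an extreme z is still assigned to that cell; the original
  workflow shares this property.
* Compartment splits can flip for spots within one voxel of the nuclear
  boundary (localization is voxel-level); totals are unaffected.
* The asymptotic KS p-value is conservative for heavily tied count data.
* Mother/bud resolution, transcription-site decomposition and sub-voxel
  localization are out of scope.
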