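# Methods

This note documents the models, conventions and numerical choices behind
`nanofa`, in the spirit of a software methods section: what is computed,
under which assumptions, and where design decisions were genuinely open.

## Scope and data model

The unit of analysis is a field of view with three co-registered 2D
channels: an actin reporter (cell outline), a vinculin reporter (focal
adhesions), and a pillar/surface channel. The pixel size is carried in nm
(34 nm by default, the in-plane optimum of the Airyscan configuration the
pipeline targets). Surface (`flat`, `p1000`, `p2000`, …) and time (`24h`,
`48h`, …) labels come from configuration or a samplesheet CSV — never from
filename parsing. The canonical interchange format is OME-TIFF (channel
order actin/vinculin/pillar) so tests and users never need a proprietary
reader.

## Preparation and segmentation

**Pillar-background subtraction.** Fluorescence from the pillar dyes
bleeds into the vinculin channel, so the pillar channel is subtracted
pixelwise and negative values are clipped to zero (intensity semantics).
`subtract_pillar_background` takes an optional `scale`: 1.0 reproduces the
standard full-channel subtraction; passing a known cross-talk fraction
subtracts exactly the bleed-through term, which is how the generator's
cross-talk linearity is verified.

**Median filter.** The denoising scale is a 10 px neighbourhood. An even
window has no centre pixel, so the default realises it as the nearest odd
square window (9×9, scipy `reflect` edge handling); the window size is
configurable. Note this filter erases vinculin spots much smaller than the
window — adhesions near the 0.05 μm² area cut-off (~43 px at 34 nm) are at
the detection limit by construction.

**Multi-Otsu.** Three-class thresholds are found by exhaustively
maximising the between-class variance over a 256-bin histogram (vectorised
over all cut pairs; ties broken towards the smallest threshold tuple, so
the result is fully deterministic). Thresholds are returned as upper bin
edges, which makes `value < t → lower class` exactly reproduce the
histogram partition. The brightest class is the FA-rich population. An
image with fewer distinct intensities than classes raises; the pipeline
treats that degenerate case as "no FA candidates" and still measures the
cells. The implementation is cross-checked in the tests against both a
naive exhaustive search and scikit-image's `threshold_multiotsu`.

**Cell segmentation.** The original method is stated only as
intensity-based detection on the actin signal, so the concrete chain here
is a design choice: Gaussian smoothing (σ = 2 px), global two-class Otsu,
morphological closing (disk radius 5 px), hole filling, 8-connected
labelling, and a 100 μm² minimum cell area. Closing uses edge-padded
morphology so a region touching the image border remains border-touching —
the default policy then excludes it, because shape metrics of truncated
cells are meaningless; `border_policy="keep"` is available. The stage
order subtraction → median → classification is fixed; a regression test
documents that permuting the first two steps changes the FA-rich pixel
count on cross-talk-containing scenes.

## Morphometrics

Areas are pixel counts times (pixel size)². Each region is fitted with
the ellipse sharing its second central moments; with eigenvalues
λ₁ ≥ λ₂ of the normalised second-moment matrix the full axes are 4√λ₁ and
4√λ₂. This convention makes the fitted axes of an exact ellipse equal its
geometric axes, which matters because roundness (unlike aspect ratio) is
not convention-invariant. Collinear regions get a one-pixel minor-axis
floor and a `degenerate` flag. On rasterised ellipses the axes are
recovered within 2% for regions ≥ 200 px; the aspect ratio compounds both
axis errors and is good to ~3% at high elongation.

**Perimeter.** No estimator is canonical for digital shapes. The raw
marching-squares contour overestimates smooth boundaries by ~6%
(staircase effect), biasing circularity of a disk to ~0.89. The estimator
used here simplifies each closed 0.5-level contour to a near-minimum-length
polygon (Douglas–Peucker, tolerance 1 px) after rolling the contour to
start at its vertex farthest from the contour centroid, which anchors
genuine corners so they are not cut. Digital disks and squares are then
recovered within ~0.5%, and circularity changes by <1% when the raster
resolution doubles. The tolerance is exposed (`tolerance=0` gives the raw
contour). A constant ≲0.5 px per true corner is still lost, so squares
much smaller than ~100 px side show a mild upward circularity bias.

Circularity is reported without clamping at 1: residual values slightly
above 1 for near-circular regions are discretisation bias and are shown
as such rather than hidden.

## FA filtering and localisation

A candidate is any connected component of the FA-rich class inside the
union of cell masks, assigned to the cell containing its centroid. Filters
are rejection-inclusive at the boundaries: AR ≤ 1.5 (too round), AR ≥ 8.5
(too elongated), area < 0.05 μm². The rejection log names every failing
rule per region, and candidate counts are conserved
(`candidates = accepted + rejected`), asserted in the run manifest.

Edge distances use the exact Euclidean distance transform of the cell
mask, scaled to μm. The per-cell normalising radius is the maximum of the
distance map — for a disk this equals the radius, matching the "maximum
distance from edge to geometric centre" reading; the literal
distance-at-centroid is deliberately not the default because it differs
for non-convex cells. FA centroids are continuous, so the distance map is
sampled bilinearly (nearest-pixel lookup is the config alternative). A
centroid falling outside its cell's mask (adhesions at the very periphery)
yields d = 0 with a flag instead of an error, so record counts stay
conserved. The second normalisation divides by the equivalent-circle
radius √(Area/π) — a dimensionally consistent convention (for a disk both
normalisations coincide), labelled as such in outputs.

## Group statistics

Two-tailed Mann-Whitney U throughout, assuming neither normality nor equal
variance. The exact null distribution is used when n₁·n₂ ≤ 400 and the
pooled sample is tie-free (validated against full enumeration in the
tests); otherwise the normal approximation with tie-corrected variance and
continuity correction. Stars: `ns` at p ≥ 0.05, `*`, `**`, `***` by
decade, `****` at p ≤ 10⁻⁴ (the four-star bound is inclusive; the other
interval bounds are half-open from above). Quartiles use linear
interpolation. Raw pairwise p-values are reported by default, mirroring
how such comparisons are usually presented; Holm adjustment is available
but off. FAs are pooled across cells within a group by default
(`pool_fas`), which treats adhesions as exchangeable and ignores per-cell
clustering — a known limitation, not corrected here.

## The synthetic generator

The generator emulates the features the pipeline must cope with, not
optics: a star-convex cell (disk radius modulated by low-order Fourier
modes with seeded random phases — guarantees a single hole-free
component and smooth control of circularity), additive oriented line
segments as cosmetic actin texture, a vinculin channel with strictly
ordered background/cytosol/FA levels, planted elliptical adhesions with
pixel-accurate ground-truth areas and edge distances (read off the
distance transform of the planted mask, bilinearly at the centre), a
hexagonal (default) or square pillar lattice of Gaussian spots with
closed-form areal density, linear cross-talk into the vinculin channel,
and optional Poisson/Gaussian noise — both off in oracle tests. All
randomness flows through one `numpy` generator from the scene seed;
identical specs give bit-identical scenes.

Default study conditions: 512×512 px fields at 34 nm/px, cell base radius
220 px (~7.5 μm, area ~176 μm² — a compact adherent cell), FA major axes
~1–1.4 μm with aspect ratios ~3, intensity levels 10/60/160 (and 120 for
actin). Distance cohorts for power analyses are drawn from a log-normal
fitted to requested quartiles (median fixes μ, interquartile ratio fixes
σ) — positive and right-skewed like real edge-distance data. The test
cohorts use medians 0.9 [0.6, 2.1] μm vs 3.1 [1.2, 7.7] μm at n = 300 per
group, the dense-array/flat-glass contrast scale.

What the generator does **not** model: the optical PSF and Airyscan
reconstruction, membrane deformation around pillars, 3D structure,
adhesion maturation over time, and spatially correlated background. A
passing recovery test therefore shows the chain is internally correct on
images satisfying its assumptions, not that segmentation is robust to
every real-world artefact.

## Problem sizes

The default verification runs use 20-image synthetic cohorts at 512×512,
1000 null replicates at n = 200 per group for type-I calibration, 100
replicates at n = 300 per group for power, 100 random histograms / 50
random ≤ 64×64 masks for the brute-force oracle comparisons, and
enumeration-based Mann-Whitney checks up to 10+10 observations. These
sizes give stable estimates (binomial SE on the type-I rate ≈ 0.007)
while keeping the whole suite fast enough to run habitually.

## Known limitations

- The 0.05 μm² area cut-off interacts with the median window: sub-window
  adhesions are erased before they can be explicitly rejected, so the
  rejection log undercounts "too small" regions relative to the planted
  truth.
- Touching cells are not split (no watershed); the border policy and
  minimum area are the only instruments for field selection.
- Perimeter (hence circularity) of regions only a few pixels across is
  dominated by discretisation; values for such regions should not be
  compared across resolutions.
- The 456 pillars/100 μm² sometimes quoted for 500 nm-pitch arrays matches
  neither hexagonal (≈462) nor square (400) closed-form packing; density
  reporting here is restricted to the geometries the closed forms cover.
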