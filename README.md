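# nanofa

Quantification of cell morphology and focal-adhesion (FA) organisation from
two-channel fluorescence micrographs of cells cultured on nanopillar
arrays — plus a synthetic-image generator that provides exact ground truth
for every stage of the analysis.

## Who this is for

Labs imaging adherent cells (e.g. U2OS expressing LifeAct-GFP and
TagRFP-vinculin) on nanostructured substrates and asking how pillar pitch
and density change cell shape and where focal adhesions form. The package
turns a folder of multichannel OME-TIFFs into tidy per-cell and per-FA
tables and pairwise group statistics, and it can simulate the whole imaging
situation so the pipeline is testable without microscope data.

## The analysis

For each field of view (actin, vinculin, pillar channels; pixel size
typically 34 nm):

1. **Cross-talk removal** — the pillar channel is subtracted from the
   vinculin channel, `max(V − P, 0)`.
2. **Denoising** — square median filter (10 px scale, realised as the
   nearest odd 9×9 window).
3. **Three-class multi-Otsu** — thresholds maximising between-class
   variance split the vinculin histogram into background, cytosolic
   vinculin, and the bright FA-rich class.
4. **Cell segmentation** — Gaussian smoothing + two-class Otsu on the
   actin channel, morphological closing, hole filling; border-touching
   cells excluded by default.
5. **Morphometrics** — pixel-count areas corrected for pixel size, a
   second-moment ellipse fit per region, and

   - aspect ratio `AR = MajorAxis / MinorAxis`,
   - circularity `C = 4π·Area / Perimeter²`,
   - roundness `R = 4·Area / (π·MajorAxis²)` (= 1/AR for an exact ellipse).

6. **FA filtering** — vinculin regions that are too round (`AR ≤ 1.5`),
   too elongated (`AR ≥ 8.5`) or smaller than 0.05 μm² are rejected.
7. **Edge distances** — the Euclidean distance transform of each cell mask
   gives the shortest distance `d` from every FA centroid to the cell
   edge; `d` is normalised by the cell's maximum edge distance (its
   "radius" for circular cells) and, alternatively, by the
   equivalent-circle radius `√(Area/π)`.
8. **Group statistics** — two-tailed Mann-Whitney U tests between all
   (surface, time) groups with the usual star convention (`ns` at
   p ≥ 0.05 down to `****` at p ≤ 10⁻⁴), plus `Q2 [Q1, Q3]` summaries.

The generator (`nanofa.simulate`) renders star-convex cells, planted
elliptical adhesions, hexagonal or square pillar lattices (closed-form
areal density, e.g. 115 pillars per 100 μm² at 1000 nm pitch), pillar
cross-talk and Poisson–Gaussian noise — all driven by one seed, with a
ground-truth table of planted areas, aspect ratios and edge distances.

## Worked example

`python examples/analyse_image.py` simulates a cell with four planted
adhesions and runs the full chain:

```
stage counts: {'n_cells': 1, 'n_fa_candidates': 3, 'n_fa_accepted': 2,
               'n_fa_rejected_ar': 1, 'n_fa_rejected_area': 0}

per-cell morphometrics:
 area_um2  perimeter_um  circularity  roundness  aspect_ratio  n_fa
  176.171        47.262        0.991      0.903         1.105     2
(planted cell area: 176.1 um^2)

accepted focal adhesions:
 fa_id  area_um2  aspect_ratio  d_um  d_norm_maxr  d_norm_area
     0     0.397         3.059 4.010        0.565        0.536
     1     0.237         2.781 6.942        0.978        0.927
(planted edge distances: [6.939, 4.01, 4.178, 4.694] um)
```

Two of the four planted adhesions pass the shape filters; their recovered
edge distances match the planted values to within one 34 nm pixel
(`d_norm_maxr` = 0.98 means that adhesion sits almost at the cell centre,
0 would be on the edge). The other examples cover scene simulation, the
analytic shape limits and cohort-level Mann-Whitney comparisons.

The same pipeline runs from the shell:

```sh
nanofa simulate --config scene.yaml --out sim/ --n-images 6 --seed 1
nanofa run --config run.yaml --out results/
```

with a samplesheet CSV (`path,surface,time`) assigning conditions.

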