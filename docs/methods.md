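# Methods

This note documents the models, procedures and numerical choices behind
`mapcover`: a pipeline that turns georeferenced RGB scans of hand-coloured
nineteenth-century topographic map sheets (the Danish Høje Målebordsblade
conventions) into machine-readable land-use/land-cover (LULC) layers,
assesses their accuracy on a point grid, and cross-tabulates them against a
contemporary categorical raster.

## The mapping problem

On the historical sheets, five target categories are drawn with distinct
conventions:

| category   | convention |
|------------|------------|
| forest     | areal colour wash (drab green) |
| wetland    | variable pale wash + a staggered-dash marsh symbol |
| heath      | variable pink wash + a plant-tuft symbol |
| dune sand  | no wash; a regular field of small black stipple dots |
| water body | solid black shoreline; blue wash often only near the shore |

Everything else (contours, hachures, text, boundaries) is black ink that
interrupts the washes.  The pipeline therefore works in three stages:
enhancement (colour algebra + assist masks), per-category extraction
(threshold segmentation or dot clustering, plus object processing), and
integration (tile/sheet mosaicking).

## Derived layers

From 8-bit R, G, B we compute hue (hexcone), saturation
(1 − min/max(intensity, 1)), intensity ((R+G+B)/3), and the band ratios
redness R/(G+B+1), greenness G/(R+B+1) and blueness B/(R+G+1); each is also
available on histogram-normalised or inverted band values, and any ordered
pair (a, b) of these layers yields a normalised difference
(a−b)/(a+b), set to 0 when both operands vanish.  Choices worth noting:

* **ε = 1 denominator stabiliser.**  The ratio denominators add one 8-bit
  count, keeping values finite on black pixels while leaving the 8-bit-scale
  interpretation intact.
* **Ratios, not bands.**  A multiplicative fade of the scan cancels in the
  ratios and normalised differences (up to the ε term), which is precisely
  why such layers separate washes more reliably than raw bands.
* **Histogram normalisation** is per-band average-rank equalisation over
  valid cells, rescaled to [0, 255] so downstream formulas see the familiar
  scale; it is a monotone transform of each band.
* **Hue of achromatic pixels** is defined as 0; intensity is the band mean
  (remote-sensing HSI convention).

## Assist masks

* **Black-parts mask**: intensity ≤ 80 and saturation ≤ 0.25 (defaults;
  both configurable).  All ink — linework, text, symbols, stipples.
* **Water assist**: regions of non-ink cells fully enclosed by ink (after a
  single 3×3 closing to bridge one-cell gaps; flood fill with
  4-connectivity from the border defines "enclosed") that contain at least
  one blue seed (blueness ≥ 0.9) are filled entirely; free-standing seeds
  pass through.  This recovers lakes whose wash covers only the near-shore
  zone.
* **Steep-slope mask**: ink components whose skeleton length lies in
  3–25 m and whose moment eccentricity is ≥ 0.9 count as hachure strokes;
  where a sliding 100 m window holds ≥ 8 strokes the ground is steep, and
  the mask is dilated by one half-window to span inter-stroke gaps.  The
  stroke-length/eccentricity/density parameters are free parameters of this
  package with the defaults above.

## Colour-category extraction

Segmentation thresholds one derived layer.  Forest and water bodies use one
fixed (layer + threshold) rule; the shipped defaults (greenness ≥ 0.62,
blueness ≥ 0.85) are tuned to the bundled synthetic conventions and carry no
claim about any archival calibration — per-archive configuration is
expected.

Wetland and heath washes vary sheet by sheet, so their rule is chosen per
sheet from the category's point symbol: template matching (normalised
cross-correlation with a 0.7 px Gaussian pre-blur on ink and template, which
makes the score tolerant to pixel-scale ink degradation; non-maximum
suppression within one template diameter; τ = 0.8) yields detections.  For
each candidate layer, the non-ink cells within 20 m of each detection are
summarised per detection, and the signal level is the *median* of the
per-detection means (with the median per-detection SD as signal spread):
rule selection only needs some of the symbols to be found, and the median
keeps a minority of false detections — the template firing on another
category's signature — from dragging the statistic.  The background is an
equal count of seeded random non-ink cells, and separability
|μ_s − μ_b| / pooled SD picks the winner (ties fall to bank order).  The
threshold is the midpoint of the two levels, directed toward the signal.
At least 5 detections are required; otherwise a configured fallback rule
applies or the error propagates.  The default candidate banks contain only
monotone-thresholdable layers; hue is excluded because a circular quantity
has no well-defined midpoint threshold.

Object processing then:

1. **Linework bridging + size filter.**  Thin ink lying within a
   closing (disk radius 3 px) of the threshold mask is treated as part of
   the object: fragments separated by contour lines re-join for the
   2 500 m² minimum-object test and the ink cells themselves are claimed,
   matching the drawn extent of the category under its linework.  Wide ink
   (text blocks) is not bridged.  The public `segment_by_rule` operation
   remains the plain threshold + 4-connected size filter; bridging is an
   orchestration step of `extract_category`.
2. **Steep second pass**: the same threshold inside the steep mask with a
   far smaller minimum size (100 m²), so washes broken up by hachures are
   kept.
3. **Water union**: the water category adds the water-assist regions.
4. **Clutter filling**: enclosed holes are filled when ≤ 1 000 m² or when
   ≥ 50 % ink (text/linework).
5. **Boundary regularisation**: majority voting over the 4-neighbourhood of
   boundary cells, ties keeping the current value (2 iterations).  This
   preserves flat edges and right-angle corners exactly while removing
   single-cell spikes and notches — a parameter-light stand-in for
   surface-tension-style resizing operators.
6. **Polygonisation**: exact cell-edge tracing (below).

## Dune sand from stippling

Dots are 4-connected ink components of 2–30 px with compactness
4πA/P² ≥ 0.5 (P counts exposed cell edges; a 2×2 dot scores 0.79, a 10×2
dash 0.44).  Aggregation mirrors density-based clustering: a dot with ≥ 3
other dots within 25 m is *core*; the extent is the union of 15 m discs
around core dots and dots within reach of a core, holes ≤ 1 000 m² filled,
regions < 2 500 m² dropped.  All values are package defaults — the source
conventions fix dot size and density only qualitatively.

## Mosaicking

Quarter tiles (each half-sheet extended 1 km past the centre split, so
adjacent tiles share a 2 km strip; the tile-size convention follows the
half-plus-overlap reading) are dissolved, and merged objects intersecting an
overlap zone are re-tested against the minimum size on their joint geometry.
Across abutting sheet borders, polygons whose separation is ≤ 20 m inside a
50 m analysis strip are bridged by the convex fill of their in-strip parts
clipped to the strip; geometry only, labels never change, and area outside
the strips is conserved exactly.

## Accuracy assessment

A regular grid (100 m equidistance, points at cell centres of the grid
offset by half a spacing) is labelled with one or more observed categories
(multi-label within the 50 m interpretation radius).  Extraction overlaps
are arbitrated by a fixed priority (water > forest > wetland > heath > dune
sand; unclaimed cells are `other`).  A point counts as correct when the
extracted category matches *any* observed label; on a miss the point is
tabulated under its first-listed observed category (the source convention
for combined points is not recorded; first-listed is this package's
documented choice, and the table records it so alternatives can be
compared).  FP%(c) = (row − diag)/row, FN%(c) = (col − diag)/col,
overall% = Σdiag / Σrow-totals, rounded half-up to one decimal as in the
published table.  Margins of published tables can be stored verbatim
(`CrossTab.from_margins`) because printed tables are not always internally
consistent to the last count.

## Change analysis

Historical layers are rasterised to the contemporary 10 m grid with the
cell-centre rule (centres strictly inside; the contemporary raster's own
grid anchors the conversion).  A historical cell of a target category whose
label disagrees with the contemporary map but lies within 40 m
(cell-centre Euclidean distance) of the same category is re-coded
*aligned-stable* — counted as stable downstream — which suppresses sliver
transitions from delineation discrepancies between two independently drawn
maps.  Re-coding (rather than geometric shifting) is used because it is
order-independent and conserves row sums: Σ_to counts[from][to] always
equals the historical cell count of *from*.  Alignment is applied one way
(historical → contemporary) and never touches agreeing cells.  Outputs are
the transition matrix (cells and km²), per-category loss/stable/gain
rasters, and a long-form flow table whose per-origin percentages sum to 100.

## Synthetic scenes

The generator emulates the drawing conventions so the pipeline is testable
without archival scans.  Category geometry comes from thresholded smoothed
Gaussian random fields (correlation length 50 m), claimed sequentially at
exact target cell counts (defaults: forest 0.20, heath 0.15, wetland 0.12,
dune sand 0.08, water 0.03); components under 5 000 m² revert to background
so every truth object is mappable.  Rendering layers paper
(232, 226, 210) → washes (forest 120, 170, 115; wetland 165, 195, 225;
heath 215, 150, 155) with smooth per-band jitter (SD 5), a ±5 %
multiplicative fade gradient and pixel noise (SD 2) → water rim wash
(70, 110, 200; 30 % of each body nearest the shore) → ink: quantised-DEM
contour boundaries (2 px), vertical hachure strokes (12 m at 20 m spacing)
in steep zones, solid shorelines, text-block words, wetland/heath symbol
stamps at 25 per km² of category area, and 2×2 stipple dots on a 10 m
jittered lattice with a 5 m boundary margin.  Stipples are not overprinted
onto existing linework (a 1-px halo must be clear), matching engraving
practice and keeping dots dot-sized.  The wetland palette is designed to
separate best on nd(blueness, redness) and heath on raw redness; these
*intended discriminating layers* are published so rule selection can be
scored.  A contemporary raster is produced by partitioning each category's
cells into spatially coherent destination patches at requested
row-stochastic rates (quantile slices of a smoothed field — realised
proportions are exact up to discretisation), and the validation grid is
auto-labelled from truth (own category first, then every target present
within 50 m).

What the scenes do **not** emulate: paper texture and bleed-through,
cross-sheet colour drift beyond the fade gradient, combined/overlapping
signatures, rivers, and georeferencing distortion.  Passing the synthetic
bars therefore demonstrates the correctness and robustness of the object
processing chain under the stated conventions, not archival-scan
performance.

## Problem sizes and tolerances

The synthetic-recovery checks use ten seeded default scenes of
2 km × 2 km at 1 m cells — large enough that every category appears with
dozens of objects while a full ten-scene sweep stays in the minutes range.
Mean IoU bars are 0.85 for the wash categories and 0.80 for dune sand; rule
selection must pick the intended layer in ≥ 9 of 10 scenes per category;
transition-rate recovery must hold to ±3 percentage points.  Geometric
round trips (rasterise ∘ vectorise, tile reassembly, mosaic idempotence)
are exact, not approximate: the polygoniser traces cell edges and assigns
boundary ties strictly to the polygon interior side.

## Known limitations

* Fixed forest/water rules must be calibrated per archive; no automatic
  fading detection (choose the alternative source raster in config).
* Overlapping category extractions are flagged and arbitrated only at
  validation time, never merged or relabelled.
* The polygon bridging rule at sheet borders is a concretisation of
  "neighbourhood decision rules"; each bridge is logged for audit.
* Rivers, buildings and roads are out of scope.
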