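# Methods

## The problem

Induced pluripotent stem cells (iPSCs) and similar lines are hard to segment
in single-channel phase-contrast images: they have low edge contrast, highly
variable morphology, and adhere into clumps, and live-imaging rigs typically
offer no nuclear channel to seed a conventional two-step segmentation.
`phasedyn` implements a two-stage workflow for this setting:

1. **Multi-scale segmentation.** Threshold-based object identification is
   run at several length scales in parallel and the per-scale label maps are
   integrated with largest-object priority.
2. **Time-dimensionality reduction.** Per-object features measured at every
   hour are collapsed, per feature and aggregation group, to the gradient of
   a linear trend, giving a single *gradient signature vector* per
   (cell line, condition) whose pairwise correlations quantify phenotype
   similarity.

## Segmentation model

A raw frame is rescaled to [0, 1] by its dtype's nominal range and inverted,
so that cells (dark in phase contrast) become the bright phase.  Each scale
`s` applies a manual threshold `theta_s` and keeps 8-connected components
whose equivalent diameter `2*sqrt(area/pi)` lies in the scale's typical
diameter window; components touching the frame border are dropped.  Defaults
(three scales):

| scale | threshold | diameter window (px) |
|------:|----------:|---------------------:|
| 1     | 0.78      | 5–20                 |
| 2     | 0.75      | 21–40                |
| 3     | 0.74      | 41–65                |

Thresholds decrease slightly with scale so that larger, dimmer structures
are still captured; the thresholds are the pipeline's only intensity
parameters and are meant to be tuned once per microscope/exposure setting.
Within each scale, objects whose minimum pixel-to-pixel distance is at most
`unify_distance` (default 2 px) are unified.

Integration then proceeds in two steps:

* **Scale priority.** A smaller-scale object whose overlap fraction with the
  union of all larger-scale objects exceeds `overlap_policy` (default 0:
  any shared pixel) is discarded entirely.  The largest object at a location
  wins; sub-objects are removed rather than trimmed.
* **Contract / merge / relabel / expand.** Every surviving object is eroded
  by `contraction_radius` (default 1 px, 3x3 structuring element),
  independently per object; an object that would vanish keeps its ultimate
  eroded pixel set (the maxima of its interior distance transform) instead.
  The eroded stack is unioned, re-segmented by connected components, and
  each component is expanded back over the original (pre-erosion) footprint
  by nearest-core Euclidean assignment, ties going to the smaller label.
  Contraction is what keeps *distinct* touching objects separate through
  the merge while overlapping segmentations of the same cell fuse.

Expansion deliberately restores the full pre-erosion footprint rather than
dilating by exactly `contraction_radius`: digital disks and ellipses
frequently carry single-pixel boundary bumps that lie farther than one
Chebyshev step from the eroded core, so a radius-capped dilation would lose
pixels and break the guarantee that well-separated objects come out of the
round trip unchanged.  With footprint restoration the conservation property
holds by construction and is asserted in the tests.

Two consequences are intended behaviour, not artifacts:

* Clumps of adherent cells — overlapping in the rendered/thresholded mask —
  are segmented as **one object**.  Adjacent cells are indistinguishable in
  intensity, and clump morphology is itself an informative phenotype.
  Cells inside a clump cannot be resolved.
* Objects whose only contact is a neck of width comparable to the
  contraction radius (e.g. disks touching at a single pixel) are split:
  this is precisely the "avoid merging distinct neighbouring objects" role
  of the contraction step.

The final merged objects are *not* filtered by the advisory final diameter
range (default 1–40 px) because that would delete large clumps; a strict
mode (`enforce_final_diameter`) is available.  All tie-breaks are
raster-scan order / smaller label; segmentation uses no randomness, so a
frame plus a configuration determines the label map byte for byte.

## Feature families

53 features per object in four families (17 intensity, 17 shape,
7 neighbour, 12 radial), fixed in an ordered registry that downstream
signature vectors depend on.  The registry is extensible; conventions:

* Quantiles interpolate linearly between order statistics; standard
  deviations are population SDs; angles are degrees in [0, 180).
* An object's edge is its pixels with an 8-neighbour outside the object.
* Perimeter is the traced 8-connected boundary path (holes included) with
  Kulpa's corrected step weights (0.948 straight, 1.340 diagonal).  The raw
  1/sqrt(2) chain length overestimates a circle's circumference by ~5%,
  which would push a disk's form factor to ~0.91; the corrected estimator is
  within ~1% of `2*pi*r` for radii >= 5, so FormFactor of a digital disk is
  ~1 as it should be.
* Solidity uses the convex hull of pixel *centers*, with membership decided
  by exact integer cross products, so oracle tests can assert it exactly.
  Degenerate (collinear) objects have solidity 1.
* Feret diameters are caliper widths of the hull swept in 1° steps.
* Radius statistics summarize the interior Euclidean distance transform.
* Neighbour adjacency is evaluated on the nearest-object partition of the
  frame (every object expanded until the frame is tiled); PercentTouching
  counts edge pixels within 2 px (configurable) of another object.
* The radial coordinate of a pixel is `d_edge / (d_edge + d_center)`
  (0 at the object edge, 1 at the innermost pixel = the distance-transform
  maximum); ring 1 is the outermost of 4 equal rings, and RadialCV is the
  coefficient of variation of per-wedge intensity sums over 8 angular
  sectors about the centroid.
* Features undefined for an object (second-closest neighbour with fewer
  than three objects, empty rings) are NaN, never zero.

## Population dynamics

Per aggregation group (well, or condition = replicate wells sharing e.g. a
fibronectin concentration) and per feature:

* **Heatmaps.** Values at each hour are histogrammed over `n_bins`
  (default 50) equal bins spanning the group's global min/max (dynamic bin
  size), each populated hour normalized to unit mass so hours with
  different cell counts are comparable.  Whole-matrix max normalization is
  available as an option.
* **Hourly statistic.** One non-iterative pass removes values more than
  `sd_k` (default 3) population SDs from the hour's raw mean; the default
  statistic is then the interquartile mean (mean of values between Q1 and
  Q3 inclusive) of the remainder.  The IQR width and midhinge are provided
  as alternatives; the interquartile mean is the default because it is the
  natural robust center consistent with averaging interquartile values
  hour by hour.
* **Trend.** Ordinary least squares of the hourly statistic on the integer
  acquisition index (starting at 0; missing hours are simply absent).
  Groups with fewer than 3 usable hours keep their summary row with a
  missing gradient.  The intercept is reported but not interpreted.
* **Signatures and correlation.** Gradients in registry order form one
  signature vector per (cell line, condition); Pearson correlation on
  pairwise-complete entries compares vectors, either raw (default) or
  feature-z-scored (useful because gradients carry heterogeneous units).

## Synthetic data

The generator emulates an automated-incubator acquisition: hourly frames
for 24 h per well, ~10 cells per well rendered as dark disks
(`background - contrast`, defaults 0.9 − 0.8) with a bright 1–2 px halo
ring, additive Gaussian noise (SD 0.01), clipped to [0, 1].  Cell areas
grow linearly at a condition-dependent rate (defaults 2/4/8 px²/h for
fibronectin 1/5/25 µg/mL) and, with a per-hour clump probability
(default 0.05), a cell is moved into overlapping contact with its nearest
neighbour; from that hour the pair is one truth object, matching how a
manual count treats clumps.  Everything is deterministic given the spec
seed, with independent substreams per (well, hour).

What the generator does **not** emulate: phase-contrast optics (diffraction,
shade-off), focus drift, uneven illumination, cell division/death, motility,
or non-circular morphology.  Passing tests therefore demonstrate the
algorithmic guarantees (exactness on resolvable objects, invariants,
determinism), not segmentation accuracy on real microscopy.

A second generator produces object tables directly from designed per-feature
linear trends (value = intercept + slope·hour + Gaussian noise), as a
controlled harness for the reduction stage, and `segmentation_metrics`
scores a predicted label map against truth by greedy one-to-one matching on
descending intersection-over-union (threshold 0.5), with deterministic tie
breaks.

## Problem sizes and numerical checks

The test suite and the acceptance script use desk-scale runs: 100 frames of
band-sampled disks (bands 6–18 / 24–38 / 44–60 px so every object sits
strictly inside one scale window) for segmentation exactness; 100 random
multi-scale layouts for round-trip conservation; 200 random blobs (≤ 30x30)
against brute-force pixel-enumeration oracles for the shape features;
100 seeds x 53 features (200 objects/hour, 24 h, noise SD 1) for gradient
recovery within 3 standard errors; 100 seeds of two synthetic lines with
replicate noise for within- vs between-line correlation; and a fixed-seed
4-well plate run twice for bit-identical CSV outputs.

## Limitations

* No single-cell resolution inside clumps; object counts on heavily
  confluent cultures reflect clump counts.
* Thresholds are manual by design; frames whose contrast regime differs
  from the configured thresholds will under- or over-segment.
* Linear trends only: populations with strongly non-linear dynamics are
  summarized by a secant-like slope.  Higher-order trend models are out of
  scope.
* Persistence targets CSV and single-file SQLite; no network database
  client is included.
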