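# Methods

This note documents the models and procedures implemented in `scrubseg`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Coordinate and raster conventions

All vector geometry lives in map units (metres). The map origin is the
top-left corner of the top-left pixel; x grows with the pixel column and y
with the pixel row. Pixel (row, col) covers the half-open square
`[col·res, (col+1)·res) × [row·res, (row+1)·res)`, so polygons derived from
label maps have vertices on pixel corners and their areas equal pixel count
× `res²` exactly. Holes in canopy polygons are preserved, never filled, so
area bookkeeping in the error metrics matches the pixel partition.
Rasterisation of polygons uses the pixel-centre rule. Georeferencing
travels as a JSON sidecar (`<raster>.aux.json` with `resolution` and
`origin`) next to plain TIFF/PNG pixels; there is no coordinate reference
system handling — all inputs to one analysis are assumed to share a local
metric frame.

Intersection arithmetic with floating point produces slivers; any area or
overlap below 10⁻⁶ m² is treated as zero throughout.

One representational edge case: a 4-connected pixel region pinched at a
diagonal corner cannot be expressed as a single valid simple polygon; the
polygonizer keeps it as one segment whose geometry is a point-touching
MultiPolygon, after verifying 4-connectivity on the pixel grid.

## Region-merging segmentation

Segmentation is bottom-up pairwise region merging controlled by Scale,
Shape and Compactness. Pixels start as singleton regions on a 4-connected
adjacency graph (4-connectivity avoids segments merging through corners).
The merge criterion for adjacent regions 1 and 2 is

    f = (1 − shape) · h_colour + shape · h_shape
    h_shape = compactness · h_cmpct + (1 − compactness) · h_smooth

with, per band b (weights w_b, default equal):

    h_colour = Σ_b w_b · (SSD_b(1∪2) − SSD_b(1) − SSD_b(2))

where SSD is the total squared deviation from the region's band mean
(n·σ²), i.e. the colour term is the increase in within-region variance mass
caused by the merge. The shape terms compare merged-minus-parts deviations
of `perimeter·√n` (compactness) and `n·perimeter / bounding-box perimeter`
(smoothness), with perimeters counted in pixel edges. Geometric bookkeeping
is in pixel units, which makes the criterion independent of ground
resolution: the Scale parameter plays the same role at 0.5 and 0.03
m/pixel. The shape terms can be negative for compactness-improving merges;
the criterion is clamped at zero, consistent with the contract that merge
costs are non-negative.

A merge executes while the *globally cheapest* admissible pair costs less
than `scale²` (strict inequality), ties broken by lowest region labels in
row-major order. Global cheapest-first ordering was chosen over
local-mutual-best-fitting for three reasons: it is deterministic with a
trivial tie-break; it has an obvious brute-force oracle (rescan all pairs
each step), against which the heap-based engine is tested exhaustively on
small grids; and it makes the merge order independent of Scale, so
partitions are nested across Scale. That nesting gives two properties the
toolkit leans on: segment count is provably non-increasing in Scale, and
one recorded merge trace per (Shape, Compactness) can be cut at every Scale
during a sweep, identical to re-segmenting from scratch (asserted in
tests). Whether the comparison is against `scale` or `scale²` is a
convention; `scale²` is used and documented, which matches the colour term
having variance (squared-intensity) units. No minimum-segment-size cleanup
is applied.

## Parameter sweep

`run_sweep` evaluates the full Cartesian grid (inclusive endpoints,
deterministic lexicographic order) and ranks rows by ED2; ties resolve to
lower Scale, then Shape, then Compactness — preferring the simplest
solution deterministically. Default ranges are Scale 80–430 step 5 and
Shape/Compactness 0.1–0.9 step 0.1 (5751 combinations; a per-image Scale
sub-range of 80–265 gives 3078). Execution is serial; results are
by construction independent of evaluation order. The helper
`scale_bounds_from_object_size` narrows the Scale range from the areas of
the objects to be segmented: bounds grow as `√area / resolution` (the
object's linear size in pixels) and are clamped to the global 80–430
range. This is a heuristic — the criterion links Scale to accumulated
heterogeneity, not directly to object size — but it preserves the two
properties that matter: proportionality to 1/resolution and monotone growth
with object size.

## Accuracy metrics

Let r_k (k = 1..m) be the reference polygons and s_i the segments. A
segment *corresponds* to the reference set when its overlap with the
reference union exceeds max(sliver, 5% of its own area). The 5% own-area
fraction keeps a large background segment that merely grazes a shrub out
of the corresponding set, while any reasonably shrub-sized segment
overlapping a reference is counted; the threshold is exposed in the API
and CLI. Then

    PSE = Σ_{corresponding i} area(s_i \ ∪r_k) / Σ_k area(r_k)
    NSR = |m − v| / m          (v = number of corresponding segments)
    ED2 = √(PSE² + NSR²)

PSE counts overestimation only (area outside the references); a segment
that undershoots its reference contributes nothing to PSE — the deficit
shows up in detection recall instead. Non-corresponding segments never
affect PSE; they surface as detection false positives.

Detection scoring is greedy one-to-one matching by descending IoU with a
0.5 default threshold (the community standard for instance segmentation),
ties broken by segment then reference id; TP + FN = m and TP + FP = number
of predictions always hold. Precision and recall are defined as 0 when
their denominator is 0, and F1 as 0 when P + R = 0.

All metrics are invariant under uniform scaling and translation of all
coordinates (tested). Reported tables round half-up at the printed
precision (4 decimals for PSE/NSR/ED2, 2 for P/R/F1); internal computation
is full double precision.

## Fusion

Two segmentations are paired one-to-one by descending overlap area (greedy,
deterministic id tie-breaks), and each matched pair is intersected into one
consensus polygon. Greedy assignment rather than optimal matching is
near-optimal for spatially scattered, non-overlapping canopies and keeps
the procedure O(p log p) and reproducible. When the two inputs disagree on
the object count, unmatched segments are excluded from the consensus but
reported in a side channel, so both "drop" and "keep" policies remain
available to callers. Intersections that break into several parts keep the
largest part (one consensus object per shrub pair); parts below the sliver
tolerance are dropped. The operation is commutative and idempotent up to
the sliver filter, and every consensus polygon is contained in both
parents — which is why fused PSE can never exceed the smaller parent PSE
when the same segments correspond.

## Synthetic scenes and perturbation models

The generator emulates the target system: square plots (default
250 × 250 m) of scattered shrubs over bare soil, at sub-metre resolutions.
Canopy outlines are random star-convex polygons — radial harmonics of
order 2–5 with amplitude `roughness/h` around the unit circle, rescaled to
the sampled area — rather than circles, so irregular boundaries exercise
the shape terms of the merge criterion. Canopy areas are uniform in
[12, 311] m² by default; placement is rejection sampling with a minimum
2 m canopy gap, failing loudly when the packing is infeasible. Colours are
Gaussian: shrub mean (60, 90, 50), soil mean (150, 130, 110), σ = 10,
chosen to give clear but noisy class contrast typical of RGB orthoimagery;
an optional low-frequency soil-brightness texture is off by default. No
radiometric statistics were available for the real plots, so these defaults
are declared, not fitted. All randomness flows from one integer seed
through `numpy.random.default_rng`; derived generators use deterministic
child seeds, so scenes and perturbations are bit-reproducible.

Perturbation specs degrade a reference set with one error mode each —
dilate, erode, shift, smooth-boundary (buffer-based, magnitudes in
metres), split, merge, drop, spurious (count modes, governed by a
per-object probability). `make_method_pair` produces two independently
seeded candidates standing in for region-merging-like (boundary
overestimation) and CNN-like (localisation) error structure.

What passing these tests shows — and does not. The synthetic scenes have
pure two-class colour statistics, no mixed boundary pixels, no shadows, no
nebkha micro-topography, no small companion shrubs, and perturbations that
are geometrically clean. They validate the algorithmic contracts
(determinism, monotonicity, metric arithmetic, the fusion-improvement
mechanism) — not field performance on real imagery, which depends on
radiometric conditions the generator does not model.

## Problem sizes used in the test suite

Tests run on scaled-down instances chosen to exercise each property at the
smallest size where it is meaningful: oracle equivalence on ≥ 100 random
grids up to 8 × 8; Scale monotonicity on 15 × 15 m plots; the fusion
experiment on 20 full-size (250 × 250 m, 60-shrub) reference sets with
dilation 0.5 m versus shift 1.0 m — magnitudes picked as plausible
boundary-overestimation and localisation errors at these canopy sizes, with
the dilation smaller than the shift so each input retains a distinct error
mode; and sweep recovery on one 500 × 500-pixel scene at 0.1 m/pixel with
a 12-point parameter grid.

## Known limitations

- The merge criterion reproduces the qualitative Scale/Shape/Compactness
  semantics of commercial multiresolution tools, not any implementation
  bit-for-bit; hierarchical multi-level segmentation is out of scope.
- Fusion of more than two segmentations is not implemented (a documented
  extension point).
- PSE ignores underestimation by construction; pair it with recall when
  undershoot matters.
- The pure-Python merging engine handles ~250 k pixels in tens of seconds;
  scenes much beyond 10⁶ pixels call for tiling.
- Shapefile I/O and CRS reprojection are not provided; convert to GeoJSON
  in a local metric frame first.
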