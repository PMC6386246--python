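# Methods

This note records the model behind `fazseg`, the parameters that
matter, what the synthetic phantoms do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Pipeline model and assumptions

The pipeline assumes an en-face OCT-A projection in which perfused
vessels are bright, the FAZ is a connected dark region near the image
center (acquisitions are macular-centered), and the field of view is a
known square of 3 or 6 mm.  Intensities are min-max normalized to
[0, 1] on load; a constant image is rejected as degenerate.  All later
thresholds are either relative to the image mean or morphological, so
the pipeline is invariant to global affine intensity changes.

Stages and their tunables (config keys, defaults in brackets):

| stage | operation | key parameters |
|---|---|---|
| enhance | white top-hat, disc element | `tophat.selem_radius` [width/32 → 10 px at 320] |
| edges | Canny, mean-adaptive hysteresis | `canny.sigma` [1.0 px], `canny.low_frac` [0.66], `canny.high_frac` [1.33] |
| candidates | closure → invert → opening | `morph.close_radius` [width/64 → 5 px], `morph.open_radius` [width/53 → 6 px] |
| filtering | peripheral / eccentric / disperse rules | `fp.border_margin_frac` [0.05], `fp.max_center_offset_frac` [0.8], `fp.min_solidity` [0.3] |
| growing | erosion seed + add/delete sweeps | `grow.seed_erosion_radius` [3 px], `grow.tolerance_frac` [0.3], `grow.abs_floor_frac` [0.18], `grow.max_iterations` [100] |

The top-hat element must be wider than a vessel cross-section (1–5 px
here) and narrower than the FAZ; width/32 satisfies both across 3 and
6 mm fields at 320 px.  The closure element sets the largest
intercapillary gap that is sealed (2 × radius); the opening element
sets the smallest avascular region that can survive as a candidate.
All three scale with image width so a configuration transfers between
resolutions.

**False-positive rules.**  "Peripheral" and "disperse" needed
quantitative definitions.  Peripheral: touching the border, or bounding
box within 5% of the short image side of any border — this removes the
dark bands that capture errors leave along borders.  Eccentric:
centroid farther than 80% of the inscribed half-extent from the image
center.  Disperse: pixel count below 30% of the bounding-box area.
The selected candidate is the survivor with the largest perimeter
(ties: larger pixel count, then the more central centroid).

**Region growing.**  The seed is the preliminary region eroded by a
3 px disc (halving the radius if erosion would empty it; centroid-pixel
fallback).  Each sweep computes ARV, the mean enhanced-image intensity
of the current region, accepts the interval
`ARV ± max(tolerance_frac·ARV, floor)`, adds every 8-neighbor inside
the interval, deletes every region pixel outside it except the anchor
seed, and keeps the single connected component containing the seed.
Recomputing ARV once per sweep (not per pixel) makes the result
independent of intra-sweep visiting order.  The sweep loop stops at the
first fixed point; on phantoms it converges in 5–20 sweeps, and
`max_iterations` (100) is a hard bound.

Two deliberate safeguards extend the plain add/delete scheme:

* *Anchor exemption.*  Deletion never removes the original seed
  pixels; without this, a seed placed on locally atypical intensities
  can evaporate the whole region.
* *Adaptive interval floor.*  The multiplicative interval degenerates
  as ARV → 0, and the FAZ is near zero on the enhanced image: with a
  30% band around ARV ≈ 0.05 almost every dark pixel fails the test
  and growth stalls inside the true region.  The half-width is
  therefore floored at `abs_floor_frac ×` (mean enhanced-image
  intensity).  Making the floor proportional to the image mean — the
  same principle as the Canny thresholds — keeps it below the vessel-
  wall intensity in both high-contrast (superficial) and low-contrast
  (deep) images; a fixed absolute floor cannot do both.  The default
  0.18 sits in the middle of a broad plateau (0.16–0.25 behave
  identically on the phantom suite); 0 disables the floor and
  reproduces the strictly multiplicative rule.

**Perimeter estimator.**  Perimeters (candidate selection and
circularity) use the Crofton formula with 4 projection directions.
The common boundary-transition estimator overestimates smooth digital
contours by ~5%, which alone drops the circularity of a digitized
r = 50 disc to 0.91; Crofton gives 0.99.  Since circularity feeds the
tertile stratification, the low-bias estimator is used everywhere, and
the same estimator backs both modules so selection and scoring agree.
Note that pixelwise region growing produces jagged boundaries whose
true digital perimeter is genuinely long: circularities of grown masks
are systematically lower than those of smooth manual contours and
should only be compared with values computed the same way (the
tertile analysis is rank-based, so this does not affect grouping).

## Evaluation machinery

Localization success is the centroid-in-mask criterion applied to the
*preliminary* extraction: the rounded first-moment centroid must fall
on a foreground pixel of the reference mask.  An empty prediction is a
failure, not an error.  Segmentation quality is the Jaccard index
|A∩B|/|A∪B|; cohort-level area agreement is the Pearson correlation
between automatic and reference area sets.  The circularity-tertile
analysis stably sorts records by circularity and splits them into
three equal groups (remainder to the lower groups: 10 → 4/3/3), then
reports per-group Pearson r and mean Jaccard.

## Synthetic phantoms

The generator emulates exactly the image features the pipeline
exploits:

* a **capillary mesh** rendered as iso-level curves of a
  Gaussian-smoothed random field (correlation length 0.05 mm, 14
  levels): meandering bright curves of naturally varying 1–4 px width
  that tile the field with small intercapillary pores.  Coverage is
  set by quantile so `vessel_density` is matched exactly.  Random
  strokes were rejected for this purpose: unguided walks cluster and
  leave large avascular voids that are morphologically
  indistinguishable from a FAZ, which real plexus images do not show;
* a central **avascular region** bounded by
  `r(θ) = r₀(1 + irregularity · s(θ))` with `s` a unit-amplitude
  random Fourier series over harmonics 2–6; vessels are clipped at the
  contour, and the region (mildly decentered, ±2%) is the ground-truth
  mask;
* **depth styles**: superficial (vessel contrast 0.75 over a 0.12
  background, 0.7 px blur) and deep (0.45, 1.5 px blur) — the diffuse
  low-contrast appearance of deep-plexus projections;
* optional **artifact bands**: one border strip (5–12% of the image
  side) attenuated to 15%, emulating capture errors;
* additive Gaussian noise (σ = 0.03) and clipping to [0, 1].

The default cohort (`generate_suite`) cycles through
{3 mm, 6 mm} × {superficial, deep}, draws the avascular area uniformly
in 0.1–0.6 mm² (the physiological range), irregularity in 0–0.6
(spanning ground-truth circularities from ~1 down to ~0.3), vessel
coverage in 0.45–0.70, and gives 10% of phantoms an artifact band.
All randomness flows from one integer seed through `numpy`'s PCG64
generator; phantoms are bit-exact across runs and platforms.

What the phantoms do **not** emulate: OCT-A speckle/decorrelation
statistics, projection artifacts from superficial onto deep layers,
motion-line artifacts, pathological capillary dropout away from the
fovea, and the smooth closed contours of manual annotation.  Passing
the synthetic suite therefore demonstrates the pipeline's geometric
and photometric logic under controlled conditions, not clinical-grade
accuracy; results on real OCT-A data depend additionally on the
features listed above.

## Benchmark sizes and observed behavior

The cohort benchmark (`fazseg.benchmark.run_phantom_benchmark`, also
behind `scripts/acceptance.py`) uses 200 phantoms at 320×320 px — 50
per subgroup — which gives subgroup means stable to a few hundredths
across seeds.  Oracle-equivalence checks run on rasters ≤ 64×64, where
brute-force morphology and flood fills are exact and fast.  With
default parameters the pipeline localizes ≥ 99% of phantoms, reaches
mean Jaccard ≈ 0.80 overall (≈ 0.88 on 3 mm superficial, the easiest
regime; ≈ 0.68 on 6 mm deep, the hardest, where the FAZ is small in
pixels and contrast is low), and correlates estimated with true areas
at r ≈ 0.96–0.97.  The ordering across subgroups — 3 mm over 6 mm,
superficial over deep — matches what the enhancement/edge model
predicts: fewer pixels per FAZ amplify boundary errors, and lower
contrast weakens vessel-wall barriers.

## Degenerate inputs and edge cases

* Zero-dynamic-range images are rejected on load; an enhanced image
  with zero mean (no structure at all) is a degenerate input to the
  edge detector.
* An image with no avascular zone yields either zero candidates or
  only peripheral ones → a `NoFazFoundError` localization failure,
  which batch tools record as an outcome rather than crash on.  There
  is deliberately no minimum-plausibility gate beyond the three FP
  rules: on images that do contain dark pores the largest-perimeter
  survivor is returned even if small.
* Jaccard of two empty masks and Pearson r of zero-variance sets raise
  `UndefinedMetricError` instead of returning a number.

## Known limitations

* Parameters were validated on phantoms; real OCT-A data may need the
  radii or FP thresholds adjusted via the YAML config.
* The perimeter-based size criterion can prefer a large spurious dark
  region over a genuinely small FAZ (6 mm fields are most exposed);
  the observed phantom failure mode matches this.
* The grown boundary is pixel-jagged; no contour smoothing or
  subpixel refinement is applied.
* Only single-FAZ output is supported by contract; images with
  multiple equally plausible avascular regions return exactly one.
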