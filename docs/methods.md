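# Methods

## The counting model

`rgcount` counts fluorescently labeled RGC somata in calibrated 2-D segments
of a flat-mounted retina. The underlying model of the image is deliberately
simple: somata are bright, compact, roughly circular objects of broadly
similar size on a darker background; overlapping somata merge into a single
connected component whose area is approximately additive in the number of
cells. Under those assumptions the pipeline is

smooth → threshold → binarize → label components → size-exclude → split by
area ratio,

and the per-segment count is

n = #singles + Σ_clusters max(2, round_half_up(A_k / Â)),

where A_k is a cluster's area and Â the estimated mean single-cell area.
There is no randomness anywhere in the detector; identical input and
configuration give bit-identical output.

Z-stacks are collapsed before counting. Maximum-intensity projection is the
default because somata stay bright regardless of which focal plane they sit
in; a mean projection is available for sensitivity checks.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `smoothing_radius` | 1.0 | μm | Gaussian σ of the pre-filter; 0 = identity |
| `tophat_radius` | 0 (off) | μm | optional white-tophat background suppression |
| `threshold_mode` | automatic | — | Otsu (256 bins) or user-supplied value |
| `connectivity` | 8 | — | neighborhood for connected components |
| `min_object_area` | 20 | μm² | size-exclusion cutoff; well below a 10 μm soma (~78 μm²) |
| `cluster_factor` f | 1.7 | — | object is a cluster if area > f·Â |
| `fill_holes` | on | — | fill enclosed background holes before labeling |

Binarization is strict (`I > t`), which fixes boundary-pixel ambiguity.
A constant image under automatic thresholding is an error, not a zero count:
it almost always indicates an acquisition failure.

### Mean single-cell area Â

Clusters would inflate a naive average, so Â is estimated iteratively:
initialize with the median area of all above-noise objects; classify objects
with area in (`min_object_area`, f·Â] as singles; re-estimate Â as the
interquartile-trimmed mean of those singles; repeat to a fixed point (at most
10 rounds; the loop also stops on any revisited value, so it terminates).
On scenes of equal-sized cells the estimate equals that size exactly.

### Why f = 1.7

With somata of one exact size, two cells overlapping at 1.2 radii merge into
a footprint of ≈1.7× the single-cell area (the union of two discs at that
distance is 1.715·πR²), and any boundary between 1 and 1.7 separates singles
from pairs. Real somata scatter in size: at a radius CV of 0.15 the measured
*area* distribution spreads ~30%, so a boundary at 1.5× sits inside the
singles' upper tail and systematically splits the largest 6–12% of single
cells into phantom pairs (a +5–10% count bias). A boundary at 2× instead
misses most true pairs. Calibration on synthetic scenes across the densities
this tool targets (≈2300–4200 cells/mm²) puts the bias-balance point near
1.7, where split-singles and missed-pairs cancel to within ~±1.5% of the
count, roughly independent of density. The boundary remains configurable;
with uniform-size material (or validated segments) 1.5 is the natural
choice and is exercised in the tests.

Residual, irreducible error: singles larger than f·Â are counted as 2, and
pairs of small cells whose merged footprint stays below f·Â are counted
as 1. Both scale with the size dispersion; with CV 0.15 and 10% paired cells
the net per-segment bias is ≈ −1…+1% depending on density. This is a
property of any pure area-ratio rule — it cannot distinguish one large cell
from two small overlapping ones.

## Sampling geometry

The user marks the optic nerve head and the two cut axes (semi-automated
workflow; nothing is detected automatically). The four sectors between the
axes are the quadrants, numbered 1–4 by increasing bisector angle. Segments
are axis-aligned squares (no interpolation, verbatim crops) of 350 μm side,
centered on each quadrant's bisector at band fractions 0.25 / 0.55 / 0.85 of
the outer radius for central / middle / peripheral. Those fractions are a
convention chosen for even spacing — eccentricity bands are not standardized
in this literature — and are configurable. `sample_regions` guarantees
exactly one segment per (quadrant, eccentricity), all inside the image and
pairwise disjoint; with 350 μm segments this requires an outer radius of
roughly ≥1.7 mm (the diagonal-bisector spacing between bands must exceed the
segment side).

Per-retina density is the arithmetic mean of the 12 segment densities;
regional means average the 4 quadrants within a band. One eye per animal is
summarized (left by default); both-eye averaging is a caller-side decision.

## Statistics

Group contrasts: unpaired two-tailed t test, equal-variance by default
(Welch optional); one-way ANOVA with Tukey's HSD for ≥3 groups. Degenerate
zero-variance inputs follow the convention p = 1 when the groups are
identical and p = 0 for a non-zero constant difference. Density–severity
association: Spearman rank correlation with average-rank ties; the p-value
is exact (full permutation enumeration) for n < 10 animals and the
t-approximation otherwise — cohorts in this field are small, and the exact
null costs nothing at n ≤ 9. Automated-vs-manual agreement: paired two-tailed
t test on per-segment count differences, pooled and per eccentricity band,
because the segment is the unit at which manual recounts are made. All four
procedures reproduce an independent reference implementation (R's t.test,
aov/TukeyHSD, cor.test) to at least six significant digits on fixed vectors
frozen into the test suite.

## Synthetic scenes

The generator emulates Brn3a-like staining well enough to stress every stage
of the detector while keeping exact ground truth:

- **Count**: deterministic, `round(density × area)`, so recovery tests are
  sharp; a Poisson option exists for sampling realism.
- **Sizes**: soma radii normal with mean 5 μm and configurable CV, truncated
  at ±2 SD (sizes are biologically bounded).
- **Placement**: dart throwing with a hash grid. Non-paired somata are solid
  bodies: centers must be ≥ r_a + r_b + 1 μm apart, with a 10 μm floor.
  Overlap is modeled *only* through explicitly planted pairs at 1.2× the
  mean pair radius (merged footprint ≈ 1.7–1.8× a single). Densities up to
  ~4500 cells/mm² remain feasible (~0.4 of the jamming coverage); beyond
  that the retry cap raises an error rather than silently under-planting.
- **Rendering**: discs with a logistic edge of width 0.08·R (≈0.9 μm 10–90%,
  matching a 20× epifluorescence PSF), composited with `max` — adjacent
  nuclei do not add their fluorescence, so a cluster's footprint is the
  geometric union of its somata, the regime the area-ratio rule assumes.
- **Noise**: additive Gaussian, clipped at zero; default SD is 5% of the
  foreground-background contrast. No shot noise, vignetting, stitching seams
  or vasculature shadows are modeled.
- Cells are planted fully inside their segment (≈2-radius margin), so the
  planted count is exactly what a detector confined to the segment should
  report; real segments additionally contain boundary-clipped cells.

Cohorts: per-animal densities are normal around group means; behavior scores
are a decreasing linear map of density (4000 → 0, 2000 → 5) plus optional
noise, clamped to [0, 5] and snapped to the clinical 0.5-step scale. Snapping
creates ties, so oracle tests that require a strictly monotone density–score
relation disable it (`snap_scores=False`).

Because the generator omits boundary-clipped cells, uneven illumination,
staining artifacts and non-circular somata, passing its tests demonstrates
the algorithm's correctness and its behavior under size scatter, overlap and
noise — not performance on any particular microscope's output, for which the
manual-agreement workflow (`rgcount agreement`) on real recounts remains the
relevant check.

## Problem sizes used in validation

The validation suite uses 350 × 350 μm segments at 0.5 μm/px (700² px) and
whole-mount scenes of ~2–5 mm at 1 μm/px. Planted-density recovery runs one
12-segment retina per density level (recovered within ±5%; observed spread
of the 12-segment mean is ≈0.6%); the clean-scene exactness check runs 20
seeds; agreement runs 5 retinas (3 control-level at 3683 cells/mm², 2
late-disease at 2272, 60 segments). These sizes mirror the real protocol
(one retina is exactly 12 segments) while keeping the full suite at about a
minute of CPU.

## Known limitations

- The area-ratio rule cannot separate one large from two small overlapping
  somata; the error is bounded by the size dispersion (see "Why f = 1.7").
- Clusters of k ≥ 3 cells in a tight clump have a union area noticeably
  below k× the single area (overlap loss), so large clumps are undercounted;
  at 10% pairing this contributes negligibly.
- Eccentricity band placement is a convention, not a reconstruction of any
  particular lab's segment positions.
- No mixed-effects modeling of eye-within-animal; the statistics operate on
  per-animal (or per-segment, for agreement) values.
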