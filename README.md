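# rgcount

Semi-automated counting of retinal ganglion cells (RGCs) on fluorescence
flat-mount images, for quantifying neurodegeneration in mouse models of CNS
autoimmune disease (e.g. MOG₃₅₋₅₅ EAE) and similar optic-neuropathy studies.

A flat-mounted retina stained for an RGC soma marker (Brn3a and similar
nuclear/somal antibodies) shows bright, roughly circular somata on a noisy
background — densely packed, with frequent touching or overlapping cells.
`rgcount` implements the standard size-segmentation recipe for this setting:

1. **Filter** — Gaussian smoothing (σ in μm, optional white tophat);
2. **Threshold** — Otsu's between-class-variance maximum, or a user value;
3. **Binarize & label** — strict `I > t` mask, hole filling, connected
   components (4- or 8-neighborhood);
4. **Size exclusion** — objects with area ≤ `min_object_area` (default
   20 μm²) are staining noise;
5. **Cluster splitting** — with Â the robustly estimated mean single-cell
   area, an object of area A is a single cell if A ≤ f·Â and otherwise a
   cluster of `max(2, round(A / Â))` overlapping cells (`f` = 1.7 by
   default; Â is an interquartile-trimmed mean iterated to a fixed point).

Counts are taken in the standard sampling scheme: four quadrants (the lobes
created by the four relieving cuts) × three eccentricity bands (central /
middle / peripheral from the optic nerve head), one ~350 × 350 μm segment
each. The 12 segment densities (cells/mm² = count / (side/1000)²) are
averaged into one value per retina.

The package also provides the study-level statistics (unpaired two-tailed t
test, one-way ANOVA with Tukey's HSD, Spearman rank correlation of density
with the 0–5 EAE behavior score, and paired automated-vs-manual agreement)
and a fully ground-truthed synthetic image generator, so the entire pipeline
is testable without microscope data.

## Worked example

```python
from rgcount import SyntheticSpec, generate_segment, count_segment, density

spec = SyntheticSpec(density=3683.0, seed=1)   # healthy-control packing
image, truth = generate_segment(spec)          # 700x700 px, 0.5 um/px
result = count_segment(image)                  # Otsu + size segmentation

print(f"planted cells : {truth.true_count}")
print(f"counted cells : {result.n_total_cells} "
      f"({result.n_singles} singles, {result.n_cluster_objects} clusters, "
      f"{result.n_noise} noise objects)")
print(f"mean soma area: {result.mean_single_area:.1f} um^2")
print(f"threshold     : {result.threshold_used:.1f}")
print(f"density       : {density(result.n_total_cells, spec.side_um):.0f} cells/mm^2")
```

prints

```
planted cells : 451
counted cells : 446 (316 singles, 52 clusters, 0 noise objects)
mean soma area: 81.6 um^2
threshold     : 115.4
density       : 3641 cells/mm^2
```

i.e. on a realistic scene (15% soma-size scatter, 10% of cells in touching
pairs, 5% noise) the automated count lands within ~1% of the planted truth:
merged pairs are recognized as clusters by their ~1.7× area and split by the
rounded area ratio.

From the shell, the same pipeline runs over a whole mount:

```sh
rgcount simulate --mode retina --densities 4000,3000,2000 --seed 1 --out sim/
rgcount count --image sim/retina.tif --pixel-size 0.5 \
    --center-x 4700 --center-y 4700 --radius-um 2000 \
    --animal-id m1 --group naive --out counts/
rgcount compare --counts counts/counts.csv ... --out report.json
```

`count` writes the 12-row per-segment table (`counts.csv`), the per-retina
summary, optional annotated overlays (red outlines and "+" for singles, blue
dots for clusters, green for size-excluded noise), and a `manifest.json`
that reproduces the run. `--mask-id` pseudonymizes the animal id during
counting (masked analysis) and `compare --id-key` re-joins group labels at
the statistics step.

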