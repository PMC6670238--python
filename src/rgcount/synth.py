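"""Synthetic flat-mount scenes with known ground truth.

Emulates Brn3a-like nuclear/somal staining: bright, roughly circular somata
on a noisy background, at a controlled density per mm². Cells are rendered as
discs with a smooth logistic edge (so automatic thresholding is non-trivial
but stable); a configurable fraction of cells is placed as touching pairs to
exercise the cluster-splitting rule; everything is driven by a single seed.

The per-segment cell count is deterministic — ``round(density × area)`` — so
recovery tests are sharp; use ``poisson_counts=True`` for sampling realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import round_half_up
from .geometry import RetinaLayout, SegmentROI, sample_regions
from .io import ECCENTRICITIES, AnimalRecord, CountTable, MosaicImage


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic segment.

    Defaults model a densely packed ganglion-cell layer under mild realism:
    5 μm mean soma radius with 15% size scatter, 10% of cells in touching
    pairs, and additive Gaussian noise at 5% of the foreground/background
    contrast.
    """

    density: float  # cells / mm²
    side_um: float = 350.0
    pixel_size: float = 0.5  # μm/px (≈ 20× objective sampling)
    cell_radius_mean: float = 5.0  # μm
    cell_radius_cv: float = 0.15  # fractional SD of radius
    cell_intensity: float = 200.0  # mean foreground level (a.u.)
    background_level: float = 50.0
    noise_sd: float = 7.5  # additive Gaussian SD (5% of 150 contrast)
    overlap_pair_fraction: float = 0.10  # fraction of cells placed as pairs
    min_separation: float = 10.0  # μm floor between non-paired cell centers
    contact_clearance: float = 1.0  # μm gap enforced between non-paired somata
    pair_separation_factor: float = 1.2  # pair center distance / radius
    edge_softness: float = 0.08  # logistic edge width / radius (~20x PSF blur)
    poisson_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if not (0 <= self.overlap_pair_fraction <= 1):
            raise ValueError("overlap_pair_fraction must lie in [0, 1]")
        if not self.cell_intensity > self.background_level:
            raise ValueError("cell_intensity must exceed background_level")
        if self.side_um <= 0 or self.pixel_size <= 0 or self.cell_radius_mean <= 0:
            raise ValueError("lengths must be positive")
        if self.cell_radius_cv < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be non-negative")

    @property
    def area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2

    @property
    def expected_count(self) -> int:
        return round_half_up(self.density * self.area_mm2)


@dataclass(frozen=True)
class GroundTruth:
    """True cell positions for one generated segment."""

    centers: np.ndarray  # (n, 2) μm
    radii: np.ndarray  # (n,) μm
    true_count: int
    pair_memberships: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.true_count != len(self.centers) or len(self.radii) != self.true_count:
            raise ValueError("true_count must equal the number of centers/radii")
        flat = [i for pair in self.pair_memberships for i in pair]
        if len(flat) != len(set(flat)):
            raise ValueError("pair memberships must be disjoint")


def _sample_radii(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    """Soma radii: normal with the given CV, truncated at ±2 SD.

    Truncation keeps sizes in a biologically plausible band and avoids
    degenerate (near-zero) somata at high CV.
    """
    mean, sd = spec.cell_radius_mean, spec.cell_radius_cv * spec.cell_radius_mean
    if sd == 0:
        return np.full(n, mean)
    radii = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[np.abs(draw - mean) <= 2 * sd]
        take = min(len(draw), n - filled)
        radii[filled : filled + take] = draw[:take]
        filled += take
    return radii


class _GridPlacer:
    """Dart-throwing with a uniform hash grid for min-distance checks.

    Two constraints keep non-paired somata distinct: a scalar floor on
    center-to-center distance (``min_sep``) and solid-body non-interpenetration
    (distance ≥ r_a + r_b + ``clearance``). Overlapping somata are modeled
    only through the explicitly planted pairs.
    """

    def __init__(
        self,
        low: float,
        high: float,
        min_sep: float,
        clearance: float,
        max_radius: float,
        rng: np.random.Generator,
    ):
        if high <= low:
            raise ValueError("placement window is empty; segment too small for the margins")
        self.low, self.high = low, high
        self.min_sep = min_sep
        self.clearance = clearance
        self.cell = max(min_sep, 2 * max_radius + clearance, 1e-6)
        self.rng = rng
        self.grid: dict[tuple[int, int], list[tuple[np.ndarray, float]]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int]:
        return (int(p[0] // self.cell), int(p[1] // self.cell))

    def _clear(self, p: np.ndarray, r: float) -> bool:
        kx, ky = self._key(p)
        for ix in range(kx - 1, kx + 2):
            for iy in range(ky - 1, ky + 2):
                for q, rq in self.grid.get((ix, iy), ()):
                    if np.hypot(*(p - q)) < max(self.min_sep, r + rq + self.clearance):
                        return False
        return True

    def add(self, p: np.ndarray, r: float) -> None:
        self.grid.setdefault(self._key(p), []).append((p, r))

    def throw(self, r: float, max_tries: int) -> np.ndarray:
        for _ in range(max_tries):
            p = self.rng.uniform(self.low, self.high, size=2)
            if self._clear(p, r):
                return p
        raise RuntimeError(
            "could not place a cell: requested density is infeasible under "
            "min_separation (dart-throwing retry cap exceeded)"
        )


def _place_cells(
    spec: SyntheticSpec, rng: np.random.Generator, offset_um: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray, tuple[tuple[int, int], ...]]:
    """Sample centers (μm) and radii for one segment.

    Cells sit fully inside the segment (margin of ~2 radii) so the planted
    count is exactly what a detector confined to the segment should see.
    """
    if spec.poisson_counts:
        n = int(rng.poisson(spec.density * spec.area_mm2))
    else:
        n = spec.expected_count
    if n == 0:
        return np.zeros((0, 2)), np.zeros(0), ()
    n_pairs = round_half_up(spec.overlap_pair_fraction * n / 2.0)
    n_singles = n - 2 * n_pairs
    radii = _sample_radii(rng, n, spec)
    margin = 2.0 * spec.cell_radius_mean * (1 + 2 * spec.cell_radius_cv)
    max_r = float(radii.max())
    placer = _GridPlacer(
        margin, spec.side_um - margin, spec.min_separation, spec.contact_clearance, max_r, rng
    )
    max_tries = max(200, 400 * n)
    centers = np.zeros((n, 2))
    pairs: list[tuple[int, int]] = []
    idx = 0
    for _ in range(n_pairs):
        r_pair = 0.5 * (radii[idx] + radii[idx + 1])
        # both members must be clear of every earlier cell; only the planted
        # within-pair overlap is exempt (the anchor enters the grid last)
        for _ in range(max_tries):
            anchor = rng.uniform(placer.low, placer.high, size=2)
            if not placer._clear(anchor, radii[idx]):
                continue
            theta = rng.uniform(0, 2 * math.pi)
            partner = anchor + spec.pair_separation_factor * r_pair * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            if (
                np.all(partner >= placer.low)
                and np.all(partner <= placer.high)
                and placer._clear(partner, radii[idx + 1])
            ):
                break
        else:
            raise RuntimeError(
                "could not place an overlapping pair: requested density is "
                "infeasible under min_separation (retry cap exceeded)"
            )
        centers[idx], centers[idx + 1] = anchor, partner
        pairs.append((idx, idx + 1))
        placer.add(anchor, radii[idx])
        placer.add(partner, radii[idx + 1])
        idx += 2
    for _ in range(n_singles):
        p = placer.throw(radii[idx], max_tries)
        centers[idx] = p
        placer.add(p, radii[idx])
        idx += 1
    centers = centers + np.asarray(offset_um)
    return centers, radii, tuple(pairs)


def _render(
    canvas: np.ndarray,
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    spec: SyntheticSpec,
) -> None:
    """Paint logistic-edged discs (amplitude = contrast) onto ``canvas`` in place.

    Overlapping cells are composited with ``max``, not summed: adjacent
    stained nuclei do not double their fluorescence where they touch, and the
    merged footprint of a cluster is then the geometric union of its somata —
    the regime the area-ratio splitting rule is built for.
    """
    amp = spec.cell_intensity - spec.background_level
    h, w = canvas.shape
    ps = spec.pixel_size
    for (cx, cy), r in zip(centers_um, radii_um):
        wdt = spec.edge_softness * r
        reach = r + 6 * wdt
        x0 = max(0, int((cx - reach) / ps))
        x1 = min(w, int((cx + reach) / ps) + 2)
        y0 = max(0, int((cy - reach) / ps))
        y1 = min(h, int((cy + reach) / ps) + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = (np.arange(x0, x1) + 0.5) * ps - cx
        ys = (np.arange(y0, y1) + 0.5) * ps - cy
        rr = np.hypot(xs[None, :], ys[:, None])
        disc = spec.background_level + amp / (1.0 + np.exp((rr - r) / wdt))
        np.maximum(canvas[y0:y1, x0:x1], disc, out=canvas[y0:y1, x0:x1])


def render_cells(
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> MosaicImage:
    """Render an explicit cell arrangement (centers/radii in μm) as a segment.

    Useful for constructing controlled scenes — e.g. archetype clusters of k
    touching cells at known positions — outside the random placement path.
    Noise is still applied per ``spec`` (seeded by ``spec.seed`` unless an
    ``rng`` is passed).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    side_px = int(round(spec.side_um / spec.pixel_size))
    canvas = np.full((side_px, side_px), float(spec.background_level))
    _render(canvas, np.asarray(centers_um, float), np.asarray(radii_um, float), spec)
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    return MosaicImage(canvas, spec.pixel_size)


def generate_segment(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[MosaicImage, GroundTruth]:
    """One calibrated synthetic segment plus its ground truth.

    The same spec (same seed) always yields a bit-identical scene.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    centers, radii, pairs = _place_cells(spec, rng)
    side_px = int(round(spec.side_um / spec.pixel_size))
    canvas = np.full((side_px, side_px), float(spec.background_level))
    _render(canvas, centers, radii, spec)
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    truth = GroundTruth(centers=centers, radii=radii, true_count=len(centers), pair_memberships=pairs)
    return MosaicImage(canvas, spec.pixel_size), truth


def generate_retina(
    layout: RetinaLayout,
    densities: Mapping[str, float],
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    animal_id: str = "sim",
    eye: str = "left",
    group: str = "naive",
    timepoint: int = 0,
    side_um: float = 350.0,
    band_fractions: Sequence[float] = (0.25, 0.55, 0.85),
) -> tuple[MosaicImage, CountTable, list[SegmentROI]]:
    """A whole-mount scene whose 12 standard sampling windows carry planted
    per-eccentricity densities, plus the matching ground-truth count table.

    Cells are planted only inside the sampling windows (fully contained, so
    segment extraction sees exactly the planted count); the rest of the mount
    is bare background.
    """
    missing = set(ECCENTRICITIES) - set(densities)
    if missing:
        raise ValueError(f"densities missing for {sorted(missing)}")
    if any(d < 0 for d in densities.values()):
        raise ValueError("densities must be non-negative")
    base = spec if spec is not None else SyntheticSpec(density=0.0)
    if abs(layout.pixel_size - base.pixel_size) > 1e-12:
        base = replace(base, pixel_size=layout.pixel_size)
    rng = np.random.default_rng(seed)
    rois = sample_regions(layout, side_um=side_um, band_fractions=band_fractions)
    h, w = layout.image_shape
    canvas = np.full((h, w), float(base.background_level))
    rows = []
    for roi in rois:
        seg_spec = replace(base, density=float(densities[roi.eccentricity]), side_um=side_um)
        centers, radii, _ = _place_cells(seg_spec, rng, offset_um=(0.0, 0.0))
        offset = np.array([roi.origin[0], roi.origin[1]]) * layout.pixel_size
        _render(canvas, centers + offset, radii, seg_spec)
        count = len(centers)
        rows.append(
            {
                "animal_id": animal_id,
                "eye": eye,
                "group": group,
                "timepoint": timepoint,
                "quadrant": roi.quadrant,
                "eccentricity": roi.eccentricity,
                "count": count,
                "density": count / (side_um / 1000.0) ** 2,
            }
        )
    if base.noise_sd > 0:
        canvas += rng.normal(0.0, base.noise_sd, size=canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    image = MosaicImage(canvas, layout.pixel_size)
    return image, CountTable(pd.DataFrame(rows)), rois


def default_score_model(density: float) -> float:
    """Monotone decreasing density → EAE score map used by the cohort
    generator: 4000 cells/mm² → 0, 2000 cells/mm² → 5, linear between."""
    return 5.0 * (4000.0 - density) / 2000.0


def generate_cohort(
    n_per_group: Mapping[str, int],
    group_density_means: Mapping[str, float],
    between_animal_sd: float = 150.0,
    score_model: Callable[[float], float] = default_score_model,
    score_noise_sd: float = 0.0,
    snap_scores: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[AnimalRecord]]:
    """Per-animal planted densities and matching behavior-score records.

    Densities are drawn per animal around the group mean; scores are a
    decreasing function of the planted density plus optional noise, clamped
    to [0, 5] and snapped to the 0.5-step clinical scale. Snapping induces
    ties between similar animals; pass ``snap_scores=False`` for a continuous
    severity scale (useful when a strictly monotone density–score relation is
    needed, e.g. for rank-correlation oracles).
    """
    if between_animal_sd < 0 or score_noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {g!r} needs at least one animal")
        if g not in group_density_means:
            raise ValueError(f"no density mean for group {g!r}")
    rng = np.random.default_rng(seed)
    rows = []
    records = []
    for g in n_per_group:
        for i in range(n_per_group[g]):
            animal = f"{g}-{i + 1:02d}"
            d = float(rng.normal(group_density_means[g], between_animal_sd))
            d = max(d, 0.0)
            raw = score_model(d)
            if score_noise_sd > 0:
                raw += float(rng.normal(0.0, score_noise_sd))
            if snap_scores:
                raw = round(raw * 2) / 2
            score = min(5.0, max(0.0, raw))
            rows.append({"animal_id": animal, "group": g, "planted_density": d})
            records.append(AnimalRecord(animal_id=animal, group=g, peak_behavior_score=score))
    return pd.DataFrame(rows), records
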