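"""Size-segmentation counting of fluorescently labeled somata.

The pipeline mirrors a semi-automated flat-mount workflow: smooth, threshold
(Otsu or user-supplied), binarize, label connected components, discard
sub-cellular speckle by area, and split merged objects by the rounded ratio
of their area to the average single-cell area. There is no randomness
anywhere in this module: identical input and configuration give bit-identical
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import trim_mean
from skimage import filters, measure, morphology

from .io import MosaicImage


def round_half_up(x: float) -> int:
    """Round with .5 going up (deterministic tie-break, unlike banker's)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the counting algorithm.

    Attributes
    ----------
    smoothing_radius : float
        Gaussian pre-filter σ in μm; 0 disables filtering entirely.
    tophat_radius : float
        White-tophat background suppression radius in μm; 0 (default) off.
    threshold_mode : str
        ``"automatic"`` (Otsu on the segment histogram) or ``"manual"``.
    manual_threshold : float or None
        Intensity used verbatim when ``threshold_mode == "manual"``.
    connectivity : int
        4 or 8; pixel neighborhood defining connected components.
    min_object_area : float
        μm²; objects at or below this are counted as noise (size exclusion).
    cluster_factor : float
        An object is a cluster of overlapping cells when its area exceeds
        ``cluster_factor ×`` the mean single-cell area. Must exceed 1. The
        default 1.7 places the boundary between the upper tail of the
        single-cell area distribution (soma areas scatter ~30% at a realistic
        15% radius CV, so a boundary at 1.5× would split the largest singles)
        and the ~1.7–1.8× footprint of two somata overlapping at 1.2 radii.
    fill_holes : bool
        Fill enclosed background holes in the binary mask before labeling.
    """

    smoothing_radius: float = 1.0
    tophat_radius: float = 0.0
    threshold_mode: str = "automatic"
    manual_threshold: float | None = None
    connectivity: int = 8
    min_object_area: float = 20.0
    cluster_factor: float = 1.7
    fill_holes: bool = True
    max_mean_iter: int = 10

    def __post_init__(self) -> None:
        if self.smoothing_radius < 0 or self.tophat_radius < 0:
            raise ValueError("filter radii must be non-negative")
        if self.threshold_mode not in ("automatic", "manual"):
            raise ValueError(f"threshold_mode must be 'automatic' or 'manual', got {self.threshold_mode!r}")
        if self.threshold_mode == "manual" and self.manual_threshold is None:
            raise ValueError("manual threshold_mode requires manual_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be non-negative")
        if not self.cluster_factor > 1:
            raise ValueError("cluster_factor must exceed 1")


@dataclass(frozen=True)
class LabeledObject:
    """One connected foreground component."""

    object_id: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]  # (x, y) pixels
    boundary: np.ndarray  # (n, 2) ordered outline points, (x, y) pixels

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("objects must contain at least one pixel")


@dataclass(frozen=True)
class ObjectClassification:
    object_id: int
    label: str  # noise | single | cluster
    estimated_cells: int

    def __post_init__(self) -> None:
        ok = (
            (self.label == "noise" and self.estimated_cells == 0)
            or (self.label == "single" and self.estimated_cells == 1)
            or (self.label == "cluster" and self.estimated_cells >= 2)
        )
        if not ok:
            raise ValueError(f"inconsistent classification {self.label}/{self.estimated_cells}")


@dataclass(frozen=True)
class SegmentCount:
    """Detection result for one segment."""

    objects: tuple[tuple[LabeledObject, ObjectClassification], ...]
    mean_single_area: float  # μm²; NaN when nothing was detected
    n_singles: int
    n_cluster_objects: int
    n_noise: int
    n_total_cells: int
    threshold_used: float

    def __post_init__(self) -> None:
        total = sum(c.estimated_cells for _, c in self.objects)
        if total != self.n_total_cells:
            raise ValueError("n_total_cells does not equal the sum of per-object estimates")


def preprocess(segment: MosaicImage, config: DetectorConfig) -> MosaicImage:
    """Optional white-tophat then Gaussian smoothing; identity at radius 0."""
    px = segment.pixels.astype(float, copy=False)
    if config.tophat_radius > 0:
        r = max(1, int(round(config.tophat_radius / segment.pixel_size)))
        px = morphology.white_tophat(px, morphology.disk(r))
    if config.smoothing_radius > 0:
        sigma = config.smoothing_radius / segment.pixel_size
        px = ndimage.gaussian_filter(px, sigma=sigma, mode="nearest")
    if px is segment.pixels:
        return segment
    return segment.with_pixels(np.clip(px, 0, None))


def compute_threshold(segment: MosaicImage, config: DetectorConfig) -> float:
    """Manual pass-through, or Otsu's between-class-variance threshold."""
    if config.threshold_mode == "manual":
        return float(config.manual_threshold)
    px = segment.pixels
    if float(px.max()) == float(px.min()):
        raise ValueError(
            "constant image: automatic thresholding has no foreground/background "
            "classes (check acquisition or use a manual threshold)"
        )
    return float(filters.threshold_otsu(px, nbins=256))


def binarize(segment: MosaicImage, threshold: float, fill_holes: bool = False) -> np.ndarray:
    """Strict ``intensity > threshold`` mask, optionally hole-filled."""
    mask = segment.pixels > threshold
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def label_objects(
    mask: np.ndarray, config: DetectorConfig, pixel_size: float
) -> list[LabeledObject]:
    """Connected components of the mask, with areas and traced outlines."""
    conn = 1 if config.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=conn)
    objects: list[LabeledObject] = []
    for region in measure.regionprops(labels):
        area_px = int(region.area)
        cy, cx = region.centroid
        boundary = _trace_boundary(region)
        objects.append(
            LabeledObject(
                object_id=int(region.label),
                area_px=area_px,
                area_um2=area_px * pixel_size**2,
                centroid=(float(cx), float(cy)),
                boundary=boundary,
            )
        )
    return objects


def _trace_boundary(region) -> np.ndarray:
    """Outer contour of one labeled region as ordered (x, y) points."""
    img = np.pad(region.image, 1)
    contours = measure.find_contours(img.astype(float), 0.5)
    if not contours:  # single pixel fallback (find_contours handles it, belt & braces)
        y0, x0 = region.bbox[:2]
        return np.array([[x0, y0]], dtype=float)
    contour = max(contours, key=len)
    y0, x0 = region.bbox[:2]
    xy = np.stack([contour[:, 1] + x0 - 1, contour[:, 0] + y0 - 1], axis=1)
    return xy


def estimate_mean_single_area(
    objects: Sequence[LabeledObject], config: DetectorConfig
) -> float:
    """Average single-cell area in μm², robust to merged clusters.

    Starts from the median area of all above-noise objects, then alternates
    (i) tagging objects within ``(min_object_area, cluster_factor × mean]`` as
    singles and (ii) re-estimating the mean as the interquartile-trimmed mean
    of those singles, until the estimate stops changing (at most
    ``max_mean_iter`` rounds; the loop also stops on a revisited value).
    """
    areas = np.array([o.area_um2 for o in objects], dtype=float)
    areas = areas[areas > config.min_object_area]
    if areas.size == 0:
        raise ValueError("no object above min_object_area; cannot estimate cell size")
    mean = float(np.median(areas))
    seen = {round(mean, 9)}
    for _ in range(config.max_mean_iter):
        singles = areas[areas <= config.cluster_factor * mean]
        if singles.size == 0:
            break
        new = float(trim_mean(singles, 0.25))
        if math.isclose(new, mean, rel_tol=1e-12, abs_tol=1e-12):
            mean = new
            break
        mean = new
        key = round(mean, 9)
        if key in seen:
            break
        seen.add(key)
    return mean


def classify_objects(
    objects: Sequence[LabeledObject], mean_single_area: float, config: DetectorConfig
) -> list[ObjectClassification]:
    """Noise / single / cluster labels from the area-ratio rule.

    area ≤ min_object_area → noise; area ≤ cluster_factor × mean → single;
    otherwise a cluster of ``max(2, round_half_up(area / mean))`` cells.
    """
    if not mean_single_area > 0:
        raise ValueError("mean_single_area must be positive")
    out: list[ObjectClassification] = []
    for obj in objects:
        if obj.area_um2 <= config.min_object_area:
            out.append(ObjectClassification(obj.object_id, "noise", 0))
        elif obj.area_um2 <= config.cluster_factor * mean_single_area:
            out.append(ObjectClassification(obj.object_id, "single", 1))
        else:
            k = max(2, round_half_up(obj.area_um2 / mean_single_area))
            out.append(ObjectClassification(obj.object_id, "cluster", k))
    return out


def count_segment(segment: MosaicImage, config: DetectorConfig | None = None) -> SegmentCount:
    """Run the full pipeline on one calibrated segment.

    A segment with no detectable objects (e.g. blank background under a
    manual threshold) yields a zero count, not an error; a constant image
    under automatic thresholding is an error, surfacing acquisition failures.
    """
    config = config or DetectorConfig()
    smoothed = preprocess(segment, config)
    threshold = compute_threshold(smoothed, config)
    mask = binarize(smoothed, threshold, fill_holes=config.fill_holes)
    objects = label_objects(mask, config, segment.pixel_size)
    above = [o for o in objects if o.area_um2 > config.min_object_area]
    if not above:
        pairs = tuple(
            (o, ObjectClassification(o.object_id, "noise", 0)) for o in objects
        )
        return SegmentCount(
            objects=pairs,
            mean_single_area=float("nan"),
            n_singles=0,
            n_cluster_objects=0,
            n_noise=len(objects),
            n_total_cells=0,
            threshold_used=threshold,
        )
    mean_area = estimate_mean_single_area(objects, config)
    classes = classify_objects(objects, mean_area, config)
    pairs = tuple(zip(objects, classes))
    n_singles = sum(1 for c in classes if c.label == "single")
    n_clusters = sum(1 for c in classes if c.label == "cluster")
    n_noise = sum(1 for c in classes if c.label == "noise")
    total = sum(c.estimated_cells for c in classes)
    return SegmentCount(
        objects=pairs,
        mean_single_area=mean_area,
        n_singles=n_singles,
        n_cluster_objects=n_clusters,
        n_noise=n_noise,
        n_total_cells=total,
        threshold_used=threshold,
    )


def objects_to_rows(result: SegmentCount) -> list[dict]:
    """Per-object rows (id, area, label, estimated cells, centroid) for CSV."""
    return [
        {
            "object_id": obj.object_id,
            "area_um2": obj.area_um2,
            "area_px": obj.area_px,
            "label": cls.label,
            "estimated_cells": cls.estimated_cells,
            "centroid_x": obj.centroid[0],
            "centroid_y": obj.centroid[1],
        }
        for obj, cls in result.objects
    ]


def render_overlay(segment: MosaicImage, result: SegmentCount) -> np.ndarray:
    """Annotated RGB image: red outlines + '+' on singles, blue dots on
    clusters, green dots on size-excluded noise."""
    px = segment.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    base = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    rgb = np.stack([base] * 3, axis=-1)
    h, w = px.shape
    red, green, blue = (1.0, 0.15, 0.15), (0.15, 1.0, 0.15), (0.3, 0.4, 1.0)

    def paint(ys, xs, color):
        ys = np.clip(np.asarray(ys, int), 0, h - 1)
        xs = np.clip(np.asarray(xs, int), 0, w - 1)
        for c in range(3):
            rgb[ys, xs, c] = color[c]

    for obj, cls in result.objects:
        cxp, cyp = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
        if cls.label == "noise":
            paint([cyp], [cxp], green)
            continue
        paint(obj.boundary[:, 1], obj.boundary[:, 0], red)
        if cls.label == "single":
            arm = 3
            paint(np.full(2 * arm + 1, cyp), np.arange(cxp - arm, cxp + arm + 1), red)
            paint(np.arange(cyp - arm, cyp + arm + 1), np.full(2 * arm + 1, cxp), red)
        else:
            yy, xx = np.mgrid[-1:2, -1:2]
            paint(cyp + yy.ravel(), cxp + xx.ravel(), blue)
    return (rgb * 255).astype(np.uint8)
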