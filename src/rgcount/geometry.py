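"""Quadrant × eccentricity sampling geometry over a flat-mounted retina.

A flat mount is relieved by four radial cuts, giving four lobes (quadrants).
Counting samples one square segment per quadrant in each of three
eccentricity bands (central / middle / peripheral, measured from the
user-marked optic nerve head), for 12 segments per retina. Segment centers
sit on each quadrant's bisector at a configurable fraction of the outer
radius; segments are axis-aligned squares cropped verbatim (no resampling).

Coordinates are (x, y) = (column, row) pixels; angles are radians in the
image plane (y increasing downwards).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ECCENTRICITIES, MosaicImage

DEFAULT_SIDE_UM = 350.0
DEFAULT_BAND_FRACTIONS = (0.25, 0.55, 0.85)


@dataclass(frozen=True)
class RetinaLayout:
    """Sampling frame for one flat mount.

    ``center`` is the optic-nerve-head position in pixels, ``quadrant_axes``
    the two cut directions (radians) whose lines through the center split the
    mount into four sectors, and ``outer_radius`` the center-to-edge distance
    in μm.
    """

    center: tuple[float, float]
    quadrant_axes: tuple[float, float]
    outer_radius: float
    pixel_size: float
    image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        if not self.outer_radius > 0:
            raise ValueError(f"outer_radius must be positive, got {self.outer_radius}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        a, b = self.quadrant_axes
        if abs(math.sin(a - b)) < 1e-9:
            raise ValueError("quadrant axes must not be parallel")
        h, w = self.image_shape
        x, y = self.center
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"center {self.center} lies outside the {h}x{w} image")

    def sector_boundaries(self) -> list[float]:
        """The four boundary angles in [0, 2π), sorted."""
        a, b = self.quadrant_axes
        angles = [a % (2 * math.pi), b % (2 * math.pi), (a + math.pi) % (2 * math.pi), (b + math.pi) % (2 * math.pi)]
        return sorted(angles)

    def quadrant_bisectors(self) -> list[float]:
        """Bisector angle of each of the four sectors, one per quadrant.

        Quadrants are numbered 1–4 in increasing bisector angle.
        """
        bounds = self.sector_boundaries()
        bis = []
        for i in range(4):
            lo = bounds[i]
            hi = bounds[(i + 1) % 4] + (2 * math.pi if i == 3 else 0)
            bis.append(((lo + hi) / 2) % (2 * math.pi))
        return bis


@dataclass(frozen=True)
class SegmentROI:
    """One axis-aligned square sampling window."""

    quadrant: int
    eccentricity: str
    origin: tuple[int, int]  # top-left (x, y) in pixels
    side_um: float
    side_px: int

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be 1..4")
        if self.eccentricity not in ECCENTRICITIES:
            raise ValueError(f"unknown eccentricity {self.eccentricity!r}")
        if not self.side_um > 0 or self.side_px < 1:
            raise ValueError("segment side must be positive")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) with exclusive upper corners."""
        x0, y0 = self.origin
        return x0, y0, x0 + self.side_px, y0 + self.side_px


def build_layout(
    image: MosaicImage,
    center: tuple[float, float],
    outer_radius: float,
    quadrant_axes: tuple[float, float] = (0.0, math.pi / 2),
) -> RetinaLayout:
    """Anchor the sampling frame on an image.

    The center and cut axes come from the user (semi-automated workflow);
    nothing is detected automatically.
    """
    return RetinaLayout(
        center=(float(center[0]), float(center[1])),
        quadrant_axes=(float(quadrant_axes[0]), float(quadrant_axes[1])),
        outer_radius=float(outer_radius),
        pixel_size=image.pixel_size,
        image_shape=image.shape,
    )


def sample_regions(
    layout: RetinaLayout,
    side_um: float = DEFAULT_SIDE_UM,
    band_fractions: Sequence[float] = DEFAULT_BAND_FRACTIONS,
) -> list[SegmentROI]:
    """Place the 12 segments: 4 quadrants × {central, middle, peripheral}.

    Each segment is centered on its quadrant's bisector at
    ``fraction × outer_radius`` from the optic nerve head. Raises if any
    segment would leave the image or if segments overlap.
    """
    fr = tuple(float(f) for f in band_fractions)
    if len(fr) != 3 or not all(0 < f <= 1 for f in fr) or not (fr[0] < fr[1] < fr[2]):
        raise ValueError(f"band_fractions must be three strictly increasing values in (0, 1], got {fr}")
    if not side_um > 0:
        raise ValueError("side_um must be positive")
    side_px = int(round(side_um / layout.pixel_size))
    if side_px < 1:
        raise ValueError("segment smaller than one pixel")
    h, w = layout.image_shape
    cx, cy = layout.center
    rois: list[SegmentROI] = []
    for q, phi in enumerate(layout.quadrant_bisectors(), start=1):
        for ecc, f in zip(ECCENTRICITIES, fr):
            r_px = f * layout.outer_radius / layout.pixel_size
            mx = cx + r_px * math.cos(phi)
            my = cy + r_px * math.sin(phi)
            x0 = int(round(mx - side_px / 2))
            y0 = int(round(my - side_px / 2))
            if x0 < 0 or y0 < 0 or x0 + side_px > w or y0 + side_px > h:
                raise ValueError(
                    f"segment (quadrant {q}, {ecc}) at ({x0}, {y0}) falls outside the "
                    f"{h}x{w} image; shrink side_um or band fractions"
                )
            rois.append(SegmentROI(q, ecc, (x0, y0), float(side_um), side_px))
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            if _overlaps(rois[i], rois[j]):
                raise ValueError(
                    f"segments {rois[i].quadrant}/{rois[i].eccentricity} and "
                    f"{rois[j].quadrant}/{rois[j].eccentricity} overlap; "
                    "layout too small for the requested segment size"
                )
    return rois


def _overlaps(a: SegmentROI, b: SegmentROI) -> bool:
    ax0, ay0, ax1, ay1 = a.bounds
    bx0, by0, bx1, by1 = b.bounds
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def extract_segment(image: MosaicImage, roi: SegmentROI) -> MosaicImage:
    """Crop one segment verbatim; calibration is inherited."""
    x0, y0, x1, y1 = roi.bounds
    h, w = image.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"ROI {roi.bounds} exceeds image bounds {h}x{w}")
    return MosaicImage(image.pixels[y0:y1, x0:x1].copy(), image.pixel_size, image.bit_depth)


def rois_to_frame(rois: Sequence[SegmentROI]) -> pd.DataFrame:
    """Tabulate ROIs (pixel coordinates) for export."""
    return pd.DataFrame(
        [
            {
                "quadrant": r.quadrant,
                "eccentricity": r.eccentricity,
                "x0": r.origin[0],
                "y0": r.origin[1],
                "side_px": r.side_px,
                "side_um": r.side_um,
            }
            for r in rois
        ]
    )
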