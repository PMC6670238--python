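"""Calibrated image and table I/O.

Images are single-channel fluorescence TIFFs — either a 2-D mosaic of a
flat-mounted retina or a multi-page z-stack to be projected before counting.
Pixel size (μm/px) is supplied by the caller rather than parsed from TIFF
metadata, because calibration tags are not consistent across microscopes.

Tabular data (per-segment counts, per-animal records, synthetic ground
truth) travel as UTF-8 CSV with fixed headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

GROUPS = ("EAE", "CFA", "naive")
ECCENTRICITIES = ("central", "middle", "peripheral")
EYES = ("left", "right")
QUADRANTS = (1, 2, 3, 4)

COUNT_COLUMNS = [
    "animal_id",
    "eye",
    "group",
    "timepoint",
    "quadrant",
    "eccentricity",
    "count",
    "density",
]

ANIMAL_COLUMNS = ["animal_id", "group", "peak_behavior_score", "sex"]


@dataclass(frozen=True)
class MosaicImage:
    """A calibrated 2-D single-channel intensity image.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities (arbitrary units).
    pixel_size : float
        Isotropic calibration in μm per pixel; must be positive.
    bit_depth : int, optional
        Acquisition bit depth, informational only.
    """

    pixels: np.ndarray
    pixel_size: float
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if px.size and float(px.min()) < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "MosaicImage":
        return MosaicImage(pixels, self.pixel_size, self.bit_depth)


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of equally shaped focal planes."""

    planes: np.ndarray  # (n_planes, h, w)
    pixel_size: float
    z_step: float = 3.0  # μm between planes
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        pl = np.asarray(self.planes)
        if pl.ndim != 3 or pl.shape[0] < 1:
            raise ValueError(f"planes must be a (n, h, w) array with n >= 1, got {pl.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.z_step > 0:
            raise ValueError("z_step must be positive")
        object.__setattr__(self, "planes", pl)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]


def read_image(
    path: str | Path, pixel_size: float, z_step: float = 3.0
) -> MosaicImage | ZStack:
    """Read a single-channel TIFF as a :class:`MosaicImage` or :class:`ZStack`.

    A single-page TIFF yields a ``MosaicImage``; a multi-page TIFF yields a
    ``ZStack`` (project with :func:`project_stack` before counting). RGB or
    multi-channel files are rejected because the counting signal would be
    ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    arr = tifffile.imread(path)
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else None
    if arr.ndim == 2:
        return MosaicImage(arr, pixel_size, bit_depth)
    if arr.ndim == 3:
        # Pages stack along the first axis; a trailing size-3/4 axis is a
        # color image, which we refuse.
        if arr.shape[-1] in (3, 4) and arr.shape[-1] != arr.shape[0]:
            raise ValueError(
                f"{path.name}: multi-channel image (shape {arr.shape}); "
                "counting requires a single channel"
            )
        return ZStack(arr, pixel_size, z_step=z_step, bit_depth=bit_depth)
    raise ValueError(f"{path.name}: unsupported TIFF dimensionality {arr.ndim}")


def write_image(path: str | Path, image: MosaicImage) -> None:
    tifffile.imwrite(Path(path), image.pixels)


def project_stack(stack: ZStack, method: str = "max") -> MosaicImage:
    """Collapse a z-stack to a single plane.

    Maximum-intensity projection is the default: bright somata remain bright
    regardless of which focal plane they sit in. A mean projection is
    available for sensitivity checks.
    """
    if method == "max":
        pixels = stack.planes.max(axis=0)
    elif method == "mean":
        pixels = stack.planes.mean(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r} (use 'max' or 'mean')")
    return MosaicImage(pixels, stack.pixel_size, stack.bit_depth)


@dataclass
class CountTable:
    """Per-segment counts and densities, one row per sampled segment."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COUNT_COLUMNS))

    def __post_init__(self) -> None:
        self.frame = validate_count_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


def validate_count_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    frame = frame[COUNT_COLUMNS]
    if len(frame) == 0:
        return frame.astype(
            {
                "animal_id": str,
                "eye": str,
                "group": str,
                "timepoint": "int64",
                "quadrant": "int64",
                "eccentricity": str,
                "count": "int64",
                "density": float,
            }
        )
    frame["animal_id"] = frame["animal_id"].astype(str)
    bad = set(frame["eye"]) - set(EYES)
    if bad:
        raise ValueError(f"unknown eye labels: {sorted(bad)}")
    bad = set(frame["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)} (expected {GROUPS})")
    bad = set(frame["eccentricity"]) - set(ECCENTRICITIES)
    if bad:
        raise ValueError(f"unknown eccentricity labels: {sorted(bad)} (expected {ECCENTRICITIES})")
    frame["timepoint"] = frame["timepoint"].astype("int64")
    frame["quadrant"] = frame["quadrant"].astype("int64")
    if not frame["quadrant"].isin(QUADRANTS).all():
        raise ValueError("quadrant must be in 1..4")
    frame["count"] = frame["count"].astype("int64")
    if (frame["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    frame["density"] = frame["density"].astype(float)
    if (frame["density"] < 0).any():
        raise ValueError("densities must be non-negative")
    keys = frame[["animal_id", "eye", "timepoint", "quadrant", "eccentricity"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate segment key {dup}")
    return frame.reset_index(drop=True)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.frame.to_csv(Path(path), index=False)


def read_count_table(path: str | Path) -> CountTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"animal_id": str})
    return CountTable(frame)


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal metadata: group, peak EAE behavior score (0–5, half steps)."""

    animal_id: str
    group: str
    peak_behavior_score: float
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} (expected one of {GROUPS})")
        s = float(self.peak_behavior_score)
        if not (0.0 <= s <= 5.0):
            raise ValueError(f"behavior score must lie in [0, 5], got {s}")


def write_animal_table(records: Sequence[AnimalRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "group": r.group,
            "peak_behavior_score": r.peak_behavior_score,
            "sex": r.sex if r.sex is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANIMAL_COLUMNS).to_csv(Path(path), index=False)


def read_animal_table(path: str | Path) -> list[AnimalRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in ANIMAL_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"animal table missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        sex = row.get("sex")
        sex = None if (sex is None or (isinstance(sex, float) and np.isnan(sex)) or sex == "") else str(sex)
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                peak_behavior_score=float(row["peak_behavior_score"]),
                sex=sex,
            )
        )
    return records
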