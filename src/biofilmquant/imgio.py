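"""Raster types and file I/O.

Images are 8-bit grayscale micrographs carrying a physical pixel size
(default 250 nm, the scale at which individual cocci span a few pixels).
Masks are binary biofilm/surface labelings with the fixed convention
1 = biofilm (rendered white on disk), 0 = surface (black).

Coordinates are 0-based with origin at the top-left; ``x`` indexes
columns and ``y`` rows, and ROI squares are half-open pixel ranges
``[x, x+size) x [y, y+size)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_NM = 250.0
MIN_IMAGE_DIM = 32

__all__ = [
    "GrayImage",
    "BinaryMask",
    "RoiSample",
    "TrainingSet",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "read_roi_set",
    "write_roi_set",
    "DEFAULT_PIXEL_SIZE_NM",
]


@dataclass
class GrayImage:
    """A 2-D 8-bit grayscale micrograph with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"GrayImage stores uint8 pixels, got {px.dtype}")
        h, w = px.shape
        if h < MIN_IMAGE_DIM or w < MIN_IMAGE_DIM:
            raise ValueError(f"image must be at least {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}, got {w}x{h}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        """Normalized float32 view in [0, 1]."""
        return self.pixels.astype(np.float32) / 255.0

    @classmethod
    def from_float(cls, arr: np.ndarray, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> "GrayImage":
        """Quantize a normalized [0, 1] array to 8 bits (round half to even)."""
        px = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
        return cls(px, pixel_size_nm)

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.pixel_size_nm)


@dataclass
class BinaryMask:
    """Per-pixel biofilm (1) / surface (0) labeling of a micrograph."""

    pixels: np.ndarray
    positive_class: str = "biofilm"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {px.shape}")
        if px.dtype == bool:
            px = px.astype(np.uint8)
        vals = np.unique(px)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        """Number of biofilm (value 1) pixels."""
        return int(self.pixels.sum())

    @property
    def coverage(self) -> float:
        return self.area_px / self.pixels.size

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.pixels.copy(), self.positive_class)


LABELS = ("surface", "biofilm")
ROI_SIZE_DEFAULT = 12


@dataclass(frozen=True)
class RoiSample:
    """A labelled square training region; ``(x, y)`` is the top-left pixel."""

    x: int
    y: int
    label: str
    size: int = ROI_SIZE_DEFAULT

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI coordinates must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.size), slice(self.x, self.x + self.size)

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.x + self.size <= w and self.y + self.size <= h


@dataclass
class TrainingSet:
    """A collection of labelled ROI samples covering both classes."""

    samples: list[RoiSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = self.class_counts()
        for lab in LABELS:
            if counts.get(lab, 0) < 1:
                raise ValueError(f"both classes required; no {lab!r} samples present")
        self._check_cross_class_overlap()

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def _check_cross_class_overlap(self) -> None:
        # Same-class overlap is tolerated (duplicated pixels, logged);
        # conflicting labels on one pixel are rejected.
        for i, a in enumerate(self.samples):
            for b in self.samples[i + 1:]:
                overlap = (a.x < b.x + b.size and b.x < a.x + a.size
                           and a.y < b.y + b.size and b.y < a.y + a.size)
                if overlap:
                    if a.label != b.label:
                        raise ValueError(
                            f"ROIs of different labels overlap: {a} and {b}")
                    logger.debug("same-class ROIs overlap (%s); duplicated pixels kept", a.label)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        for s in self.samples:
            if not s.in_bounds(shape):
                raise ValueError(f"ROI {s} exceeds image bounds {shape[1]}x{shape[0]}")

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> GrayImage:
    """Read an 8-bit grayscale TIFF/PNG micrograph.

    RGB images whose channels are identical are collapsed to one channel;
    genuinely colored input is rejected.  16-bit input is min-max rescaled
    to 8 bits with a warning, since SEM exports vary in bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3 or not (np.array_equal(arr[:, :, 0], arr[:, :, 1])
                                     and np.array_equal(arr[:, :, 0], arr[:, :, 2])):
            raise ValueError(f"{path.name}: not grayscale (unequal color channels)")
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        pass
    elif arr.dtype == np.uint16:
        warnings.warn(f"{path.name}: 16-bit input rescaled to 8-bit (min-max)", stacklevel=2)
        lo, hi = int(arr.min()), int(arr.max())
        if hi == lo:
            arr = np.zeros_like(arr, dtype=np.uint8)
        else:
            arr = np.rint((arr.astype(np.float64) - lo) / (hi - lo) * 255.0).astype(np.uint8)
    else:
        raise ValueError(f"{path.name}: unsupported bit depth {arr.dtype}; expected 8 or 16 bit")
    return GrayImage(arr, pixel_size_nm)


def _write_u8(arr: np.ndarray, path: Path) -> None:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format {suffix!r}; use .tif/.tiff/.png")


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale TIFF or PNG."""
    _write_u8(img.pixels, Path(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit raster with biofilm=255, surface=0."""
    _write_u8(mask.pixels * np.uint8(255), Path(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask raster; any non-zero pixel counts as biofilm."""
    img = read_image(path)
    return BinaryMask((img.pixels > 127).astype(np.uint8))


def read_roi_set(path: str | Path, image_shape: tuple[int, int] | None = None) -> TrainingSet:
    """Read a JSON ROI list ``[{"x":..,"y":..,"size":12,"label":"biofilm"},..]``."""
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError("ROI file must contain a JSON list of records")
    samples = [RoiSample(x=int(r["x"]), y=int(r["y"]),
                         size=int(r.get("size", ROI_SIZE_DEFAULT)),
                         label=str(r["label"])) for r in records]
    ts = TrainingSet(samples)
    if image_shape is not None:
        ts.validate_bounds(image_shape)
    return ts


def write_roi_set(ts: TrainingSet, path: str | Path) -> None:
    records = [{"x": s.x, "y": s.y, "size": s.size, "label": s.label} for s in ts.samples]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")
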