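"""Surface-specific image conditioning.

Two presets mirror the conditioning applied before pixel classification:

* ``sla`` (rough, pitted surfaces): sliding-paraboloid background
  subtraction (radius 1000 px) to level the uneven illumination caused by
  the etched texture, 1% saturated contrast stretch, bright-outlier
  removal (threshold 50, radius 2), gamma 0.6, then a 3x3 sharpen.
* ``polished``: 0.4% saturated contrast stretch and outlier removal with
  threshold 0 / radius 2, which replaces every pixel brighter than its
  local median and thereby smooths scratch artifacts that would otherwise
  be mistaken for bacteria.

All filters operate in the 8-bit intensity domain (0-255), preserve image
dimensions and keep outputs in range.  Neighborhood filters use reflected
borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from ._util import paraboloid_opening
from .imgio import GrayImage

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "contrast_bounds",
    "enhance_contrast",
    "remove_outliers",
    "gamma_adjust",
    "sharpen",
    "apply_preset",
    "apply_preset_pair",
]


@dataclass(frozen=True)
class PreprocessConfig:
    surface_type: str = "sla"
    rolling_ball_radius: float = 1000.0
    use_paraboloid: bool = True
    contrast_saturated_pct: float = 1.0
    outlier_threshold: float = 50.0
    outlier_radius: int = 2
    gamma: float = 0.6
    do_sharpen: bool = True

    def __post_init__(self) -> None:
        if self.rolling_ball_radius <= 0:
            raise ValueError("rolling_ball_radius must be > 0")
        if not (0.0 <= self.contrast_saturated_pct < 50.0):
            raise ValueError("contrast_saturated_pct must be in [0, 50)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.outlier_radius < 1:
            raise ValueError("outlier_radius must be >= 1")
        if self.surface_type not in ("sla", "polished"):
            raise ValueError("surface_type must be 'sla' or 'polished'")

    @classmethod
    def for_surface(cls, surface_type: str) -> "PreprocessConfig":
        if surface_type == "sla":
            return cls(surface_type="sla", contrast_saturated_pct=1.0,
                       outlier_threshold=50.0, gamma=0.6, do_sharpen=True)
        if surface_type == "polished":
            return cls(surface_type="polished", contrast_saturated_pct=0.4,
                       outlier_threshold=0.0, gamma=1.0, do_sharpen=False)
        raise ValueError(f"unknown surface type {surface_type!r}")


def subtract_background(img: GrayImage, radius: float = 1000.0,
                        paraboloid: bool = True) -> GrayImage:
    """Subtract the slowly varying background (uneven illumination).

    The background is the lower envelope traced by sliding a paraboloid of
    curvature ``1/(2*radius)`` (intensity levels per px^2) under the
    intensity surface; the flat-ball variant uses a grayscale opening with
    a flat disc.  The envelope never exceeds the image, so the output mean
    never exceeds the input mean.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    f = img.pixels.astype(np.float64)
    if paraboloid:
        bg = paraboloid_opening(f, curvature=1.0 / (2.0 * radius))
    else:
        r = int(min(radius, max(img.shape)))
        bg = ndi.grey_opening(f, footprint=disk(r), mode="reflect")
    out = np.clip(f - bg, 0.0, 255.0)
    return GrayImage(np.rint(out).astype(np.uint8), img.pixel_size_nm)


def contrast_bounds(img: GrayImage, saturated_pct: float) -> tuple[float, float]:
    """The (vmin, vmax) cutoffs of the saturated linear stretch."""
    if not (0.0 <= saturated_pct < 50.0):
        raise ValueError("saturated_pct must be in [0, 50)")
    v = np.sort(img.pixels, axis=None).astype(np.float64)
    k = int(v.size * saturated_pct / 200.0)
    return float(v[k]), float(v[v.size - 1 - k])


def enhance_contrast(img: GrayImage, saturated_pct: float,
                     bounds: tuple[float, float] | None = None) -> GrayImage:
    """Linear stretch saturating ``saturated_pct`` of pixels (split equally
    between the low and high ends); a constant image is returned unchanged.

    ``bounds`` overrides the cutoffs, allowing one image's stretch (e.g.
    the before frame of a registered pair) to be replayed on another so
    both frames share a single intensity mapping.
    """
    vmin, vmax = bounds if bounds is not None else contrast_bounds(img, saturated_pct)
    if vmax <= vmin:
        logger.info("enhance_contrast: constant image, no-op")
        return img.copy()
    f = img.pixels.astype(np.float64)
    out = np.clip((f - vmin) / (vmax - vmin) * 255.0, 0.0, 255.0)
    return GrayImage(np.rint(out).astype(np.uint8), img.pixel_size_nm)


def remove_outliers(img: GrayImage, threshold: float, radius: int = 2) -> GrayImage:
    """Replace bright outliers by their local median.

    A pixel is replaced by the median over the disc of the given radius
    (center included) iff it exceeds that median by strictly more than
    ``threshold``; threshold 0 therefore replaces every pixel brighter
    than its local median.  Never increases any pixel.
    """
    if threshold < 0 or radius < 1:
        raise ValueError("threshold must be >= 0 and radius >= 1")
    px = img.pixels
    med = ndi.median_filter(px, footprint=disk(radius), mode="reflect")
    replace = px.astype(np.int64) - med.astype(np.int64) > threshold
    out = np.where(replace, med, px).astype(np.uint8)
    return GrayImage(out, img.pixel_size_nm)


def gamma_adjust(img: GrayImage, gamma: float) -> GrayImage:
    """Power-law intensity mapping on normalized [0, 1] values; monotone
    and endpoint-preserving for any gamma > 0."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    out = np.power(img.as_float().astype(np.float64), gamma)
    return GrayImage.from_float(out, img.pixel_size_nm)


_SHARPEN_KERNEL = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]], dtype=np.float64) / 4.0


def sharpen(img: GrayImage) -> GrayImage:
    """3x3 unsharp kernel (-1 everywhere, +12 center, /4), reflected
    borders, clipped to range.  The kernel sums to 1, so flat regions are
    unchanged."""
    f = img.pixels.astype(np.float64)
    out = ndi.convolve(f, _SHARPEN_KERNEL, mode="reflect")
    return GrayImage(np.rint(np.clip(out, 0.0, 255.0)).astype(np.uint8), img.pixel_size_nm)


def apply_preset(img: GrayImage, cfg: PreprocessConfig,
                 shared_contrast_bounds: tuple[float, float] | None = None) -> GrayImage:
    """Apply the surface-specific filter chain in its fixed order."""
    out = img
    if cfg.surface_type == "sla":
        out = subtract_background(out, cfg.rolling_ball_radius, cfg.use_paraboloid)
        logger.debug("sla preset: background subtracted")
        out = enhance_contrast(out, cfg.contrast_saturated_pct, shared_contrast_bounds)
        out = remove_outliers(out, cfg.outlier_threshold, cfg.outlier_radius)
        out = gamma_adjust(out, cfg.gamma)
        if cfg.do_sharpen:
            out = sharpen(out)
    else:
        out = enhance_contrast(out, cfg.contrast_saturated_pct, shared_contrast_bounds)
        out = remove_outliers(out, cfg.outlier_threshold, cfg.outlier_radius)
    return out


def apply_preset_pair(before: GrayImage, after: GrayImage,
                      cfg: PreprocessConfig) -> tuple[GrayImage, GrayImage]:
    """Preprocess a registered pair with one shared intensity mapping.

    The contrast-stretch cutoffs are computed once, on the before frame
    (after its background subtraction for the SLA preset), and replayed on
    the after frame.  Stretching each frame independently would let the
    frame with less biofilm expand its narrower histogram differently,
    so a classifier trained on one frame would not transfer to the other.
    """
    ref = before
    if cfg.surface_type == "sla":
        ref = subtract_background(before, cfg.rolling_ball_radius, cfg.use_paraboloid)
    bounds = contrast_bounds(ref, cfg.contrast_saturated_pct)
    return (apply_preset(before, cfg, shared_contrast_bounds=bounds),
            apply_preset(after, cfg, shared_contrast_bounds=bounds))
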