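"""Rigid before/after registration from matched local features.

Before/after micrographs of the same field are related by a small rigid
motion (stage relocation error).  Scale-space keypoints with local
gradient-orientation descriptors are matched between the frames, a
rotation+translation model is estimated by random-sample consensus over
minimal two-match models (inlier residual bound 8 px by default, the
"geometric consensus filter"), and the consensus inlier set is refit by
least squares.  The after frame is then resampled into the before frame
and both images are cropped to the maximal rectangle free of blank
(out-of-frame) pixels, so downstream pixelwise comparison sees identical
dimensions and no resampling artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac

from ._util import largest_true_rectangle
from .imgio import GrayImage

MAX_ALIGNMENT_ERROR = 8.0
MIN_OVERLAP = 32

__all__ = ["RegistrationError", "RigidTransform", "FeatureMatchSet",
           "detect_and_match", "estimate_rigid", "apply_and_crop", "register_pair",
           "MAX_ALIGNMENT_ERROR"]


class RegistrationError(RuntimeError):
    """Raised when a pair cannot be brought into alignment."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``theta`` about the image center plus translation.

    Maps after-frame coordinates (x, y) = (col, row) into the before
    frame: ``p' = R(theta) (p - c) + c + (tx, ty)`` with
    ``c = ((w-1)/2, (h-1)/2)``.  The linear part is orthonormal with
    determinant +1 by construction (no scale or shear).
    """

    theta: float
    tx: float
    ty: float
    center: tuple[float, float]  # (cx, cy)

    def to_skimage(self) -> sktransform.EuclideanTransform:
        c = np.asarray(self.center)
        return (sktransform.EuclideanTransform(translation=-c)
                + sktransform.EuclideanTransform(rotation=self.theta)
                + sktransform.EuclideanTransform(translation=c + np.array([self.tx, self.ty])))

    @classmethod
    def from_skimage(cls, t: sktransform.EuclideanTransform,
                     shape: tuple[int, int]) -> "RigidTransform":
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        theta = math.atan2(t.params[1, 0], t.params[0, 0])
        # translation about the center: t_c = (R - I) c + t
        R = t.params[:2, :2]
        tc = (R - np.eye(2)) @ np.array([cx, cy]) + t.params[:2, 2]
        return cls(theta=theta, tx=float(tc[0]), ty=float(tc[1]), center=(cx, cy))

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "RigidTransform":
        h, w = shape
        return cls(0.0, 0.0, 0.0, ((w - 1) / 2.0, (h - 1) / 2.0))


@dataclass
class FeatureMatchSet:
    """Matched keypoints between a before ("a") and after ("b") frame.

    Keypoints are (row, col) arrays; ``matches`` holds (index_a, index_b)
    pairs with descriptor distances.  ``inlier_flags`` is populated by the
    consensus fit: inliers have residual <= the alignment-error bound.
    """

    keypoints_a: np.ndarray = field(repr=False)
    keypoints_b: np.ndarray = field(repr=False)
    matches: np.ndarray = field(repr=False)
    distances: np.ndarray = field(repr=False)
    shape_a: tuple[int, int] = (0, 0)
    inlier_flags: np.ndarray | None = field(repr=False, default=None)

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    def matched_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) coordinate arrays in (x, y) order: src = after frame,
        dst = before frame."""
        kp_a = self.keypoints_a[self.matches[:, 0]][:, ::-1]
        kp_b = self.keypoints_b[self.matches[:, 1]][:, ::-1]
        return kp_b.astype(np.float64), kp_a.astype(np.float64)


def detect_and_match(img_a: GrayImage, img_b: GrayImage,
                     max_ratio: float = 0.8) -> FeatureMatchSet:
    """Detect scale-space keypoints in both frames and match descriptors
    (nearest neighbor with ratio test and cross-check)."""
    kp, desc = [], []
    for img in (img_a, img_b):
        sift = SIFT()
        try:
            sift.detect_and_extract(img.as_float())
        except RuntimeError as exc:
            raise RegistrationError(f"no detectable features: {exc}") from exc
        if len(sift.keypoints) == 0:
            raise RegistrationError("no detectable features in one frame")
        kp.append(sift.keypoints)
        desc.append(sift.descriptors)
    matches = match_descriptors(desc[0], desc[1], cross_check=True, max_ratio=max_ratio)
    if len(matches) < 3:
        raise RegistrationError(f"only {len(matches)} putative matches (need >= 3)")
    d = np.linalg.norm(desc[0][matches[:, 0]].astype(np.float64)
                       - desc[1][matches[:, 1]].astype(np.float64), axis=1)
    return FeatureMatchSet(keypoints_a=kp[0], keypoints_b=kp[1], matches=matches,
                           distances=d, shape_a=img_a.shape)


def estimate_rigid(ms: FeatureMatchSet,
                   max_alignment_error: float = MAX_ALIGNMENT_ERROR,
                   seed: int = 0, n_trials: int = 1000) -> RigidTransform:
    """Consensus rigid fit: random minimal 2-match samples, inliers within
    ``max_alignment_error`` px, least-squares refit on the largest inlier set."""
    if ms.n_matches < 3:
        raise RegistrationError("need at least 3 putative matches")
    src, dst = ms.matched_xy()
    model, inliers = ransac((src, dst), sktransform.EuclideanTransform,
                            min_samples=2, residual_threshold=max_alignment_error,
                            max_trials=n_trials, rng=int(seed))
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationError("geometric consensus failed (< 3 inliers)")
    refit = sktransform.EuclideanTransform.from_estimate(src[inliers], dst[inliers])
    if not refit:
        raise RegistrationError("least-squares refit failed")
    residuals = np.linalg.norm(refit(src) - dst, axis=1)
    ms.inlier_flags = residuals <= max_alignment_error
    if ms.inlier_flags.sum() < 3:
        raise RegistrationError("refit left < 3 inliers")
    return RigidTransform.from_skimage(refit, ms.shape_a)


def apply_and_crop(img_a: GrayImage, img_b: GrayImage,
                   t: RigidTransform) -> tuple[GrayImage, GrayImage, tuple[int, int, int, int]]:
    """Resample the after frame into the before frame and crop away blank
    pixels.

    Returns ``(before_crop, after_crop, rect)`` where ``rect`` is the
    half-open (r0, c0, r1, c1) crop window (the maximal axis-aligned
    rectangle containing no out-of-frame pixels) applied to both frames.
    The identity transform leaves the pair untouched.
    """
    if t.theta == 0.0 and t.tx == 0.0 and t.ty == 0.0:
        return img_a.copy(), img_b.copy(), (0, 0, *img_a.shape)
    # t maps after -> before; warp wants the output->input (before -> after)
    # coordinate map, i.e. the inverse
    inv = t.to_skimage().inverse
    warped = sktransform.warp(img_b.as_float().astype(np.float64), inv,
                              output_shape=img_a.shape, order=1, cval=0.0)
    validity = sktransform.warp(np.ones(img_b.shape, dtype=np.float64), inv,
                                output_shape=img_a.shape, order=1, cval=0.0)
    valid = validity > 1.0 - 1e-6
    r0, c0, r1, c1 = largest_true_rectangle(valid)
    if (r1 - r0) < MIN_OVERLAP or (c1 - c0) < MIN_OVERLAP:
        raise RegistrationError("insufficient overlap after registration")
    a_crop = GrayImage(img_a.pixels[r0:r1, c0:c1].copy(), img_a.pixel_size_nm)
    b_crop = GrayImage.from_float(warped[r0:r1, c0:c1], img_b.pixel_size_nm)
    return a_crop, b_crop, (r0, c0, r1, c1)


def register_pair(img_a: GrayImage, img_b: GrayImage,
                  max_alignment_error: float = MAX_ALIGNMENT_ERROR,
                  seed: int = 0) -> tuple[GrayImage, GrayImage, RigidTransform, tuple[int, int, int, int]]:
    """Full registration: detect/match features, fit the rigid model,
    resample and crop.  Returns (before_crop, after_crop, transform, rect)."""
    ms = detect_and_match(img_a, img_b)
    t = estimate_rigid(ms, max_alignment_error=max_alignment_error, seed=seed)
    a_crop, b_crop, rect = apply_and_crop(img_a, img_b, t)
    return a_crop, b_crop, t, rect
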