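"""Multi-scale feature stack for trainable pixel classification.

Each pixel is described by the responses of a bank of filters evaluated
at a geometric ladder of scales (sigma = powers of two from 1 to 16 by
default).  The default member set covers edge detectors (Sobel, Hessian,
difference of Gaussians), smoothers (Gaussian, neighborhood mean /
minimum / maximum / median, bilateral), a texture statistic (variance)
and membrane projections -- thin-line kernels at 30 orientations whose
pixelwise projections highlight elongated structures such as cell rims
and chain boundaries.  An extended set adds Laplacian, first-order
derivatives, structure-tensor eigenvalues, local entropy and shifted
"neighbour" planes for images that are hard to segment.

Plane order is a pure function of the configuration, so a classifier
trained on one stack can be applied to any stack built with the same
fingerprint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage.filters import rank as skrank
from skimage.morphology import disk

from .imgio import GrayImage

DEFAULT_MEMBERS = (
    "gaussian", "sobel", "hessian", "dog", "membrane",
    "variance", "mean", "minimum", "maximum", "median", "bilateral",
)
EXTENDED_MEMBERS = DEFAULT_MEMBERS + (
    "laplacian", "derivatives", "structure", "entropy", "neighbours",
)
_CANONICAL_ORDER = EXTENDED_MEMBERS

__all__ = ["FeatureConfig", "FeatureStack", "compute_feature_stack",
           "DEFAULT_MEMBERS", "EXTENDED_MEMBERS"]


def _sigma_ladder(sigma_min: float, sigma_max: float) -> tuple[float, ...]:
    """Powers of two from sigma_min to sigma_max inclusive."""
    sigmas = []
    s = float(sigma_min)
    while s <= sigma_max * (1 + 1e-9):
        sigmas.append(s)
        s *= 2.0
    return tuple(sigmas)


@dataclass(frozen=True)
class FeatureConfig:
    """Which filter-bank members to compute, and their scale parameters."""

    members: tuple[str, ...] = DEFAULT_MEMBERS
    sigma_min: float = 1.0
    sigma_max: float = 16.0
    membrane_thickness: int = 1
    membrane_patch_size: int = 19
    n_membrane_orientations: int = 30
    bilateral_spatial: tuple[int, ...] = (5, 10)
    bilateral_range: tuple[int, ...] = (50, 100)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("members must be non-empty")
        unknown = set(self.members) - set(_CANONICAL_ORDER)
        if unknown:
            raise ValueError(f"unknown feature members: {sorted(unknown)}")
        if self.sigma_min <= 0 or self.sigma_max < self.sigma_min:
            raise ValueError("require 0 < sigma_min <= sigma_max")

    @property
    def sigmas(self) -> tuple[float, ...]:
        return _sigma_ladder(self.sigma_min, self.sigma_max)

    @classmethod
    def default(cls) -> "FeatureConfig":
        return cls()

    @classmethod
    def extended(cls) -> "FeatureConfig":
        return cls(members=EXTENDED_MEMBERS)

    def fingerprint(self) -> str:
        payload = json.dumps({
            "members": sorted(self.members),
            "sigma_min": self.sigma_min, "sigma_max": self.sigma_max,
            "membrane_thickness": self.membrane_thickness,
            "membrane_patch_size": self.membrane_patch_size,
            "n_membrane_orientations": self.n_membrane_orientations,
            "bilateral_spatial": list(self.bilateral_spatial),
            "bilateral_range": list(self.bilateral_range),
        }, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureStack:
    """Ordered set of feature planes for one image: ``data[h, w, f]``."""

    data: np.ndarray = field(repr=False)
    names: list[str]
    fingerprint: str

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def flat(self) -> np.ndarray:
        """(n_pixels, n_features) float32 view for classification."""
        return self.data.reshape(-1, self.n_features)


# ---------------------------------------------------------------------------
# plane computations (all on normalized float32 in [0, 1]; rank filters run
# on the 8-bit image and are rescaled back)


def _reflect_fftconvolve(im: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflected borders via FFT."""
    pr, pc = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(im, ((pr, pr), (pc, pc)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[pr:pr + im.shape[0], pc:pc + im.shape[1]]


def _membrane_kernels(patch: int, thickness: int, n_orient: int) -> list[np.ndarray]:
    base = np.zeros((patch, patch), dtype=np.float64)
    c = patch // 2
    half = thickness // 2
    base[:, c - half:c - half + thickness] = 1.0
    kernels = []
    for i in range(n_orient):
        angle = 180.0 * i / n_orient
        k = ndi.rotate(base, angle, reshape=False, order=1)
        s = k.sum()
        kernels.append(k / s if s > 0 else k)
    return kernels


def _disc_mean(im: np.ndarray, radius: int) -> np.ndarray:
    d = disk(radius).astype(np.float64)
    return _reflect_fftconvolve(im, d / d.sum())


def compute_feature_stack(img: GrayImage, cfg: FeatureConfig) -> FeatureStack:
    """Compute the ordered feature stack of an image.

    The original (normalized) image is always the first plane.  Members are
    evaluated in a canonical order independent of how ``cfg.members`` is
    spelled, so equal configs always yield identical stacks.
    """
    im = img.as_float().astype(np.float64)
    u8 = img.pixels
    sigmas = cfg.sigmas
    int_sigmas = [max(1, int(round(s))) for s in sigmas]

    planes: list[np.ndarray] = [im]
    names: list[str] = ["original"]

    gaussians = {s: ndi.gaussian_filter(im, s) for s in sigmas}
    members = set(cfg.members)

    for member in _CANONICAL_ORDER:
        if member not in members:
            continue
        if member == "gaussian":
            for s in sigmas:
                planes.append(gaussians[s])
                names.append(f"gaussian_s{s:g}")
        elif member == "sobel":
            for s in sigmas:
                planes.append(skfilters.sobel(gaussians[s]))
                names.append(f"sobel_s{s:g}")
        elif member == "hessian":
            for s in sigmas:
                Hrr, Hrc, Hcc = skfeature.hessian_matrix(
                    im, sigma=s, mode="reflect", order="rc",
                    use_gaussian_derivatives=True)
                l1, l2 = skfeature.hessian_matrix_eigvals([Hrr, Hrc, Hcc])
                module = np.sqrt(Hrr**2 + 2.0 * Hrc**2 + Hcc**2)
                planes.extend([l1, l2, module])
                names.extend([f"hessian_eig1_s{s:g}", f"hessian_eig2_s{s:g}",
                              f"hessian_module_s{s:g}"])
        elif member == "dog":
            for i, si in enumerate(sigmas):
                for sj in sigmas[i + 1:]:
                    planes.append(gaussians[si] - gaussians[sj])
                    names.append(f"dog_s{si:g}_s{sj:g}")
        elif member == "membrane":
            kernels = _membrane_kernels(cfg.membrane_patch_size, cfg.membrane_thickness,
                                        cfg.n_membrane_orientations)
            resp = np.stack([_reflect_fftconvolve(im, k) for k in kernels], axis=0)
            for proj_name, proj in (("sum", resp.sum(0)), ("mean", resp.mean(0)),
                                    ("std", resp.std(0)), ("median", np.median(resp, 0)),
                                    ("max", resp.max(0)), ("min", resp.min(0))):
                planes.append(proj)
                names.append(f"membrane_{proj_name}")
        elif member == "variance":
            for r in int_sigmas:
                m1 = _disc_mean(im, r)
                m2 = _disc_mean(im * im, r)
                planes.append(np.clip(m2 - m1 * m1, 0.0, None))
                names.append(f"variance_r{r}")
        elif member == "mean":
            for r in int_sigmas:
                planes.append(_disc_mean(im, r))
                names.append(f"mean_r{r}")
        elif member == "minimum":
            for r in int_sigmas:
                planes.append(skrank.minimum(u8, disk(r)) / 255.0)
                names.append(f"minimum_r{r}")
        elif member == "maximum":
            for r in int_sigmas:
                planes.append(skrank.maximum(u8, disk(r)) / 255.0)
                names.append(f"maximum_r{r}")
        elif member == "median":
            for r in int_sigmas:
                planes.append(skrank.median(u8, disk(r)) / 255.0)
                names.append(f"median_r{r}")
        elif member == "bilateral":
            for rs in cfg.bilateral_spatial:
                for rr in cfg.bilateral_range:
                    planes.append(skrank.mean_bilateral(u8, disk(rs), s0=rr, s1=rr) / 255.0)
                    names.append(f"bilateral_sp{rs}_rg{rr}")
        elif member == "laplacian":
            for s in sigmas:
                planes.append(ndi.gaussian_laplace(im, s))
                names.append(f"laplacian_s{s:g}")
        elif member == "derivatives":
            for s in sigmas:
                planes.append(ndi.gaussian_filter(im, s, order=(0, 1)))
                names.append(f"deriv_x_s{s:g}")
                planes.append(ndi.gaussian_filter(im, s, order=(1, 0)))
                names.append(f"deriv_y_s{s:g}")
        elif member == "structure":
            for s in sigmas:
                Arr, Arc, Acc = skfeature.structure_tensor(im, sigma=s, mode="reflect", order="rc")
                e1, e2 = skfeature.structure_tensor_eigenvalues([Arr, Arc, Acc])
                planes.extend([e1, e2])
                names.extend([f"structure_eig1_s{s:g}", f"structure_eig2_s{s:g}"])
        elif member == "entropy":
            for r in int_sigmas:
                planes.append(skrank.entropy(u8, disk(r)) / 8.0)
                names.append(f"entropy_r{r}")
        elif member == "neighbours":
            for s in int_sigmas:
                for dy in (-s, 0, s):
                    for dx in (-s, 0, s):
                        if dy == 0 and dx == 0:
                            continue
                        planes.append(_shift_reflect(im, dy, dx))
                        names.append(f"neighbour_dy{dy}_dx{dx}")
    data = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(data=data, names=names, fingerprint=cfg.fingerprint())


def _shift_reflect(im: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with reflected borders (value of the pixel dy/dx away)."""
    h, w = im.shape
    pad = np.pad(im, ((abs(dy), abs(dy)), (abs(dx), abs(dx))), mode="reflect")
    return pad[abs(dy) + dy:abs(dy) + dy + h, abs(dx) + dx:abs(dx) + dx + w]
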