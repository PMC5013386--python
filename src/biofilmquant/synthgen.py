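"""Synthetic SEM-like micrograph pairs with ground truth.

The generator emulates the two titanium implant surface classes used in
quantitative biofilm-removal studies -- a polished surface (smooth
background with thin scratch artifacts) and an SLA-like surface
(sandblasted/acid-etched: multi-scale pitted texture under uneven
illumination) -- colonised by coccal-chain biofilm rendered with the
SEM edge effect (bright rims, interiors close to the surface intensity).
The weak fill contrast is deliberate: on the SLA texture a global
intensity threshold cannot separate biofilm from surface, which is the
regime trainable pixel classification is designed for.

Each pair consists of a "before" frame and an "after" frame in which a
chosen fraction of biofilm clusters has been detached (removal is
patch-wise, as mechanical disruption detaches biofilm in patches) and a
known rigid misalignment has been applied, mimicking imperfect stage
relocation between SEM sessions.  Ground-truth masks and the realized
percent-remaining are recorded, so every downstream stage can be scored
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import transform as sktransform

from ._util import stream_rng
from .imgio import DEFAULT_PIXEL_SIZE_NM, BinaryMask, GrayImage

__all__ = ["SyntheticSpec", "SyntheticPair", "generate_surface", "place_biofilm", "render_pair"]

# stream ids for deriving per-stage rngs from the spec seed
_S_SURFACE, _S_PLACE, _S_NOISE_BEFORE, _S_NOISE_AFTER, _S_REMOVAL = range(5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic before/after pair.

    Defaults model typical experimental conditions: 250 nm pixels, cocci of ~0.5-1 um
    diameter (radius 2-4 px, default 3), chains of a few cells grouped into
    clusters, ~30% biofilm coverage before treatment and half of the
    clusters detached by it.
    """

    surface_type: str = "sla"
    width: int = 512
    height: int = 512
    target_coverage: float = 0.3
    removal_fraction: float = 0.5
    cell_radius_px: float = 3.0
    chain_length: float = 6.0
    noise_sd: float = 0.02
    rim_gain: float = 0.25
    illumination_amplitude: float = 0.15
    scratch_count: int = 12
    misalignment: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (theta_rad, tx, ty)
    seed: int = 0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        if self.surface_type not in ("polished", "sla"):
            raise ValueError(f"surface_type must be 'polished' or 'sla', got {self.surface_type!r}")
        if not (0.0 <= self.target_coverage <= 0.9):
            raise ValueError("target_coverage must be in [0, 0.9]")
        if not (0.0 <= self.removal_fraction <= 1.0):
            raise ValueError("removal_fraction must be in [0, 1]")
        if self.cell_radius_px < 1:
            raise ValueError("cell_radius_px must be >= 1")
        if self.width < 32 or self.height < 32:
            raise ValueError("image must be at least 32x32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticPair:
    """A rendered before/after pair plus its ground truth.

    ``after_mask`` lives in the after frame (aligned with ``after_img``);
    ``after_mask_ref`` is the same truth before the rigid misalignment was
    applied, i.e. in the before frame, and is exact (no resampling), so
    the recorded ``realized_percent_remaining`` is an integer-pixel ratio.
    """

    spec: SyntheticSpec
    before_img: GrayImage
    after_img: GrayImage
    before_mask: BinaryMask
    after_mask: BinaryMask
    after_mask_ref: BinaryMask
    true_transform: tuple[float, float, float]
    realized_coverage_before: float
    realized_percent_remaining: float
    cluster_labels: np.ndarray = field(repr=False, default=None)


def _value_noise(shape: tuple[int, int], cell: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field: coarse grid upsampled with cubic interpolation."""
    h, w = shape
    gh, gw = max(2, h // cell + 2), max(2, w // cell + 2)
    grid = rng.standard_normal((gh, gw))
    return sktransform.resize(grid, shape, order=3, mode="reflect", anti_aliasing=False)


def generate_surface(spec: SyntheticSpec) -> GrayImage:
    """Render a clean (biofilm-free) surface image for the given spec."""
    return GrayImage.from_float(_surface_field(spec, noisy=True), spec.pixel_size_nm)


def _surface_field(spec: SyntheticSpec, noisy: bool, noise_stream: int = _S_NOISE_BEFORE) -> np.ndarray:
    field_ = _surface_base(spec) + _illumination(spec)
    if noisy and spec.noise_sd > 0:
        rng = stream_rng(spec.seed, noise_stream, 0)
        field_ = field_ + rng.normal(0.0, spec.noise_sd, field_.shape)
    return np.clip(field_, 0.0, 1.0)


def _surface_base(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free surface intensity field in [0, 1]."""
    rng = stream_rng(spec.seed, _S_SURFACE)
    shape = (spec.height, spec.width)
    if spec.surface_type == "polished":
        field_ = np.full(shape, 0.66, dtype=np.float64)
        for _ in range(spec.scratch_count):
            field_ += _scratch_line(shape, rng)
    else:
        # multi-octave value noise: grain texture with pit-like dark minima
        field_ = np.full(shape, 0.5, dtype=np.float64)
        # acid-etched grain texture is fine-grained (1-5 um at 250 nm/px);
        # large-scale variation comes from illumination, not the texture
        for cell, amp in ((64, 0.03), (32, 0.045), (16, 0.055), (8, 0.045), (4, 0.025)):
            field_ += amp * _value_noise(shape, cell, rng)
        pits = _value_noise(shape, 12, rng)
        field_ -= 0.12 * np.clip(pits - 0.8, 0.0, None)  # acid-etch pits: sparse dark minima
    return field_


def _illumination(spec: SyntheticSpec) -> np.ndarray:
    """Low-frequency shading field (SLA only); applied to the composed
    scene, since uneven illumination affects biofilm and surface alike."""
    shape = (spec.height, spec.width)
    if spec.surface_type != "sla" or spec.illumination_amplitude == 0:
        return np.zeros(shape)
    rng = stream_rng(spec.seed, _S_SURFACE, 1)
    # a low-order (near-planar) field: detector-level shading is smooth at
    # the frame scale, which is what background subtraction can correct
    f = _value_noise(shape, 2 * max(shape), rng)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak  # amplitude = maximal deviation from flat illumination
    return spec.illumination_amplitude * f


def _scratch_line(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """One thin bright/dark polishing scratch, slightly blurred."""
    h, w = shape
    canvas = np.zeros(shape, dtype=np.float64)
    # random chord across the frame
    if rng.random() < 0.5:
        r0, r1 = rng.integers(0, h, 2)
        c0, c1 = 0, w - 1
    else:
        c0, c1 = rng.integers(0, w, 2)
        r0, r1 = 0, h - 1
    rr, cc = skdraw.line(int(r0), int(c0), int(r1), int(c1))
    amp = rng.uniform(0.08, 0.18) * (1 if rng.random() < 0.5 else -1)
    canvas[rr, cc] = amp
    return ndi.gaussian_filter(canvas, 0.6)


# ---------------------------------------------------------------------------
# Biofilm placement


def place_biofilm(spec: SyntheticSpec) -> BinaryMask:
    """Place coccal-chain biofilm clusters reaching the target coverage."""
    labels, _, _ = _place_biofilm_labels(spec)
    return BinaryMask((labels > 0).astype(np.uint8))


def _place_biofilm_labels(spec: SyntheticSpec) -> tuple[np.ndarray, int, np.ndarray]:
    """Cluster-labelled biofilm placement.

    Returns ``(labels, n_clusters, centers)`` where ``labels`` is an int32
    image with 0 = surface and k = cluster id, and ``centers`` marks cell
    centers (used for per-cell shading).  Chains of touching discs (center
    spacing ~1.6 x radius, random-walk orientation) are grown cluster by
    cluster until coverage is within the tolerance of ``target_coverage``.
    """
    rng = stream_rng(spec.seed, _S_PLACE)
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)
    centers = np.zeros((h, w), dtype=bool)
    if spec.target_coverage <= 0:
        return labels, 0, centers
    r = float(spec.cell_radius_px)
    # chains are grown to slightly below target; closing the inter-cell
    # crevices (the EPS matrix filling gaps between cells) adds the rest
    target_px = spec.target_coverage * h * w
    raw_target_px = 0.93 * target_px
    cluster_id = 0
    attempts = 0
    max_attempts = 20000
    covered = 0
    while covered < raw_target_px:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"coverage target {spec.target_coverage} unreachable for {w}x{h} image")
        cluster_id += 1
        cy, cx = rng.uniform(r, h - r - 1), rng.uniform(r, w - r - 1)
        # compact microcolony: many chains curling around a common center,
        # forming the dense patchy mats typical of mature biofilm
        n_chains = int(rng.integers(12, 26))
        for _ in range(n_chains):
            y = float(np.clip(cy + rng.normal(0, 4.0 * r), r, h - r - 1))
            x = float(np.clip(cx + rng.normal(0, 4.0 * r), r, w - r - 1))
            theta = rng.uniform(0, 2 * np.pi)
            n_cells = 1 + rng.poisson(max(spec.chain_length - 1, 0))
            for _ in range(n_cells):
                rr, cc = skdraw.disk((y, x), r, shape=(h, w))
                labels[rr, cc] = cluster_id
                centers[int(round(y)), int(round(x))] = True
                theta += rng.normal(0, 0.5)
                y = float(np.clip(y + 1.6 * r * np.sin(theta), r, h - r - 1))
                x = float(np.clip(x + 1.6 * r * np.cos(theta), r, w - r - 1))
            covered = int(np.count_nonzero(labels))
            if covered >= raw_target_px:
                break
    if cluster_id > 0:
        labels = _fill_crevices(labels)
    return labels, cluster_id, centers


def _fill_crevices(labels: np.ndarray) -> np.ndarray:
    """Close small inter-cell gaps (the EPS matrix of a dense mat); filled
    pixels inherit the nearest cell's cluster id."""
    from skimage.morphology import disk

    m = labels > 0
    closed = ndi.binary_closing(m, structure=disk(2), border_value=0)
    new_px = closed & ~m
    if not new_px.any():
        return labels
    _, (iy, ix) = ndi.distance_transform_edt(~m, return_indices=True)
    out = labels.copy()
    out[new_px] = labels[iy[new_px], ix[new_px]]
    return out


# ---------------------------------------------------------------------------
# Pair rendering


def _render_scene(spec: SyntheticSpec, surface: np.ndarray, mask: np.ndarray,
                  centers: np.ndarray, texture: np.ndarray) -> np.ndarray:
    """Compose biofilm onto a clean surface field (no noise).

    Each coccus is rendered as a bright-ringed sphere (the SEM edge
    effect): a ring of gain ~rim_gain at the cell radius around every
    cell center, a slightly darker cell core, and an extra boost on the
    outer cluster boundary.  Mean fill intensity stays close to the
    surface intensity, so segmentation must rely on the fine-scale ring
    texture rather than a global threshold.
    """
    img = surface.copy()
    m = mask.astype(bool)
    r = float(spec.cell_radius_px)
    d = ndi.distance_transform_edt(~centers)
    ring = np.exp(-0.5 * ((d - r) / 0.9) ** 2)
    # body intensity is anchored near the SLA surface mean (0.5), so fill
    # contrast is weak on SLA but clear against the brighter polished surface
    body = 0.46 + 0.5 * texture - 0.05 * np.clip(1.0 - d / r, 0.0, 1.0)
    vals = body + 0.8 * spec.rim_gain * ring
    img[m] = vals[m]
    eroded = ndi.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    rim = m & ~eroded
    img[rim] += 0.6 * spec.rim_gain
    return img


def render_pair(spec: SyntheticSpec) -> SyntheticPair:
    """Render a before/after pair with ground-truth masks and transform."""
    labels, n_clusters, centers = _place_biofilm_labels(spec)
    before_mask = (labels > 0)
    surface = _surface_base(spec)
    illum = _illumination(spec)

    tex_rng = stream_rng(spec.seed, _S_PLACE, 1)
    texture = ndi.gaussian_filter(tex_rng.normal(0.0, 0.12, surface.shape), 1.0)

    before = _render_scene(spec, surface, before_mask, centers, texture) + illum
    rng_b = stream_rng(spec.seed, _S_NOISE_BEFORE)
    if spec.noise_sd > 0:
        before = before + rng_b.normal(0.0, spec.noise_sd, before.shape)
    before = np.clip(before, 0.0, 1.0)

    # cluster-wise removal: a fixed random permutation makes the removed set
    # nested in removal_fraction, so percent-remaining is monotone in it
    rng_rm = stream_rng(spec.seed, _S_REMOVAL)
    order = rng_rm.permutation(np.arange(1, n_clusters + 1))
    n_remove = int(round(spec.removal_fraction * n_clusters))
    removed = set(order[:n_remove].tolist())
    after_labels = np.where(np.isin(labels, list(removed)), 0, labels) if removed else labels
    after_mask_ref = (after_labels > 0)
    centers_after = centers & after_mask_ref

    after_scene = _render_scene(spec, surface, after_mask_ref, centers_after, texture) + illum
    rng_a = stream_rng(spec.seed, _S_NOISE_AFTER)
    if spec.noise_sd > 0:
        after_scene = after_scene + rng_a.normal(0.0, spec.noise_sd, after_scene.shape)
    after_scene = np.clip(after_scene, 0.0, 1.0)

    theta, tx, ty = spec.misalignment
    if theta == 0.0 and tx == 0.0 and ty == 0.0:
        after = after_scene
        after_mask = after_mask_ref.copy()
    else:
        tform = _misalignment_transform(spec, theta, tx, ty)
        # the forward map (after frame -> before frame) is exactly what warp
        # needs as its output->input coordinate map
        after = sktransform.warp(after_scene, tform, order=1, cval=0.0, preserve_range=True)
        after_mask = sktransform.warp(after_mask_ref.astype(np.float64), tform,
                                      order=0, cval=0.0) > 0.5

    area_before = int(before_mask.sum())
    area_after = int(after_mask_ref.sum())
    pct_remaining = 100.0 * area_after / area_before if area_before > 0 else float("nan")

    return SyntheticPair(
        spec=spec,
        before_img=GrayImage.from_float(before, spec.pixel_size_nm),
        after_img=GrayImage.from_float(after, spec.pixel_size_nm),
        before_mask=BinaryMask(before_mask.astype(np.uint8)),
        after_mask=BinaryMask(after_mask.astype(np.uint8)),
        after_mask_ref=BinaryMask(after_mask_ref.astype(np.uint8)),
        true_transform=(float(theta), float(tx), float(ty)),
        realized_coverage_before=area_before / before_mask.size,
        realized_percent_remaining=pct_remaining,
        cluster_labels=labels,
    )


def _misalignment_transform(spec: SyntheticSpec, theta: float, tx: float, ty: float):
    """Rigid map from after-frame coordinates to before-frame coordinates,
    rotating about the image center (x, y) = ((w-1)/2, (h-1)/2)."""
    cx, cy = (spec.width - 1) / 2.0, (spec.height - 1) / 2.0
    center = np.array([cx, cy])
    shift = sktransform.EuclideanTransform(translation=-center)
    rot = sktransform.EuclideanTransform(rotation=theta)
    back = sktransform.EuclideanTransform(translation=center + np.array([tx, ty]))
    return shift + rot + back
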