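"""Segmentation accuracy and reproducibility evaluation.

Pixelwise sensitivity/specificity against a reference mask, a per-image
ROC scatter (one operating point per image, not a threshold sweep), the
retraining reproducibility experiment (six classifiers trained from
freshly randomized ROI placements, each scored against the segmentation
of a 40-ROI reference classifier), and the Mann-Whitney rank-sum test
used for group comparisons at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._util import stream_rng
from .features import FeatureConfig, compute_feature_stack
from .imgio import BinaryMask, GrayImage, RoiSample, TrainingSet
from .segment import (DEFAULT_N_TREES, apply_classifier, extract_training_samples,
                      remove_small_objects, train_classifier)

__all__ = [
    "ValidationMetrics", "ReproducibilityReport", "confusion", "roc_scatter",
    "sample_rois_from_mask", "reproducibility_test", "rank_sum_test",
    "EXACT_RANKSUM_MAX_N",
]

EXACT_RANKSUM_MAX_N = 12
ROI_PURITY = 0.9


@dataclass(frozen=True)
class ValidationMetrics:
    """Pixel confusion counts with biofilm as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            warnings.warn("sensitivity undefined: no positive reference pixels", stacklevel=2)
            return float("nan")
        return self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        if denom == 0:
            warnings.warn("specificity undefined: no negative reference pixels", stacklevel=2)
            return float("nan")
        return self.tn / denom


def confusion(pred: BinaryMask, ref: BinaryMask) -> ValidationMetrics:
    """Pixelwise confusion of a predicted mask against a reference mask."""
    if pred.shape != ref.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {ref.shape}")
    p = pred.as_bool()
    r = ref.as_bool()
    return ValidationMetrics(
        tp=int(np.count_nonzero(p & r)),
        fp=int(np.count_nonzero(p & ~r)),
        tn=int(np.count_nonzero(~p & ~r)),
        fn=int(np.count_nonzero(~p & r)),
    )


def roc_scatter(metrics: list[ValidationMetrics]) -> list[tuple[float, float]]:
    """One (1 - specificity, sensitivity) operating point per image,
    order-preserving."""
    if not metrics:
        raise ValueError("empty metrics list")
    return [(1.0 - m.specificity, m.sensitivity) for m in metrics]


def sample_rois_from_mask(truth: BinaryMask, n: int, rng: np.random.Generator,
                          size: int = 12, purity: float = ROI_PURITY,
                          max_tries: int = 20000) -> TrainingSet:
    """Randomly place class-valid ROIs, emulating an operator choosing
    unambiguous regions.

    A candidate square is accepted for a class only if at least ``purity``
    of its truth-mask pixels belong to that class.  Target labels alternate
    biofilm/surface so both classes are always represented.
    """
    h, w = truth.shape
    if h < size or w < size:
        raise ValueError("image too small for ROI placement")
    m = truth.as_bool()
    samples: list[RoiSample] = []
    labels = ["biofilm" if i % 2 == 0 else "surface" for i in range(n)]
    # operators spread their samples over the image rather than clumping,
    # so candidates cycle through a shuffled coarse grid of sectors
    gy = gx = 3
    sectors: list[tuple[int, int]] = []
    for label in labels:
        want = label == "biofilm"
        placed = False
        for attempt in range(max_tries):
            if not sectors:
                sectors = [(i, j) for i in range(gy) for j in range(gx)]
                rng.shuffle(sectors)
            si, sj = sectors.pop()
            y0, y1 = si * h // gy, min((si + 1) * h // gy, h - size) + 1
            x0, x1 = sj * w // gx, min((sj + 1) * w // gx, w - size) + 1
            if y1 <= y0 or x1 <= x0:
                continue
            y = int(rng.integers(y0, y1))
            x = int(rng.integers(x0, x1))
            block = m[y:y + size, x:x + size]
            frac = block.mean() if want else 1.0 - block.mean()
            clash = any(s.label != label
                        and s.x < x + size and x < s.x + s.size
                        and s.y < y + size and y < s.y + s.size
                        for s in samples)
            if frac >= purity and not clash:
                samples.append(RoiSample(x=x, y=y, label=label, size=size))
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place a class-valid {label!r} ROI "
                               f"(purity >= {purity}) after {max_tries} tries")
    return TrainingSet(samples)


@dataclass
class ReproducibilityReport:
    """Per-repeat metrics of retrained classifiers versus the reference
    segmentation (classifier trained with ``ref_roi_count`` ROIs)."""

    repeats: list[ValidationMetrics]
    ref_roi_count: int
    roi_counts: list[int]
    seed: int

    @property
    def sensitivities(self) -> list[float]:
        return [m.sensitivity for m in self.repeats]

    @property
    def specificities(self) -> list[float]:
        return [m.specificity for m in self.repeats]

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivities))

    @property
    def sd_sensitivity(self) -> float:
        return float(np.std(self.sensitivities, ddof=1))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificities))

    @property
    def sd_specificity(self) -> float:
        return float(np.std(self.specificities, ddof=1))


def reproducibility_test(img: GrayImage, truth: BinaryMask, *,
                         n_repeats: int = 6,
                         roi_count_range: tuple[int, int] = (10, 20),
                         ref_roi_count: int = 40,
                         seed: int = 0,
                         feature_cfg: FeatureConfig | None = None,
                         n_trees: int = DEFAULT_N_TREES) -> ReproducibilityReport:
    """The retraining reproducibility experiment on one image.

    A reference classifier is trained from ``ref_roi_count`` randomly
    placed class-valid ROIs and its (cleaned) segmentation becomes the
    reference mask.  Each of ``n_repeats`` classifiers is then trained
    with a fresh random ROI count in ``roi_count_range`` and fresh
    placements, and its segmentation is scored against the reference.
    Fully deterministic for a fixed master seed.
    """
    cfg = feature_cfg or FeatureConfig.default()
    stack = compute_feature_stack(img, cfg)

    ref_rng = stream_rng(seed, 100)
    ref_ts = sample_rois_from_mask(truth, ref_roi_count, ref_rng)
    X, y = extract_training_samples(stack, ref_ts, truth=truth)
    ref_clf = train_classifier(X, y, feature_fingerprint=stack.fingerprint,
                               n_trees=n_trees, seed=seed)
    ref_mask = remove_small_objects(apply_classifier(ref_clf, stack).mask)

    repeats: list[ValidationMetrics] = []
    roi_counts: list[int] = []
    for rep in range(n_repeats):
        rng = stream_rng(seed, 200, rep)
        n_rois = int(rng.integers(roi_count_range[0], roi_count_range[1] + 1))
        ts = sample_rois_from_mask(truth, n_rois, rng)
        Xr, yr = extract_training_samples(stack, ts, truth=truth)
        clf = train_classifier(Xr, yr, feature_fingerprint=stack.fingerprint,
                               n_trees=n_trees, seed=seed + rep + 1)
        mask = remove_small_objects(apply_classifier(clf, stack).mask)
        repeats.append(confusion(mask, ref_mask))
        roi_counts.append(n_rois)
    return ReproducibilityReport(repeats=repeats, ref_roi_count=ref_roi_count,
                                 roi_counts=roi_counts, seed=seed)


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U1 without ties: counts[u] = number of rank
    arrangements with U1 = u, via the classic recurrence
    N(u | m, n) = N(u - n | m-1, n) + N(u | m, n-1)."""
    prev = [np.array([1.0]) for _ in range(n2 + 1)]  # m = 0 row: delta at u = 0
    for m in range(1, n1 + 1):
        cur = [np.array([1.0])]  # n = 0: delta at u = 0
        for n in range(1, n2 + 1):
            size = m * n + 1
            arr = np.zeros(size)
            arr[:cur[n - 1].size] += cur[n - 1]
            arr[n:n + prev[n].size] += prev[n]
            cur.append(arr)
        prev = cur
    return prev[n2]


def rank_sum_test(group_a: list[float], group_b: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where U is the U statistic of the first group
    (midranks for ties).  The p-value is exact (full null enumeration of
    the U distribution) when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < combined.size
    if n1 + n2 <= EXACT_RANKSUM_MAX_N and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u1))
        p_low = counts[:ui + 1].sum() / total
        p_high = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return float(u1), float(p)
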