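"""Trainable pixel classification of biofilm versus surface.

A randomized-tree ensemble is trained on the per-pixel feature vectors of
user-supplied 12x12 ROI samples and then applied to every pixel of the
image (or a batch of images).  Post-processing removes speckle objects
smaller than 20 pixels, and the before/after biofilm pixel areas give the
percent of biofilm remaining after treatment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from skimage import morphology as skmorph
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, FeatureStack, compute_feature_stack
from .imgio import BinaryMask, GrayImage, TrainingSet

logger = logging.getLogger(__name__)

CLASS_SURFACE = 0
CLASS_BIOFILM = 1
_LABEL_TO_CLASS = {"surface": CLASS_SURFACE, "biofilm": CLASS_BIOFILM}

DEFAULT_N_TREES = 200
MIN_OBJECT_SIZE = 20

__all__ = [
    "PixelClassifier", "SegmentationResult", "RemovalResult",
    "extract_training_samples", "train_classifier", "apply_classifier",
    "segment_image", "remove_small_objects", "quantify",
    "save_classifier", "load_classifier",
    "CLASS_SURFACE", "CLASS_BIOFILM", "DEFAULT_N_TREES", "MIN_OBJECT_SIZE",
]


@dataclass
class PixelClassifier:
    """A trained randomized-tree ensemble bound to a feature configuration.

    The ensemble uses bootstrap sampling per tree and a random feature
    subset per split of size floor(log2(n_features)) + 1; a fixed seed
    plus fixed samples yields a bit-identical model.  Class order is
    fixed: 0 = surface, 1 = biofilm.
    """

    model: RandomForestClassifier
    feature_fingerprint: str
    n_trees: int
    seed: int
    n_features: int

    def require_compatible(self, stack: FeatureStack) -> None:
        if stack.fingerprint != self.feature_fingerprint:
            raise ValueError(
                "feature configuration mismatch: classifier trained with "
                f"fingerprint {self.feature_fingerprint}, stack has {stack.fingerprint}")


@dataclass
class SegmentationResult:
    mask: BinaryMask
    probability_map: np.ndarray = field(repr=False, default=None)

    @property
    def biofilm_area_px(self) -> int:
        return self.mask.area_px

    @property
    def coverage(self) -> float:
        return self.mask.coverage


@dataclass
class RemovalResult:
    """Before/after biofilm areas and the percent remaining/removed."""

    area_before_px: int
    area_after_px: int

    def __post_init__(self) -> None:
        if self.area_before_px <= 0:
            raise ValueError("no biofilm before treatment (area_before_px must be > 0)")

    @property
    def percent_remaining(self) -> float:
        return 100.0 * self.area_after_px / self.area_before_px

    @property
    def percent_removed(self) -> float:
        return 100.0 - self.percent_remaining


def extract_training_samples(stack: FeatureStack, ts: TrainingSet,
                             truth: BinaryMask | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One labelled feature-vector row per ROI pixel (144 rows per 12x12 ROI).

    Row order is deterministic: samples in training-set order, pixels in
    row-major order within each ROI.  In harness mode (``truth`` given),
    each pixel takes its label from the ground-truth mask instead of the
    ROI label, so ROIs may legitimately span biofilm/surface boundaries.
    """
    ts.validate_bounds(stack.shape)
    if truth is not None and truth.shape != stack.shape:
        raise ValueError("truth mask dimensions must match the stack")
    rows, labels = [], []
    for s in ts.samples:
        ys, xs = s.slices()
        block = stack.data[ys, xs, :].reshape(-1, stack.n_features)
        rows.append(block)
        if truth is not None:
            labels.append(truth.pixels[ys, xs].reshape(-1).astype(np.int64))
        else:
            labels.append(np.full(block.shape[0], _LABEL_TO_CLASS[s.label], dtype=np.int64))
    X = np.concatenate(rows, axis=0)
    y = np.concatenate(labels, axis=0)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples must contain both classes")
    return X, y


def train_classifier(X: np.ndarray, y: np.ndarray, *, feature_fingerprint: str,
                     n_trees: int = DEFAULT_N_TREES, seed: int = 0) -> PixelClassifier:
    """Fit the randomized-tree ensemble on labelled feature vectors."""
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("cannot train on a single class")
    n_features = X.shape[1]
    max_features = int(np.floor(np.log2(n_features))) + 1
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(X, y)
    return PixelClassifier(model=model, feature_fingerprint=feature_fingerprint,
                           n_trees=n_trees, seed=int(seed), n_features=n_features)


def apply_classifier(clf: PixelClassifier, stack: FeatureStack,
                     chunk_rows: int = 200_000) -> SegmentationResult:
    """Classify every pixel; probability = ensemble vote fraction for
    biofilm, mask = probability > 0.5."""
    clf.require_compatible(stack)
    flat = stack.flat()
    biofilm_col = int(np.where(clf.model.classes_ == CLASS_BIOFILM)[0][0])
    probs = np.empty(flat.shape[0], dtype=np.float32)
    for start in range(0, flat.shape[0], chunk_rows):
        chunk = flat[start:start + chunk_rows]
        probs[start:start + chunk_rows] = clf.model.predict_proba(chunk)[:, biofilm_col]
    prob_map = probs.reshape(stack.shape)
    mask = BinaryMask((prob_map > 0.5).astype(np.uint8))
    return SegmentationResult(mask=mask, probability_map=prob_map)


def segment_image(img: GrayImage, training: TrainingSet | None = None, *,
                  classifier: PixelClassifier | None = None,
                  feature_cfg: FeatureConfig | None = None,
                  n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                  min_object_size: int = MIN_OBJECT_SIZE) -> SegmentationResult:
    """Convenience wrapper: feature stack -> (train) -> classify -> clean."""
    cfg = feature_cfg or FeatureConfig.default()
    stack = compute_feature_stack(img, cfg)
    if classifier is None:
        if training is None:
            raise ValueError("either a training set or a classifier is required")
        X, y = extract_training_samples(stack, training)
        classifier = train_classifier(X, y, feature_fingerprint=stack.fingerprint,
                                      n_trees=n_trees, seed=seed)
    result = apply_classifier(classifier, stack)
    cleaned = remove_small_objects(result.mask, min_size=min_object_size)
    return SegmentationResult(mask=cleaned, probability_map=result.probability_map)


def remove_small_objects(mask: BinaryMask, min_size: int = MIN_OBJECT_SIZE,
                         connectivity: int = 8) -> BinaryMask:
    """Drop connected components with strictly fewer than ``min_size``
    pixels (8-connectivity by default); larger components are untouched."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 2 if connectivity == 8 else 1
    # max_size removes components <= its value, so "< min_size" is min_size - 1
    cleaned = skmorph.remove_small_objects(mask.as_bool(), max_size=min_size - 1,
                                           connectivity=conn)
    return BinaryMask(cleaned.astype(np.uint8))


def quantify(mask_before: BinaryMask, mask_after: BinaryMask) -> RemovalResult:
    """Percent of biofilm remaining: 100 * area_after / area_before."""
    if mask_before.shape != mask_after.shape:
        raise ValueError(
            f"mask dimensions differ: {mask_before.shape} vs {mask_after.shape}")
    result = RemovalResult(area_before_px=mask_before.area_px,
                           area_after_px=mask_after.area_px)
    if result.percent_remaining > 100.0:
        warnings.warn(
            f"biofilm area increased after treatment "
            f"({result.percent_remaining:.1f}% remaining)", stacklevel=2)
    return result


def save_classifier(clf: PixelClassifier, path) -> None:
    """Serialize a classifier with its feature fingerprint and seed."""
    joblib.dump({
        "format": "biofilmquant-classifier-v1",
        "model": clf.model,
        "feature_fingerprint": clf.feature_fingerprint,
        "n_trees": clf.n_trees,
        "seed": clf.seed,
        "n_features": clf.n_features,
    }, path)


def load_classifier(path) -> PixelClassifier:
    payload = joblib.load(path)
    if payload.get("format") != "biofilmquant-classifier-v1":
        raise ValueError("not a biofilmquant classifier file")
    return PixelClassifier(model=payload["model"],
                           feature_fingerprint=payload["feature_fingerprint"],
                           n_trees=payload["n_trees"], seed=payload["seed"],
                           n_features=payload["n_features"])
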