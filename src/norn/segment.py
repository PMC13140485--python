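"""MLP pixel classification of multichannel marker images.

Mirrors the wand-tool workflow of interactive image-analysis software: a
handful of manually annotated pixels per class train a multilayer
perceptron on a multi-scale Gaussian feature stack; the trained model is
applied at full resolution to produce per-class masks, which feed the
area-fraction and proximity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

from norn.markers import AnnotationStrokes, MarkerObjects

# thin luminal brush-border rings are ~6 px at full resolution; smoothing
# scales wider than the structure blur it into the background halo
DEFAULT_SCALES = (1.0, 2.0)


def _as_stack(image: np.ndarray) -> np.ndarray:
    """Coerce (H, W) or (C, H, W) to (C, H, W)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValueError(f"expected (H, W) or (C, H, W) image, got shape {image.shape}")
    return image


def extract_features(image: np.ndarray, scales=DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack: raw intensity plus Gaussian-smoothed
    intensity at each scale, for every channel.

    Parameters
    ----------
    image
        (H, W) or (channels, H, W) intensity image.
    scales
        Gaussian sigmas in pixels; all must be > 0. An empty list yields
        the raw channels only.

    Returns
    -------
    (H, W, n_features) array with features ordered channel-major:
    [c0_raw, c0_s1, ..., c0_sk, c1_raw, ...].
    """
    stack = _as_stack(image)
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise ValueError(f"Gaussian scales must be > 0, got {scales}")
    feats = []
    for plane in stack:
        feats.append(plane)
        for s in scales:
            feats.append(ndimage.gaussian_filter(plane, sigma=s))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifierModel:
    """Trained ANN/MLP pixel classifier with its feature recipe."""

    pipeline: Pipeline
    scales: tuple[float, ...]
    class_names: tuple[str, ...]  # declared order; index 0 is background
    n_channels: int
    pixel_size: float = 1.0
    min_object_px: int = 5

    def predict_proba(self, features_2d: np.ndarray) -> np.ndarray:
        return self.pipeline.predict_proba(features_2d)


def train_classifier(
    image: np.ndarray,
    strokes: AnnotationStrokes,
    seed: int = 0,
    scales=DEFAULT_SCALES,
    hidden_layer_sizes: tuple[int, ...] = (32,),
    min_pixels_per_class: int = 50,
    pixel_size: float = 1.0,
    min_object_px: int = 5,
) -> PixelClassifierModel:
    """Fit an MLP on the annotated pixels of each class.

    Features are standardized; the network has one hidden layer of 32 units
    by default, with early stopping on a 10% holdout of the annotations.
    Training is fully seeded. Classes with no annotated pixels raise an
    error naming the class; classes with fewer than ``min_pixels_per_class``
    are rejected as too sparse to learn from.
    """
    stack = _as_stack(image)
    shape = stack.shape[1:]
    for name, coords in strokes.pixels.items():
        if coords.size == 0:
            raise ValueError(f"annotation class {name!r} has zero pixels")
        if len(coords) < min_pixels_per_class:
            raise ValueError(
                f"annotation class {name!r} has {len(coords)} pixels; "
                f"need at least {min_pixels_per_class}"
            )
    strokes.validate(shape)

    features = extract_features(stack, scales)
    class_names = tuple(strokes.classes)
    X, y = [], []
    for label, name in enumerate(class_names):
        coords = strokes.pixels[name]
        X.append(features[coords[:, 0], coords[:, 1]])
        y.append(np.full(len(coords), label))
    X = np.concatenate(X)
    y = np.concatenate(y)

    mlp = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        random_state=seed,
        max_iter=500,
        learning_rate_init=0.01,  # annotation sets are small; the default
        early_stopping=True,      # rate stalls under early stopping
        validation_fraction=0.1,
        n_iter_no_change=30,
    )
    pipeline = make_pipeline(StandardScaler(), mlp)
    pipeline.fit(X, y)
    return PixelClassifierModel(
        pipeline=pipeline,
        scales=tuple(float(s) for s in scales),
        class_names=class_names,
        n_channels=stack.shape[0],
        pixel_size=pixel_size,
        min_object_px=min_object_px,
    )


def predict_mask(
    model: PixelClassifierModel, image: np.ndarray, min_object_px: int | None = None
) -> MarkerObjects:
    """Apply a trained classifier to an image and return per-class masks.

    Each pixel gets the argmax-posterior class (ties broken by lowest class
    index); connected components smaller than ``min_object_px`` are removed.
    The background class (index 0) gets no mask. Deterministic: predicting
    twice yields identical masks.
    """
    stack = _as_stack(image)
    if stack.shape[0] != model.n_channels:
        raise ValueError(
            f"image has {stack.shape[0]} channels; model was trained on "
            f"{model.n_channels}"
        )
    if min_object_px is None:
        min_object_px = model.min_object_px
    features = extract_features(stack, model.scales)
    h, w, f = features.shape
    proba = model.predict_proba(features.reshape(-1, f))
    labels = np.argmax(proba, axis=1).reshape(h, w)

    masks: dict[str, np.ndarray] = {}
    for idx, name in enumerate(model.class_names):
        if idx == 0:
            continue  # background
        mask = labels == idx
        if min_object_px > 1:
            mask = _remove_small(mask, min_object_px)
        masks[name] = mask
    return MarkerObjects(masks=masks, pixel_size=model.pixel_size)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop connected components (8-connectivity) below ``min_px`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def area_fraction(mask: np.ndarray, tissue_region: np.ndarray) -> float:
    """Summed object area within a region, divided by the region area.

    Both arrays are boolean masks on the same pixel grid; the result is in
    [0, 1] and independent of pixel calibration. A zero-area region is an
    error.
    """
    mask = np.asarray(mask, dtype=bool)
    region = np.asarray(tissue_region, dtype=bool)
    if mask.shape != region.shape:
        raise ValueError("mask and tissue_region must share a pixel grid")
    region_area = int(region.sum())
    if region_area == 0:
        raise ValueError("tissue region has zero area")
    return float((mask & region).sum()) / region_area


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum()) / float(union)
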