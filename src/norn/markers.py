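"""Calibrated marker-object containers shared by the simulator, the pixel
classifier and the proximity analysis.

A :class:`MarkerObjects` bundle holds one binary mask per marker class
(channel), all on the same pixel grid with a known micrometre-per-pixel
calibration. Masks may originate from the simulator's ground truth or from
the pixel classifier's predictions; downstream code does not care which.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure


@dataclass
class MarkerObjects:
    """Per-class binary masks with pixel calibration.

    Parameters
    ----------
    masks
        Mapping from marker class name to a 2-D boolean array. All arrays
        must share the same shape.
    pixel_size
        Calibration in micrometres per pixel (> 0).
    """

    masks: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, int]:
        if not self.masks:
            raise ValueError("no masks present")
        return next(iter(self.masks.values())).shape

    @property
    def classes(self) -> list[str]:
        return list(self.masks)

    def labeled(self, name: str) -> np.ndarray:
        """Connected-component label image (8-connectivity) for one class."""
        labels, _ = ndimage.label(self.masks[name], structure=np.ones((3, 3)))
        return labels

    def object_count(self, name: str) -> int:
        _, n = ndimage.label(self.masks[name], structure=np.ones((3, 3)))
        return int(n)

    def area_um2(self, name: str) -> float:
        """Total mask area of a class in square micrometres."""
        return float(self.masks[name].sum()) * self.pixel_size**2

    def to_polygons(self, name: str) -> list[dict]:
        """Approximate mask outlines as GeoJSON polygon features (µm).

        Contours are extracted at the 0.5 iso-level; coordinates are
        (x, y) in micrometres. Intended for export/interop, not for exact
        geometry: sub-pixel detail is lost.
        """
        mask = self.masks[name].astype(float)
        padded = np.pad(mask, 1)
        features = []
        for contour in measure.find_contours(padded, 0.5):
            # contour rows/cols are in padded pixel index space
            xy = (contour[:, ::-1] - 1.0 + 0.5) * self.pixel_size
            features.append(
                {
                    "type": "Feature",
                    "properties": {"classification": name},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [xy.tolist()],
                    },
                }
            )
        return features


@dataclass
class AnnotationStrokes:
    """Sparse manual training marks for the pixel classifier.

    ``pixels`` maps class name -> integer array of shape (n, 2) holding
    (row, col) pixel coordinates, mimicking wand-tool strokes. At least two
    classes (one of them typically background) are required for training.
    """

    pixels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coerced = {}
        for k, v in self.pixels.items():
            arr = np.asarray(v, dtype=int)
            if arr.size == 0:
                arr = np.empty((0, 2), dtype=int)
            coerced[k] = np.atleast_2d(arr)
        self.pixels = coerced

    @property
    def classes(self) -> list[str]:
        return list(self.pixels)

    def validate(self, shape: tuple[int, int]) -> None:
        if len(self.pixels) < 2:
            raise ValueError("need at least two annotated classes")
        for name, coords in self.pixels.items():
            if coords.size == 0:
                raise ValueError(f"class {name!r} has zero annotated pixels")
            if (
                coords[:, 0].min() < 0
                or coords[:, 1].min() < 0
                or coords[:, 0].max() >= shape[0]
                or coords[:, 1].max() >= shape[1]
            ):
                raise ValueError(f"class {name!r} has strokes outside image bounds")
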