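"""Calibrated nearest-object distances and REP-cell proximity classes.

The central measurement: for every REP cell (an Epo mRNA-positive
interstitial cell, given as a centroid in µm), the Euclidean distance to
the nearest detected object of each marker class, computed on the exact
Euclidean distance transform of the class mask and calibrated to
micrometres before any thresholding. A REP cell within the threshold
(default 15 µm — half of an average mouse proximal tubule diameter) of both
Sglt2 and Sglt1 is in "shared proximity"; within only one, it belongs to
that marker's class; beyond the threshold of both, it is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from norn.markers import MarkerObjects

logger = logging.getLogger(__name__)


@dataclass
class ProximityParams:
    """Threshold and marker pair for the three-class rule."""

    threshold_um: float = 15.0
    markers: tuple[str, str] = ("Sglt2", "Sglt1")
    source_reference: str = "centroid"  # future option: "boundary"

    def __post_init__(self) -> None:
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be > 0")
        if len(self.markers) != 2:
            raise ValueError("the three-class rule is defined for a marker pair")


def nearest_distance(
    points_um: np.ndarray,
    objects: MarkerObjects,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Distance from each point to the nearest object pixel of each class.

    Distances are exact-EDT based: the Euclidean distance transform of the
    inverted class mask is sampled at each point's pixel and multiplied by
    the pixel calibration, so values are micrometres. A point inside an
    object gets 0. A class with no objects yields infinity for every point
    (with a logged warning).

    Parameters
    ----------
    points_um
        (n, 2) array of (x, y) coordinates in micrometres.
    objects
        Calibrated per-class masks sharing the points' coordinate frame.
    classes
        Subset of classes to evaluate; defaults to all.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.size and pts.shape[1] != 2:
        raise ValueError("points_um must be (n, 2)")
    classes = list(classes) if classes is not None else objects.classes
    ps = objects.pixel_size
    ny, nx = objects.shape

    cols = (np.clip(np.floor(pts[:, 0] / ps), 0, nx - 1)).astype(int) if pts.size else np.empty(0, int)
    rows = (np.clip(np.floor(pts[:, 1] / ps), 0, ny - 1)).astype(int) if pts.size else np.empty(0, int)

    out = {}
    for name in classes:
        mask = objects.masks[name]
        if not mask.any():
            logger.warning("marker class %r has no objects; distances set to inf", name)
            out[name] = np.full(len(pts), np.inf)
            continue
        edt = ndimage.distance_transform_edt(~mask) * ps
        out[name] = edt[rows, cols]
    return pd.DataFrame(out)


def classify_rep_cells(
    distances: pd.DataFrame,
    params: ProximityParams = ProximityParams(),
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign the three-class proximity label to each REP cell.

    With marker pair (A, B) and threshold T, "within" is inclusive:
    dA <= T and dB <= T -> shared; dA <= T < dB -> A_only; dB <= T < dA ->
    B_only; both beyond T -> ignored. Returns the distance table with a
    ``proximity_class`` column (labels ``{A}_only``, ``{B}_only``,
    ``shared``, ``ignored``), plus any metadata columns passed in.
    """
    a, b = params.markers
    for m in (a, b):
        if m not in distances.columns:
            raise ValueError(f"distance column for marker {m!r} is missing")
    t = params.threshold_um
    da = distances[a].to_numpy(dtype=float)
    db = distances[b].to_numpy(dtype=float)
    labels = np.where(
        (da <= t) & (db <= t),
        "shared",
        np.where(da <= t, f"{a}_only", np.where(db <= t, f"{b}_only", "ignored")),
    )
    table = distances.copy()
    table["proximity_class"] = labels
    if meta is not None:
        for col in meta.columns:
            table[col] = np.asarray(meta[col])
    return table


def class_labels(params: ProximityParams) -> list[str]:
    a, b = params.markers
    return [f"{a}_only", f"{b}_only", "shared", "ignored"]


def within_threshold_percentage(
    distances: pd.DataFrame, marker: str, params: ProximityParams = ProximityParams()
) -> float:
    """Percentage of REP cells whose distance to ``marker`` is within the
    threshold (inclusive). Markers are evaluated independently, so
    percentages over a panel may sum to more than 100."""
    if marker not in distances.columns:
        raise ValueError(f"distance column for marker {marker!r} is missing")
    d = distances[marker].to_numpy(dtype=float)
    if len(d) == 0:
        raise ValueError("no REP cells: percentage undefined")
    return 100.0 * float(np.sum(d <= params.threshold_um)) / len(d)


def class_density(
    table: pd.DataFrame,
    params: ProximityParams = ProximityParams(),
    region_area_mm2: float | None = None,
    mode: str = "fraction",
) -> pd.Series:
    """Per-class REP cell density.

    mode="per_area": counts per mm² of annotated tissue (requires
    ``region_area_mm2`` > 0); includes the ignored class. mode="fraction":
    each non-ignored class count divided by the total classified
    (non-ignored) count.
    """
    counts = table["proximity_class"].value_counts()
    labels = class_labels(params)
    counts = counts.reindex(labels, fill_value=0)
    if mode == "per_area":
        if region_area_mm2 is None or region_area_mm2 <= 0:
            raise ValueError("per_area mode requires region_area_mm2 > 0")
        return counts / region_area_mm2
    if mode == "fraction":
        classified = counts[labels[:3]]
        total = classified.sum()
        if total == 0:
            raise ValueError("no classified (non-ignored) cells; fraction undefined")
        return classified / total
    raise ValueError(f"unknown mode {mode!r}")


def aggregate_per_animal(
    table: pd.DataFrame,
    params: ProximityParams = ProximityParams(),
    region_area_mm2: float | None = None,
    mode: str = "fraction",
) -> pd.DataFrame:
    """Tidy per-animal summary for external statistics.

    Densities are computed per section and then averaged per animal (the
    usual two-sections-per-mouse design), yielding one row per animal x
    class (x condition when present) in long format.
    """
    for col in ("section_id", "animal_id"):
        if col not in table.columns:
            raise ValueError(f"metadata column {col!r} is required")
    has_condition = "condition" in table.columns
    if has_condition:
        dup = (
            table.groupby(["animal_id", "section_id"])["condition"].nunique()
        )
        if (dup > 1).any():
            bad = dup[dup > 1].index.tolist()
            raise ValueError(f"conflicting conditions within sections: {bad}")

    rows = []
    group_cols = ["animal_id", "section_id"] + (["condition"] if has_condition else [])
    for keys, sec in table.sort_values(group_cols).groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        dens = class_density(sec, params, region_area_mm2=region_area_mm2, mode=mode)
        for cls, value in dens.items():
            rec = {"animal_id": keys[0], "section_id": keys[1], "class": cls, "value": value}
            if has_condition:
                rec["condition"] = keys[2]
            rows.append(rec)
    per_section = pd.DataFrame(rows)
    agg_cols = ["animal_id", "class"] + (["condition"] if has_condition else [])
    summary = (
        per_section.groupby(agg_cols, sort=True)["value"].mean().reset_index()
    )
    return summary.sort_values(agg_cols).reset_index(drop=True)


def brute_force_nearest(points_um: np.ndarray, mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Reference oracle: minimum distance from each point to any foreground
    pixel centre, by exhaustive enumeration. O(points x pixels); use only
    on small masks, e.g. to validate the EDT path."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    fg = np.argwhere(mask)
    if len(fg) == 0:
        return np.full(len(pts), np.inf)
    centers = (fg[:, ::-1] + 0.5) * pixel_size  # (x, y) of pixel centres
    d = np.hypot(
        pts[:, None, 0] - centers[None, :, 0], pts[:, None, 1] - centers[None, :, 1]
    )
    return d.min(axis=1)
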