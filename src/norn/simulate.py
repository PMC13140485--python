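"""Synthetic kidney tissue with known ground truth.

The simulator emulates the data modalities of a REP-cell microenvironment
study on 2-D kidney sections: zone-structured tissue geometry (cortex,
corticomedullary border, inner medulla) populated with circular tubule
cross-sections; clustered interstitial REP cells placed with a configurable
proximity preference towards PT S1 (Sglt2+) and PT S2/S3 (Sglt1+) tubules;
multichannel immunofluorescence-style marker images with luminal
brush-border rings; and a hexagonal Visium-style spot grid whose counts are
negative-binomial mixtures over cell types, with Epo counts injected only
into spots overlapping REP cells. A UUO-injury transform shifts composition
mass from PT S2/S3 to an injured PT type, silences Sglt2, preserves Sglt1,
and elevates injury-marker expression.

All randomness flows from one integer seed; each stage draws from its own
sub-stream so that, e.g., the gene panel is identical between a healthy and
an injured run of the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from anndata import AnnData
from scipy import ndimage, sparse
from shapely.geometry import Point
from shapely.ops import unary_union

from norn.markers import MarkerObjects

# ---------------------------------------------------------------------------
# vocabulary

ZONES = ("cortex", "corticomedullary_border", "inner_medulla")

SEGMENTS = ("PT_S1", "PT_S2S3", "TAL", "DCT", "IMCD")

#: nephron segment -> immunofluorescence channel
SEGMENT_CHANNELS = {
    "PT_S1": "Sglt2",
    "PT_S2S3": "Sglt1",
    "TAL": "Nkcc2",
    "DCT": "Ncc",
    "IMCD": "Ut-a",
}

CHANNELS = ("Sglt2", "Sglt1", "Nkcc2", "Ncc", "Ut-a", "aSMA", "KIM1")

CELL_TYPES = (
    "PT_S1",
    "PT_S2S3",
    "injured_PT",
    "TAL",
    "DCT",
    "IMCD",
    "Endo",
    "Norn",
    "Macro",
)

#: interstitial area is split between these types (healthy defaults)
INTERSTITIAL_FRACTIONS = {"Endo": 0.60, "Norn": 0.35, "Macro": 0.05}

#: marker gene -> cell type it identifies
MARKER_GENES = {
    "Slc5a2": "PT_S1",
    "Slc5a1": "PT_S2S3",
    "Slc12a1": "TAL",
    "Slc12a3": "DCT",
    "Slc14a2": "IMCD",
    "Pecam1": "Endo",
    "Pdgfrb": "Norn",
    "Cd68": "Macro",
}

INJURY_GENES = ("Havcr1", "Lcn2", "Vcam1", "Tgfb1", "Spp1")

RECEPTOR_GENES = ("Cd44", "Itgav", "Itgb3", "Tgfbr1", "Tgfbr2")

#: per-zone relative frequencies of tubule segments
ZONE_SEGMENT_FREQS = {
    "cortex": {"PT_S1": 0.45, "PT_S2S3": 0.25, "DCT": 0.20, "TAL": 0.10},
    "corticomedullary_border": {"PT_S1": 0.20, "PT_S2S3": 0.45, "TAL": 0.30, "DCT": 0.05},
    "inner_medulla": {"IMCD": 0.60, "TAL": 0.40},
}

PROXIMITY_CLASSES = ("near_s1", "near_s2s3", "shared", "far")

# fixed sub-stream tags so stages are independently reproducible
_STREAM_GEOMETRY = 1
_STREAM_CELLS = 2
_STREAM_RENDER = 3
_STREAM_SIGNATURES = 4
_STREAM_COUNTS = 5
_STREAM_STROKES = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(stream), int(seed)])


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class SimulationConfig:
    """All tunable parameters of one simulated tissue section.

    Geometric units are micrometres throughout. Defaults describe a healthy
    hypoxic section: 1.2 x 1.2 mm extent, ~30 µm proximal tubules, REP cells
    clustered in the corticomedullary band with a preference for Sglt1+
    (PT S2/S3) and shared Sglt2/Sglt1 neighbourhoods.
    """

    seed: int = 0
    extent: tuple[float, float] = (1200.0, 1200.0)  # (width, height) µm
    zone_fractions: tuple[float, float, float] = (0.40, 0.25, 0.35)
    n_tubules: int = 500
    tubule_diameter_um: float = 30.0
    tubule_margin_um: float = 2.0
    n_rep_cells: int = 100
    cluster_intensity: float = 150.0  # Neyman-Scott parents per mm^2 of band
    cluster_radius_um: float = 40.0
    proximity_preference: tuple[float, float, float, float] = (0.20, 0.35, 0.45, 0.0)
    threshold_um: float = 15.0  # half of an average mouse PT diameter
    placement_margin_um: float = 1.0
    pixel_size: float = 0.33  # µm/pixel, full-resolution imaging
    ring_width_um: float = 2.0  # luminal brush-border thickness
    background: float = 10.0
    amplitude: float = 200.0
    noise_sd: float = 8.0
    spot_diameter: float = 55.0
    spot_pitch: float = 100.0
    depth: float = 5000.0  # expected counts per spot
    dispersion: float = 10.0  # NB theta; np.inf -> Poisson
    n_background_genes: int = 120
    epo_level: float = 40.0  # expected Epo counts per overlapping REP cell
    pt_size_weight: float = 3.0  # mRNA-content weight of PT cell types
    interstitial_cell_weight: float = 0.3  # sparse interstitium, low mRNA
    injury: bool = False
    injury_fraction: float = 0.6  # PT S2/S3 composition mass converted
    sglt2_loss: float = 0.7  # global fractional loss of Slc5a2 expression
    macro_gain: float = 0.10  # tubular mass fraction shifted to macrophages
    section_id: int = 0
    animal_id: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.spot_diameter > self.spot_pitch:
            raise ValueError("spot_diameter must be <= spot_pitch")
        p = np.asarray(self.proximity_preference, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("proximity_preference must be 4 non-negative values summing to 1")
        if abs(sum(self.zone_fractions) - 1.0) > 1e-9:
            raise ValueError("zone_fractions must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TubuleObject:
    id: int
    segment: str
    polygon: shapely.Polygon
    diameter: float
    zone: str
    injured: bool = False  # injury-marker (KIM1) positive
    sglt2_silenced: bool = False  # PT S1 tubule that lost Sglt2 protein


@dataclass
class TissueGeometry:
    extent: tuple[float, float]
    zone_bounds: dict[str, tuple[float, float]]  # zone -> (y0, y1)
    tubules: list[TubuleObject]

    def zone_of(self, y: float) -> str:
        for zone, (y0, y1) in self.zone_bounds.items():
            if y0 <= y < y1:
                return zone
        return ZONES[-1]

    def tubules_of(self, segment: str) -> list[TubuleObject]:
        return [t for t in self.tubules if t.segment == segment]

    def segment_union(self, segment: str):
        polys = [t.polygon for t in self.tubules_of(segment)]
        return unary_union(polys) if polys else None

    @property
    def area_mm2(self) -> float:
        return self.extent[0] * self.extent[1] / 1e6


@dataclass
class GroundTruth:
    """Oracle for recovery tests: everything the analysis tries to infer."""

    rep_cells: pd.DataFrame  # cell_id, x_um, y_um, d_s1, d_s2s3, true_class, ...
    compositions: pd.DataFrame | None = None  # spots x cell types, rows on simplex
    spot_positions: pd.DataFrame | None = None  # spot_id, x_um, y_um
    markers: MarkerObjects | None = None
    signatures: pd.DataFrame | None = None  # cell types x genes, rows sum to 1

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            rep_cells=self.rep_cells.copy(),
            compositions=None if self.compositions is None else self.compositions.copy(),
            spot_positions=None if self.spot_positions is None else self.spot_positions.copy(),
            markers=self.markers,
            signatures=None if self.signatures is None else self.signatures.copy(),
        )


@dataclass
class SimulatedSample:
    config: SimulationConfig
    geometry: TissueGeometry
    truth: GroundTruth
    image: np.ndarray | None  # (channels, H, W) float32
    channel_names: tuple[str, ...]
    adata: AnnData | None


# ---------------------------------------------------------------------------
# geometry


def _zone_bounds(config: SimulationConfig) -> dict[str, tuple[float, float]]:
    height = config.extent[1]
    bounds = {}
    y0 = 0.0
    for zone, frac in zip(ZONES, config.zone_fractions):
        y1 = y0 + frac * height
        bounds[zone] = (y0, y1)
        y0 = y1
    bounds[ZONES[-1]] = (bounds[ZONES[-1]][0], height)
    return bounds


def build_geometry(config: SimulationConfig) -> TissueGeometry:
    """Place non-overlapping circular tubule cross-sections into zone bands.

    Tubule segments are drawn with zone-dependent frequencies (PT S1
    cortex-enriched, PT S2/S3 enriched in the corticomedullary border, IMCD
    confined to the inner medulla); each tubule lies entirely within its
    zone. Placement is rejection sampling on circle centres; an extent too
    small to hold a single tubule, or overcrowding, is an error.
    """
    width, height = config.extent
    if min(width, height) < config.tubule_diameter_um:
        raise ValueError(
            f"extent {config.extent} smaller than one tubule diameter "
            f"({config.tubule_diameter_um} µm)"
        )
    if min(width, height) < config.spot_pitch:
        raise ValueError("extent must cover at least one spot pitch in each direction")

    rng = _rng(config.seed, _STREAM_GEOMETRY)
    bounds = _zone_bounds(config)

    # allocate tubule counts to zones proportionally to zone area
    fracs = np.asarray(config.zone_fractions, dtype=float)
    counts = np.floor(fracs * config.n_tubules).astype(int)
    remainder = config.n_tubules - counts.sum()
    order = np.argsort(-(fracs * config.n_tubules - counts))
    for i in range(remainder):
        counts[order[i % 3]] += 1

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tubules: list[TubuleObject] = []
    margin = config.tubule_margin_um
    tid = 0
    for zone, n_zone in zip(ZONES, counts):
        if n_zone == 0:
            continue
        y0, y1 = bounds[zone]
        freqs = ZONE_SEGMENT_FREQS[zone]
        seg_names = list(freqs)
        seg_p = np.asarray([freqs[s] for s in seg_names], dtype=float)
        seg_p /= seg_p.sum()
        segments = rng.choice(seg_names, size=n_zone, p=seg_p)
        for segment in segments:
            diameter = config.tubule_diameter_um * rng.uniform(0.85, 1.15)
            r = diameter / 2.0
            if y1 - y0 < diameter or width < diameter:
                raise ValueError(f"zone {zone!r} too thin for a tubule of {diameter:.1f} µm")
            placed = False
            for _ in range(4000):
                x = rng.uniform(r, width - r)
                y = rng.uniform(y0 + r, y1 - r)
                if centers:
                    c = np.asarray(centers)
                    rr = np.asarray(radii)
                    if np.any(np.hypot(c[:, 0] - x, c[:, 1] - y) < rr + r + margin):
                        continue
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place tubule {tid} in zone {zone!r}; "
                    "reduce n_tubules or enlarge the extent"
                )
            centers.append((x, y))
            radii.append(r)
            tubules.append(
                TubuleObject(
                    id=tid,
                    segment=str(segment),
                    polygon=Point(x, y).buffer(r, quad_segs=24),
                    diameter=diameter,
                    zone=zone,
                )
            )
            tid += 1

    if config.injury:
        for t in tubules:
            if t.segment == "PT_S1" and rng.uniform() < config.sglt2_loss:
                t.sglt2_silenced = True
            if t.segment == "PT_S2S3" and rng.uniform() < config.injury_fraction:
                t.injured = True

    return TissueGeometry(extent=config.extent, zone_bounds=bounds, tubules=tubules)


# ---------------------------------------------------------------------------
# REP cell placement


def _class_conditions(d1: np.ndarray, d2: np.ndarray, thr: float, eps: float) -> dict[str, np.ndarray]:
    return {
        "near_s1": (d1 < thr - eps) & (d2 >= thr + eps),
        "near_s2s3": (d2 < thr - eps) & (d1 >= thr + eps),
        "shared": (d1 < thr - eps) & (d2 < thr - eps),
        "far": (d1 >= thr + eps) & (d2 >= thr + eps),
    }


def place_rep_cells(
    geom: TissueGeometry,
    config: SimulationConfig,
    grid_res_um: float = 2.0,
    max_attempts_per_cell: int = 400,
) -> GroundTruth:
    """Place clustered interstitial REP cells with known proximity classes.

    Each cell first draws its true class (near-S1-only, near-S2/S3-only,
    shared, far) from ``proximity_preference``; a location satisfying that
    class's distance conditions (with a ``placement_margin_um`` guard band
    around the threshold so pixelation cannot flip the label) is then
    sampled from a Neyman-Scott cluster field: Poisson parent points in the
    corticomedullary band, Gaussian offspring dispersal, restricted to the
    interstitium. Distance conditions are verified exactly against the
    tubule polygons.
    """
    n = config.n_rep_cells
    cols = ["cell_id", "x_um", "y_um", "d_s1", "d_s2s3", "true_class", "parent_id",
            "section_id", "animal_id"]
    if n == 0:
        return GroundTruth(rep_cells=pd.DataFrame(columns=cols))

    pref = np.asarray(config.proximity_preference, dtype=float)
    s1_union = geom.segment_union("PT_S1")
    s2_union = geom.segment_union("PT_S2S3")
    if pref[0] + pref[2] > 0 and s1_union is None:
        raise ValueError("proximity preference requires PT_S1 tubules but none exist")
    if pref[1] + pref[2] > 0 and s2_union is None:
        raise ValueError("proximity preference requires PT_S2S3 tubules but none exist")

    rng = _rng(config.seed, _STREAM_CELLS)
    width, height = geom.extent
    thr = config.threshold_um
    eps = config.placement_margin_um

    # coarse feasibility grid: distances to each PT marker set and to any tubule
    nx = max(int(np.ceil(width / grid_res_um)), 2)
    ny = max(int(np.ceil(height / grid_res_um)), 2)
    gx = (np.arange(nx) + 0.5) * grid_res_um
    gy = (np.arange(ny) + 0.5) * grid_res_um
    xx, yy = np.meshgrid(gx, gy)

    def grid_distance(union) -> np.ndarray:
        if union is None:
            return np.full((ny, nx), np.inf)
        inside = shapely.contains_xy(union, xx.ravel(), yy.ravel()).reshape(ny, nx)
        if not inside.any():
            return np.full((ny, nx), np.inf)
        return ndimage.distance_transform_edt(~inside) * grid_res_um

    d1g = grid_distance(s1_union)
    d2g = grid_distance(s2_union)
    all_union = unary_union([t.polygon for t in geom.tubules]) if geom.tubules else None
    dallg = grid_distance(all_union)

    conditions = _class_conditions(d1g.ravel(), d2g.ravel(), thr, eps)
    interstitial = dallg.ravel() > 0.5  # small clearance from tubule walls
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    allowed: dict[str, np.ndarray] = {}
    for cls in PROXIMITY_CLASSES:
        allowed[cls] = np.flatnonzero(conditions[cls] & interstitial)
        if pref[PROXIMITY_CLASSES.index(cls)] > 0 and allowed[cls].size == 0:
            raise RuntimeError(
                f"proximity class {cls!r} has positive preference mass but no "
                "feasible interstitial location in this geometry"
            )

    # Neyman-Scott parents confined to the corticomedullary band
    y0, y1 = geom.zone_bounds["corticomedullary_border"]
    band_area_mm2 = width * (y1 - y0) / 1e6
    n_parents = max(int(rng.poisson(config.cluster_intensity * band_area_mm2)), 1)
    parents = np.column_stack(
        [rng.uniform(0, width, n_parents), rng.uniform(y0, y1, n_parents)]
    )
    sigma = config.cluster_radius_um

    # exact quota per class (largest remainder), shuffled: the configured
    # preference is reproduced exactly up to integer rounding
    quota = np.floor(pref * n).astype(int)
    frac = pref * n - quota
    for j in np.argsort(-frac, kind="stable")[: n - quota.sum()]:
        quota[j] += 1
    classes = np.repeat(np.arange(len(PROXIMITY_CLASSES)), quota)
    rng.shuffle(classes)
    rows = []
    for i in range(n):
        cls = PROXIMITY_CLASSES[classes[i]]
        cand_idx = allowed[cls]
        cand = coords[cand_idx]
        placed = False
        for attempt in range(max_attempts_per_cell):
            parent_id = int(rng.integers(n_parents))
            px, py = parents[parent_id]
            d2p = (cand[:, 0] - px) ** 2 + (cand[:, 1] - py) ** 2
            w = np.exp(-d2p / (2 * sigma**2))
            wsum = w.sum()
            if wsum < 1e-12:
                # parent too far from any feasible cell: fall back to uniform
                w = np.ones(len(cand))
                wsum = w.sum()
            j = rng.choice(len(cand), p=w / wsum)
            x = cand[j, 0] + rng.uniform(-grid_res_um / 2, grid_res_um / 2)
            y = cand[j, 1] + rng.uniform(-grid_res_um / 2, grid_res_um / 2)
            if not (0 <= x <= width and 0 <= y <= height):
                continue
            pt = Point(x, y)
            if all_union is not None and all_union.distance(pt) <= 0.5:
                continue
            d1 = np.inf if s1_union is None else s1_union.distance(pt)
            d2 = np.inf if s2_union is None else s2_union.distance(pt)
            ok = _class_conditions(np.asarray([d1]), np.asarray([d2]), thr, eps)[cls][0]
            if ok:
                rows.append((i, x, y, d1, d2, cls, parent_id,
                             config.section_id, config.animal_id))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"failed to place REP cell {i} of class {cls!r} after "
                f"{max_attempts_per_cell} attempts; preference may be infeasible "
                "for this geometry"
            )

    rep = pd.DataFrame(rows, columns=cols)
    return GroundTruth(rep_cells=rep)


# ---------------------------------------------------------------------------
# marker rendering


def _rasterize(polys, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside any polygon."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(minx / pixel_size) - 1, 0)
        c1 = min(int(maxx / pixel_size) + 2, shape[1])
        r0 = max(int(miny / pixel_size) - 1, 0)
        r1 = min(int(maxy / pixel_size) + 2, shape[0])
        if c1 <= c0 or r1 <= r0:
            continue
        xs = (np.arange(c0, c1) + 0.5) * pixel_size
        ys = (np.arange(r0, r1) + 0.5) * pixel_size
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        mask[r0:r1, c0:c1] |= inside
    return mask


def _luminal_ring(filled: np.ndarray, width_um: float, pixel_size: float) -> np.ndarray:
    """Band of pixels inside the tubule within ``width_um`` of its wall."""
    if not filled.any():
        return filled.copy()
    inner = ndimage.distance_transform_edt(filled) * pixel_size
    return filled & (inner <= width_um)


def _outer_ring(filled: np.ndarray, width_um: float, pixel_size: float) -> np.ndarray:
    """Band of pixels just outside the tubule wall (peritubular)."""
    if not filled.any():
        return filled.copy()
    outer = ndimage.distance_transform_edt(~filled) * pixel_size
    return (outer > 0) & (outer <= width_um)


def render_markers(
    geom: TissueGeometry, config: SimulationConfig
) -> tuple[MarkerObjects, np.ndarray, tuple[str, ...]]:
    """Render the marker channels and their ground-truth masks.

    Each nephron-segment channel is a luminal brush-border ring of elevated
    intensity along the inner tubule wall (matching apical transporter
    localisation), over an autofluorescence background with Gaussian noise.
    KIM1 marks the luminal ring of injured tubules; aSMA marks a peritubular
    (myofibroblast) band around injured tubules. Returns the ground-truth
    binary masks, the noisy image stack (channels, H, W) and channel names.
    """
    ps = config.pixel_size
    width, height = geom.extent
    shape = (int(round(height / ps)), int(round(width / ps)))
    rng = _rng(config.seed, _STREAM_RENDER)

    masks: dict[str, np.ndarray] = {}
    for segment, channel in SEGMENT_CHANNELS.items():
        tubs = geom.tubules_of(segment)
        if channel == "Sglt2":
            tubs = [t for t in tubs if not t.sglt2_silenced]
        filled = _rasterize([t.polygon for t in tubs], shape, ps)
        masks[channel] = _luminal_ring(filled, config.ring_width_um, ps)

    injured = [t for t in geom.tubules if t.injured]
    filled_inj = _rasterize([t.polygon for t in injured], shape, ps)
    masks["KIM1"] = _luminal_ring(filled_inj, config.ring_width_um, ps)
    masks["aSMA"] = _outer_ring(filled_inj, config.ring_width_um, ps)

    image = np.empty((len(CHANNELS), *shape), dtype=np.float32)
    for c, channel in enumerate(CHANNELS):
        plane = np.full(shape, config.background, dtype=np.float32)
        plane[masks[channel]] += config.amplitude
        if config.noise_sd > 0:
            plane += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        image[c] = np.clip(plane, 0.0, None)

    return MarkerObjects(masks=masks, pixel_size=ps), image, CHANNELS


# ---------------------------------------------------------------------------
# reference signatures


def reference_signatures(config: SimulationConfig) -> pd.DataFrame:
    """Cell-type expression signatures (rows on the simplex).

    Marker genes are strongly enriched in their own type; a panel of injury,
    receptor and Epo genes gets low baselines that the injury transform and
    the Epo injection modulate; ``n_background_genes`` filler genes receive
    log-normal type-specific rates. Depends only on the seed and panel size,
    never on the injury flag, so healthy and injured runs share one panel.
    """
    rng = _rng(config.seed, _STREAM_SIGNATURES)
    genes = (
        list(MARKER_GENES)
        + list(INJURY_GENES)
        + list(RECEPTOR_GENES)
        + ["Acta2", "Epo"]
        + [f"Bg{i:04d}" for i in range(config.n_background_genes)]
    )
    K = len(CELL_TYPES)
    rates = pd.DataFrame(0.02, index=list(CELL_TYPES), columns=genes, dtype=float)

    for gene, ctype in MARKER_GENES.items():
        rates.loc[ctype, gene] = 25.0
    # injured PT keeps the S2/S3 identity before the injury transform
    for gene in INJURY_GENES:
        rates[gene] = 0.05
    rates.loc["Macro", "Spp1"] = 0.3
    for gene in RECEPTOR_GENES:
        rates[gene] = 0.5
        rates.loc["Norn", gene] = 2.0
    rates["Acta2"] = 0.1  # vascular smooth muscle is not modelled
    rates["Epo"] = 0.0  # quiescent Norn cells: Epo appears only by induction

    bg_cols = [g for g in genes if g.startswith("Bg")]
    rates.loc[:, bg_cols] = 0.25 * rng.lognormal(0.0, 1.0, size=(K, len(bg_cols)))

    rates.loc["injured_PT"] = rates.loc["PT_S2S3"]
    rates.loc["injured_PT", "Slc5a1"] = rates.loc["PT_S2S3", "Slc5a1"]

    return rates.div(rates.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# spot grid


def hex_lattice(extent: tuple[float, float], pitch: float) -> pd.DataFrame:
    """Pointy-top hexagonal lattice of spot centres covering the extent."""
    width, height = extent
    dy = pitch * np.sqrt(3) / 2
    rows = []
    sid = 0
    y = pitch / 2
    row = 0
    while y <= height - pitch / 4:
        x0 = pitch / 2 + (pitch / 2 if row % 2 else 0)
        x = x0
        while x <= width - pitch / 4:
            rows.append((f"spot_{sid:04d}", x, y, row))
            sid += 1
            x += pitch
        y += dy
        row += 1
    if not rows:
        raise ValueError(f"extent {extent} too small for spot pitch {pitch}")
    return pd.DataFrame(rows, columns=["spot_id", "x_um", "y_um", "grid_row"]).set_index(
        "spot_id"
    )


def true_compositions(geom: TissueGeometry, config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Area- and cell-size-weighted true cell-type proportions per spot.

    Each spot's 55 µm capture disc is intersected with the tubule polygons;
    overlap areas map to the tubule's cell type, the residual interstitial
    area is split between endothelial, Norn and macrophage mass, and each
    type's area is weighted by its relative mRNA content (PT cells are large
    and mRNA-rich, weight ``pt_size_weight``). Rows are normalized onto the
    simplex.
    """
    positions = hex_lattice(config.extent, config.spot_pitch)
    radius = config.spot_diameter / 2.0
    tree = shapely.STRtree([t.polygon for t in geom.tubules]) if geom.tubules else None

    weights = {t: 1.0 for t in CELL_TYPES}
    for t in ("PT_S1", "PT_S2S3", "injured_PT"):
        weights[t] = config.pt_size_weight
    for t in INTERSTITIAL_FRACTIONS:
        weights[t] = config.interstitial_cell_weight

    comp = pd.DataFrame(0.0, index=positions.index, columns=list(CELL_TYPES))
    for sid, row in positions.iterrows():
        disc = Point(row.x_um, row.y_um).buffer(radius, quad_segs=24)
        disc_area = disc.area
        tub_area: dict[str, float] = {}
        if tree is not None:
            for idx in tree.query(disc):
                tub = geom.tubules[int(idx)]
                a = disc.intersection(tub.polygon).area
                if a > 0:
                    tub_area[tub.segment] = tub_area.get(tub.segment, 0.0) + a
        inter_area = max(disc_area - sum(tub_area.values()), 0.0)
        masses = {ct: 0.0 for ct in CELL_TYPES}
        for seg, a in tub_area.items():
            masses[seg] += a * weights[seg]
        for ct, frac in INTERSTITIAL_FRACTIONS.items():
            masses[ct] += inter_area * frac * weights[ct]
        total = sum(masses.values())
        comp.loc[sid] = [masses[ct] / total for ct in CELL_TYPES]
    return comp, positions


def simulate_spot_counts(
    geom: TissueGeometry, truth: GroundTruth, config: SimulationConfig
) -> AnnData:
    """Draw negative-binomial spot counts from the true mixtures.

    Per spot j the expected count of gene g is ``depth * sum_k w_jk s_gk``
    with composition w and signatures s; counts are NB with overdispersion
    ``dispersion`` (theta; infinite theta is the Poisson limit). Epo counts
    are injected only into spots whose capture disc overlaps at least one
    REP centroid. Fills ``truth.compositions``/``signatures`` if missing.
    """
    if truth.compositions is None or truth.spot_positions is None:
        truth.compositions, truth.spot_positions = true_compositions(geom, config)
    if truth.signatures is None:
        truth.signatures = reference_signatures(config)

    comp = truth.compositions
    positions = truth.spot_positions.loc[comp.index]
    sig = truth.signatures.loc[list(comp.columns)]
    genes = list(sig.columns)

    rng = _rng(config.seed, _STREAM_COUNTS)
    mean = config.depth * (comp.to_numpy() @ sig.to_numpy())  # spots x genes

    # Epo induction: count REP centroids inside each spot disc
    n_rep = np.zeros(len(positions), dtype=int)
    if len(truth.rep_cells):
        px = positions["x_um"].to_numpy()[:, None]
        py = positions["y_um"].to_numpy()[:, None]
        cx = truth.rep_cells["x_um"].to_numpy()[None, :]
        cy = truth.rep_cells["y_um"].to_numpy()[None, :]
        inside = np.hypot(px - cx, py - cy) <= config.spot_diameter / 2.0
        n_rep = inside.sum(axis=1)
    epo_idx = genes.index("Epo")
    mean[:, epo_idx] += config.epo_level * n_rep

    if np.isinf(config.dispersion):
        counts = rng.poisson(mean)
    else:
        theta = float(config.dispersion)
        lam = rng.gamma(theta, mean / theta)
        counts = rng.poisson(lam)

    obs = pd.DataFrame(
        {
            "x_um": positions["x_um"].to_numpy(),
            "y_um": positions["y_um"].to_numpy(),
            "in_tissue": 1,
            "n_rep_cells": n_rep,
            "epo_spot_true": n_rep > 0,
            "condition": "injured" if config.injury else "healthy",
        },
        index=comp.index.astype(str),
    )
    adata = AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obsm["true_compositions"] = comp.to_numpy()
    adata.uns["cell_types"] = list(comp.columns)
    adata.uns["seed"] = int(config.seed)
    return adata


# ---------------------------------------------------------------------------
# injury transform


def apply_injury_transform(truth: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """UUO-style injury: composition and signature remodelling.

    A fraction ``injury_fraction`` (f, the injury severity) of each spot's
    PT S2/S3 mass converts to injured PT; a further ``f * macro_gain``
    fraction of tubular (PT) mass shifts to macrophages (immune
    infiltration). Endothelial and Norn mass are untouched. On the
    expression side, Slc5a2 (Sglt2) is scaled down globally by
    ``f * sglt2_loss``, Slc5a1 (Sglt1) is preserved, and injury markers
    (Havcr1, Lcn2, Vcam1, Tgfb1, Spp1) are elevated in the injured PT
    signature in proportion to f. Every term scales with f, so f = 0 is the
    identity and f = 1 the fully remodelled kidney. Returns a new
    GroundTruth; the input is not modified.
    """
    f = config.injury_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"injury_fraction must be in [0, 1], got {f}")
    if truth.compositions is None or truth.signatures is None:
        raise ValueError("truth must have compositions and signatures; run true_compositions/reference_signatures first")

    out = truth.copy()
    comp = out.compositions
    moved = f * comp["PT_S2S3"]
    comp["PT_S2S3"] = comp["PT_S2S3"] - moved
    comp["injured_PT"] = comp["injured_PT"] + moved

    g = f * config.macro_gain
    pt_cols = ["PT_S1", "PT_S2S3", "injured_PT"]
    delta = g * comp[pt_cols].sum(axis=1)
    pt_total = comp[pt_cols].sum(axis=1).replace(0.0, np.nan)
    for col in pt_cols:
        comp[col] = comp[col] - (comp[col] / pt_total).fillna(0.0) * delta
    comp["Macro"] = comp["Macro"] + delta

    sig = out.signatures
    boosts = {"Havcr1": 200.0, "Lcn2": 60.0, "Vcam1": 60.0, "Tgfb1": 30.0, "Spp1": 120.0}
    for gene, factor in boosts.items():
        sig.loc["injured_PT", gene] *= 1.0 + f * (factor - 1.0)
    sig["Slc5a2"] = sig["Slc5a2"] * (1.0 - f * config.sglt2_loss)
    out.signatures = sig.div(sig.sum(axis=1), axis=0)
    return out


# ---------------------------------------------------------------------------
# stroke sampling (training annotations from ground truth)


def sample_strokes(
    markers: MarkerObjects,
    config: SimulationConfig,
    n_per_class: int = 200,
    classes: tuple[str, ...] | None = None,
):
    """Sample wand-tool-style training pixels from ground-truth masks.

    Picks ``n_per_class`` random pixels inside each requested marker mask
    plus the same number of background pixels. Half of the background
    pixels are drawn from the immediate surroundings of the signal (as an
    annotator marking "diverse" examples would), half from far background.
    Classes whose mask is empty are skipped.
    """
    from norn.markers import AnnotationStrokes

    rng = _rng(config.seed, _STREAM_STROKES)
    classes = tuple(classes) if classes is not None else tuple(markers.classes)
    pixels: dict[str, np.ndarray] = {}
    union = np.zeros(markers.shape, dtype=bool)
    for name in classes:
        union |= markers.masks[name]
    near = ndimage.binary_dilation(union, iterations=10) & ~union
    far = ~union & ~near
    n_near = min(n_per_class // 2, int(near.sum()))
    picks = []
    if n_near:
        cand = np.flatnonzero(near.ravel())
        picks.append(rng.choice(cand, size=n_near, replace=False))
    cand = np.flatnonzero(far.ravel())
    picks.append(rng.choice(cand, size=min(n_per_class - n_near, cand.size), replace=False))
    take = np.concatenate(picks)
    pixels["background"] = np.column_stack(np.unravel_index(take, markers.shape))
    for name in classes:
        fg = np.flatnonzero(markers.masks[name].ravel())
        if fg.size == 0:
            continue
        take = rng.choice(fg, size=min(n_per_class, fg.size), replace=False)
        pixels[name] = np.column_stack(np.unravel_index(take, markers.shape))
    return AnnotationStrokes(pixels=pixels)


# ---------------------------------------------------------------------------
# orchestration


def simulate_sample(config: SimulationConfig, render: bool = True) -> SimulatedSample:
    """Full simulation of one tissue section with ground truth.

    Runs geometry, REP placement, (optionally) marker rendering, signature
    construction, the injury transform when ``config.injury`` is set, and
    the spot-count draw. Deterministic given the config.
    """
    geom = build_geometry(config)
    truth = place_rep_cells(geom, config)
    image = None
    channel_names: tuple[str, ...] = ()
    if render:
        truth.markers, image, channel_names = render_markers(geom, config)
    truth.signatures = reference_signatures(config)
    truth.compositions, truth.spot_positions = true_compositions(geom, config)
    if config.injury:
        truth = apply_injury_transform(truth, config)
    adata = simulate_spot_counts(geom, truth, config)
    return SimulatedSample(
        config=config,
        geometry=geom,
        truth=truth,
        image=image,
        channel_names=channel_names,
        adata=adata,
    )
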