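"""Merged travel-cost surface: land cover + roads + barriers + travel scenario.

The friction surface is built the way AccessMod-style accessibility analyses
build theirs: vector roads and travel barriers are rasterised onto the land
cover grid with the priority *roads > barriers > land cover* (a road crossing
a river is a bridge and stays traversable), then every cell class is mapped to
a travel mode and speed from a multimodal travel scenario (walk on land
cover, motorcycle on minor roads, vehicle on the higher road classes).
Walking speeds are corrected for terrain slope with Tobler's hiking function,
normalised so that flat ground gives the scenario's base speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .grid import Grid

__all__ = [
    "LANDCOVER_CLASSES",
    "ROAD_CLASSES",
    "BARRIER_CLASSES",
    "ScenarioEntry",
    "TravelScenario",
    "MergedCostGrid",
    "merge_layers",
    "assign_speeds",
    "tobler_factor",
    "rasterize_features",
]

# Integer codes for the merged class grid. Land cover occupies 1-6, barriers
# 21-22, roads 31-37; 0 is reserved for nodata (outside the county).
LANDCOVER_CLASSES = {
    "tree_cover": 1,
    "shrubland": 2,
    "bare_land": 3,
    "grassland": 4,
    "built_up": 5,
    "wetland": 6,
}
BARRIER_CLASSES = {
    "river": 21,
    "protected_area": 22,
}
# Ordered lowest to highest class; when several roads share a cell the
# highest-priority (fastest) class is burned.
ROAD_CLASSES = {
    "rural_road": 31,
    "settlement_road": 32,
    "government_road": 33,
    "minor_road": 34,
    "secondary_road": 35,
    "primary_road": 36,
    "national_road": 37,
}
_CODE_TO_LABEL = {
    code: label
    for table in (LANDCOVER_CLASSES, BARRIER_CLASSES, ROAD_CLASSES)
    for label, code in table.items()
}

NODATA_CODE = 0


@dataclass(frozen=True)
class ScenarioEntry:
    class_label: str
    mode: str  # walking | motorcycle | vehicle
    speed_kmh: float

    def __post_init__(self):
        if self.mode not in ("walking", "motorcycle", "vehicle"):
            raise ValueError(f"unknown travel mode {self.mode!r}")
        if self.speed_kmh <= 0:
            raise ValueError(
                f"speed for {self.class_label!r} must be positive (barriers have no entry)"
            )


@dataclass
class TravelScenario:
    """Mapping from surface class to travel mode and speed (km/h).

    Barrier classes carry no entry: they are impassable unless overridden by
    a road. The shipped default speeds are documented placeholders: walking
    on open land cover, motorcycle on the minor road classes, vehicle on the
    secondary/primary/national roads.
    """

    entries: dict[str, ScenarioEntry] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "TravelScenario":
        spec = [
            ("tree_cover", "walking", 2.0),
            ("shrubland", "walking", 2.0),
            ("bare_land", "walking", 4.0),
            ("grassland", "walking", 4.0),
            ("built_up", "walking", 4.0),
            ("wetland", "walking", 1.0),
            ("rural_road", "motorcycle", 20.0),
            ("settlement_road", "motorcycle", 20.0),
            ("government_road", "motorcycle", 25.0),
            ("minor_road", "motorcycle", 30.0),
            ("secondary_road", "vehicle", 50.0),
            ("primary_road", "vehicle", 65.0),
            ("national_road", "vehicle", 80.0),
        ]
        return cls({label: ScenarioEntry(label, mode, v) for label, mode, v in spec})

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TravelScenario":
        """Build from ``{label: {mode: ..., speed_kmh: ...}}`` (config form)."""
        return cls(
            {
                label: ScenarioEntry(label, row["mode"], float(row["speed_kmh"]))
                for label, row in mapping.items()
            }
        )

    def to_mapping(self) -> dict:
        return {
            label: {"mode": e.mode, "speed_kmh": e.speed_kmh}
            for label, e in self.entries.items()
        }

    def speed_for(self, label: str) -> float:
        return self.entries[label].speed_kmh

    def mode_for(self, label: str) -> str:
        return self.entries[label].mode


@dataclass
class MergedCostGrid:
    """Per-cell travel class and speed after priority stacking.

    ``class_grid`` holds integer class codes (0 = nodata); ``speed`` is km/h
    with exactly 0 on barrier cells not overridden by a road, and ``mode``
    holds 0 for impassable, 1 walking, 2 motorcycle, 3 vehicle.
    """

    class_grid: Grid
    speed: Grid | None = None
    mode: Grid | None = None

    @property
    def cell_size(self) -> float:
        return self.class_grid.cell_size


def rasterize_features(features, grid: Grid) -> dict[str, np.ndarray]:
    """Rasterise (geometry, class_label) features onto ``grid``.

    Returns ``{label: boolean mask}``. Lines are burned into every cell whose
    center lies within half a cell of the line; polygons into every cell whose
    center they contain.
    """
    nr, nc = grid.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    cx, cy = grid.cell_center(rows.ravel(), cols.ravel())
    pts = shapely.points(cx, cy)
    masks: dict[str, np.ndarray] = {}
    for feat in features:
        geom = feat["geometry"]
        label = feat["class"]
        if geom.geom_type in ("Polygon", "MultiPolygon"):
            hit = shapely.contains_xy(geom, cx, cy)
        else:
            hit = shapely.dwithin(geom, pts, grid.cell_size * 0.5)
        mask = masks.setdefault(label, np.zeros((nr, nc), dtype=bool))
        mask |= hit.reshape(nr, nc)
    return masks


def merge_layers(
    landcover: Grid,
    roads=(),
    barriers=(),
) -> MergedCostGrid:
    """Stack roads, barriers and land cover into one class grid.

    Priority per cell is roads > barriers > land cover; cells that are nodata
    in the land cover stay nodata. Unknown class codes or labels raise.
    """
    lc = np.asarray(landcover.data).astype(int)
    known_lc = set(LANDCOVER_CLASSES.values()) | set(BARRIER_CLASSES.values()) | set(
        ROAD_CLASSES.values()
    )
    bad = set(np.unique(lc)) - known_lc - {int(landcover.nodata), NODATA_CODE}
    if bad:
        raise ValueError(f"unknown land cover class codes: {sorted(bad)}")

    merged = np.where(lc == int(landcover.nodata), NODATA_CODE, lc)

    feature_lists = {"barriers": list(barriers), "roads": list(roads)}
    for kind, feats in feature_lists.items():
        table = BARRIER_CLASSES if kind == "barriers" else ROAD_CLASSES
        for feat in feats:
            if feat["class"] not in table:
                raise ValueError(f"unknown {kind[:-1]} class {feat['class']!r}")

    if feature_lists["barriers"]:
        for label, mask in rasterize_features(feature_lists["barriers"], landcover).items():
            merged[mask & (merged != NODATA_CODE)] = BARRIER_CLASSES[label]
    if feature_lists["roads"]:
        road_masks = rasterize_features(feature_lists["roads"], landcover)
        # burn lowest-priority first so the fastest class wins shared cells
        for label in ROAD_CLASSES:  # dict order = ascending priority
            if label in road_masks:
                mask = road_masks[label]
                merged[mask & (merged != NODATA_CODE)] = ROAD_CLASSES[label]
    out = landcover.copy_with(merged.astype(np.int32))
    out.nodata = NODATA_CODE
    return MergedCostGrid(class_grid=out)


_MODE_CODE = {"walking": 1, "motorcycle": 2, "vehicle": 3}


def assign_speeds(merged: MergedCostGrid, scenario: TravelScenario) -> MergedCostGrid:
    """Populate the speed (km/h) and mode grids from the travel scenario.

    Every non-barrier class present in the grid must have a scenario entry;
    barrier cells get speed 0 (impassable).
    """
    classes = merged.class_grid.data
    present = set(np.unique(classes)) - {NODATA_CODE}
    barrier_codes = set(BARRIER_CLASSES.values())
    missing = [
        _CODE_TO_LABEL[c]
        for c in sorted(present - barrier_codes)
        if _CODE_TO_LABEL[c] not in scenario.entries
    ]
    if missing:
        raise ValueError(f"travel scenario missing classes: {missing}")

    speed = np.zeros(classes.shape, dtype=float)
    mode = np.zeros(classes.shape, dtype=np.int8)
    for code in present:
        if code in barrier_codes:
            continue
        label = _CODE_TO_LABEL[int(code)]
        sel = classes == code
        speed[sel] = scenario.speed_for(label)
        mode[sel] = _MODE_CODE[scenario.mode_for(label)]
    speed[classes == NODATA_CODE] = 0.0
    g = merged.class_grid
    return MergedCostGrid(
        class_grid=g,
        speed=g.copy_with(speed),
        mode=g.copy_with(mode),
    )


_TOBLER_NORM = math.exp(-3.5 * 0.05)


def tobler_factor(slope) -> np.ndarray:
    """Slope multiplier for walking speed, normalised to 1 on flat ground.

    ``slope`` is rise over run (dimensionless, signed: positive uphill).
    Tobler's hiking function ``exp(-3.5 |s + 0.05|)`` peaks at a gentle
    downhill of s = -0.05; dividing by its value at s = 0 makes the factor
    exactly 1.0 on the flat, strictly decreasing in ``|s + 0.05|``.
    """
    slope = np.asarray(slope, dtype=float)
    return np.exp(-3.5 * np.abs(slope + 0.05)) / _TOBLER_NORM
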