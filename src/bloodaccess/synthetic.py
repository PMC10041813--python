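"""Synthetic county generator and the packaged transfusing-facility table.

The generator emulates the study setting of a western-Kenyan county: a few
towns concentrating population and high-capacity hospitals, ~250 health
facilities of which ~15 are transfusing (received AND transfused at least one
blood unit over a four-year window), ~1,400 enumeration areas (EAs, census
units of roughly 100 households) nested in ~12 sub-counties, a hierarchical
7-class road network draped over a 6-class land cover with river and
protected-area travel barriers, and blood-unit volumes positively associated
with facility size. Everything is a pure function of the scenario (seed
included), so repeated runs are byte-identical.

Coordinates are planar metres throughout; the county occupies the full
rectangular grid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from functools import cached_property

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, box

from .cost import BARRIER_CLASSES, LANDCOVER_CLASSES, ROAD_CLASSES
from .grid import Grid

__all__ = [
    "CountyScenario",
    "CountyBundle",
    "InfeasibleScenarioError",
    "generate_county",
    "adjust_population",
    "load_table1",
]


class InfeasibleScenarioError(ValueError):
    """Raised when a scenario cannot be realised, naming the constraint."""


@dataclass(frozen=True)
class CountyScenario:
    """Parameters of a synthetic county.

    Defaults mirror the study setting: a county roughly 84 km across
    (modelled at 300 m resolution for desk-scale runtimes), 12 sub-counties,
    250 facilities with 15 transfusing, 1,400 EAs, ~1.73 million residents. ``urban_fraction`` is the proportion of
    transfusing facilities located inside urban built-up clusters;
    ``blood_units_per_bed`` is the expected blood units received per
    inpatient bed over the four-year reporting window, with log-normal noise
    of standard deviation ``blood_noise_sd``.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (280, 280)
    cell_size: float = 300.0
    n_subcounties: int = 12
    n_facilities: int = 250
    n_transfusing: int = 15
    n_eas: int = 1400
    total_population: float = 1_734_900.0
    urban_fraction: float = 0.8
    blood_units_per_bed: float = 15.0
    blood_noise_sd: float = 0.5

    def __post_init__(self):
        if self.n_transfusing > self.n_facilities:
            raise InfeasibleScenarioError("n_transfusing exceeds n_facilities")
        if self.n_eas < self.n_subcounties:
            raise InfeasibleScenarioError("n_eas must be at least n_subcounties")
        if self.total_population <= 0:
            raise InfeasibleScenarioError("total_population must be positive")
        if min(self.grid_shape) < 16:
            raise InfeasibleScenarioError("grid_shape dimensions must be at least 16")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise InfeasibleScenarioError("urban_fraction must lie in [0, 1]")


@dataclass
class CountyBundle:
    """Everything :func:`generate_county` produces for one county."""

    scenario: CountyScenario
    landcover: Grid
    dem: Grid
    roads: list  # [{"geometry": LineString, "class": label}, ...]
    barriers: list
    population: Grid
    facilities: pd.DataFrame
    ea_labels: Grid  # integer EA id per cell
    subcounty_labels: Grid  # integer sub-county id per cell
    ea_centroids: pd.DataFrame  # id, x, y, population, subcounty
    urban_mask: Grid

    @cached_property
    def ea_polygons(self) -> dict[int, shapely.Geometry]:
        """EA polygons as unions of member cell boxes (exact partition)."""
        return _label_polygons(self.ea_labels)

    @cached_property
    def subcounty_polygons(self) -> dict[int, shapely.Geometry]:
        return _label_polygons(self.subcounty_labels)

    @property
    def ea_populations(self) -> pd.Series:
        return self.ea_centroids.set_index("id")["population"]


def _label_polygons(labels: Grid) -> dict:
    lab = np.asarray(labels.data)
    cs = labels.cell_size
    out = {}
    rows, cols = np.nonzero(lab != labels.nodata)
    vals = lab[rows, cols]
    x = labels.x0 + cols * cs
    y = labels.y0 - rows * cs
    boxes = shapely.box(x, y - cs, x + cs, y)
    order = np.argsort(vals, kind="stable")
    vals, boxes = vals[order], boxes[order]
    splits = np.flatnonzero(np.diff(vals)) + 1
    for chunk, v in zip(
        np.split(boxes, splits), vals[np.concatenate(([0], splits))]
    ):
        out[int(v)] = shapely.unary_union(chunk)
    return out


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def _spread_points(rng: np.random.Generator, n: int, nr: int, nc: int, margin: int = 2):
    """n well-spread (row, col) seed points via best-candidate sampling."""
    pts = np.empty((n, 2))
    pts[0] = (rng.uniform(margin, nr - margin), rng.uniform(margin, nc - margin))
    for i in range(1, n):
        cand = np.column_stack(
            [rng.uniform(margin, nr - margin, 8), rng.uniform(margin, nc - margin, 8)]
        )
        d = cKDTree(pts[:i]).query(cand)[0]
        pts[i] = cand[np.argmax(d)]
    return pts


def generate_county(scenario: CountyScenario) -> CountyBundle:
    """Generate a fully synthetic county; deterministic given the scenario."""
    rng = np.random.default_rng(scenario.seed)
    nr, nc = scenario.grid_shape
    cs = scenario.cell_size
    geo = dict(x0=0.0, y0=nr * cs, cell_size=cs)

    # --- terrain: gentle relief plus one protected mountain massif ---------
    relief = _smooth_field(rng, (nr, nc), sigma=max(nr, nc) / 12)
    peak_r = rng.uniform(0.1, 0.3) * nr
    peak_c = rng.uniform(0.6, 0.9) * nc
    rr, cc = np.mgrid[0:nr, 0:nc]
    d2 = ((rr - peak_r) ** 2 + (cc - peak_c) ** 2) / (0.12 * max(nr, nc)) ** 2
    mountain = np.exp(-d2)
    elev = 1198.0 + 900.0 * relief + 3100.0 * mountain
    dem = Grid(elev, **geo)

    # --- towns and urban built-up clusters ---------------------------------
    n_towns = max(1, scenario.n_subcounties // 4)
    towns = _spread_points(rng, n_towns, nr, nc, margin=max(4, nr // 10))
    # keep towns off the mountain
    towns = np.array(
        [t if mountain[int(t[0]), int(t[1])] < 0.3 else (nr - t[0], nc - t[1]) for t in towns]
    )
    urban = np.zeros((nr, nc), dtype=bool)
    radius = max(3.0, 0.05 * max(nr, nc))
    for tr, tc in towns:
        urban |= (rr - tr) ** 2 + (cc - tc) ** 2 <= radius**2

    # --- land cover: 6 classes ---------------------------------------------
    veg = _smooth_field(rng, (nr, nc), sigma=max(nr, nc) / 20)
    dry = _smooth_field(rng, (nr, nc), sigma=max(nr, nc) / 15)
    lc = np.full((nr, nc), LANDCOVER_CLASSES["grassland"], dtype=np.int32)
    lc[veg > 0.75] = LANDCOVER_CLASSES["shrubland"]
    lc[(veg > 0.75) & (elev > np.quantile(elev, 0.8))] = LANDCOVER_CLASSES["tree_cover"]
    lc[mountain > 0.5] = LANDCOVER_CLASSES["tree_cover"]
    lc[dry > 0.85] = LANDCOVER_CLASSES["bare_land"]
    lc[elev < np.quantile(elev, 0.04)] = LANDCOVER_CLASSES["wetland"]
    lc[urban] = LANDCOVER_CLASSES["built_up"]
    # guarantee all six classes are present
    flat_order = np.argsort(elev.ravel())
    for i, code in enumerate(LANDCOVER_CLASSES.values()):
        if not np.any(lc == code):
            lc.ravel()[flat_order[nr * nc // 2 + i]] = code

    landcover = Grid(lc, **geo, nodata=0)

    # --- administrative partition: EAs nested in sub-counties --------------
    sub_seeds = _spread_points(rng, scenario.n_subcounties, nr, nc)
    ea_extra_urban = min(scenario.n_eas // 3, int(urban.sum()))
    n_uniform = scenario.n_eas - ea_extra_urban
    ea_seeds = _spread_points(rng, n_uniform, nr, nc, margin=0)
    if ea_extra_urban:
        urb_cells = np.column_stack(np.nonzero(urban))
        pick = rng.choice(len(urb_cells), size=ea_extra_urban, replace=False)
        ea_seeds = np.vstack([ea_seeds, urb_cells[pick] + rng.uniform(0, 1, (ea_extra_urban, 2))])
    cell_pts = np.column_stack([rr.ravel(), cc.ravel()])
    ea_of_cell = cKDTree(ea_seeds).query(cell_pts)[1].reshape(nr, nc)
    sub_of_ea = cKDTree(sub_seeds).query(ea_seeds)[1]
    sub_of_cell = sub_of_ea[ea_of_cell]
    ea_labels = Grid(ea_of_cell.astype(np.int32), **geo, nodata=-1)
    sub_labels = Grid(sub_of_cell.astype(np.int32), **geo, nodata=-1)

    # --- roads: 7-class hierarchy ------------------------------------------
    def center_xy(r, c):
        return (0.0 + (c + 0.5) * cs, nr * cs - (r + 0.5) * cs)

    roads = []
    town_xy = [center_xy(*t) for t in towns]
    national = town_xy + [(nc * cs, town_xy[-1][1])]
    national = [(0.0, town_xy[0][1])] + national
    roads.append({"geometry": LineString(national), "class": "national_road"})
    town_tree = cKDTree(towns)
    sub_xy = [center_xy(*s) for s in sub_seeds]
    for i, s in enumerate(sub_seeds):
        t = towns[town_tree.query(s)[1]]
        cls = "primary_road" if i % 2 == 0 else "secondary_road"
        roads.append({"geometry": LineString([center_xy(*s), center_xy(*t)]), "class": cls})
    minor_classes = ["minor_road", "government_road", "settlement_road", "rural_road"]
    ea_tree = cKDTree(ea_seeds)
    n_spurs = max(4, scenario.n_eas // 40)
    for i, s in enumerate(sub_seeds):
        _, near = ea_tree.query(s, k=min(n_spurs + 1, len(ea_seeds)))
        for j, ea_idx in enumerate(np.atleast_1d(near)[1:]):
            cls = minor_classes[(i + j) % 4]
            roads.append(
                {"geometry": LineString([center_xy(*s), center_xy(*ea_seeds[ea_idx])]), "class": cls}
            )
    present = {f["class"] for f in roads}
    for miss in set(ROAD_CLASSES) - present:  # guarantee all 7 labels
        a = ea_seeds[rng.integers(len(ea_seeds))]
        b = sub_seeds[rng.integers(len(sub_seeds))]
        roads.append({"geometry": LineString([center_xy(*a), center_xy(*b)]), "class": miss})

    # --- barriers: one river, one protected area over the massif -----------
    ys = np.linspace(0.05 * nr, 0.95 * nr, 9)
    xs = nc * (0.35 + 0.25 * _smooth_field(rng, (9,), 1.2))
    river = LineString([center_xy(r, c) for r, c in zip(ys, xs)])
    barriers = [{"geometry": river, "class": "river"}]
    prot = Point(center_xy(peak_r, peak_c)).buffer(0.1 * max(nr, nc) * cs)
    barriers.append({"geometry": prot, "class": "protected_area"})

    # --- population: dasymetric-style concentration with a rural floor.
    # Settlement follows the road network (people live along roads), with a
    # strong urban boost and a small floor everywhere.
    road_mask = np.zeros((nr, nc), dtype=bool)
    from .cost import rasterize_features

    for m in rasterize_features(roads, landcover).values():
        road_mask |= m
    road_dist = ndimage.distance_transform_edt(~road_mask) * cs  # metres
    near_road = np.exp(-road_dist / 1800.0)
    w = 0.04 + 0.30 * _smooth_field(rng, (nr, nc), sigma=max(nr, nc) / 15)
    w = w * (0.12 + 3.88 * near_road)
    w = w + 8.0 * urban
    pop = scenario.total_population * w / w.sum()
    population = Grid(pop, **geo)

    # --- facilities ---------------------------------------------------------
    facilities = _make_facilities(scenario, rng, landcover, roads, urban, population)

    ea_ids = np.arange(len(ea_seeds))
    sums = np.bincount(ea_of_cell.ravel(), weights=pop.ravel(), minlength=len(ea_seeds))
    counts = np.bincount(ea_of_cell.ravel(), minlength=len(ea_seeds)).astype(float)
    denom = np.where(counts == 0, 1.0, counts)
    cx = np.bincount(ea_of_cell.ravel(), weights=(0.0 + (cc.ravel() + 0.5) * cs), minlength=len(ea_seeds)) / denom
    cy = np.bincount(ea_of_cell.ravel(), weights=(nr * cs - (rr.ravel() + 0.5) * cs), minlength=len(ea_seeds)) / denom
    # an EA seed may capture no cell (dense urban seeding); fall back to the
    # seed location so the centroid stays inside the county
    empty = counts == 0
    if empty.any():
        seed_x = (np.clip(ea_seeds[:, 1], 0, nc - 1) + 0.5) * cs
        seed_y = nr * cs - (np.clip(ea_seeds[:, 0], 0, nr - 1) + 0.5) * cs
        cx[empty] = seed_x[empty]
        cy[empty] = seed_y[empty]
    ea_centroids = pd.DataFrame(
        {"id": ea_ids, "x": cx, "y": cy, "population": sums, "subcounty": sub_of_ea[ea_ids]}
    )

    return CountyBundle(
        scenario=scenario,
        landcover=landcover,
        dem=dem,
        roads=roads,
        barriers=barriers,
        population=population,
        facilities=facilities,
        ea_labels=ea_labels,
        subcounty_labels=sub_labels,
        ea_centroids=ea_centroids,
        urban_mask=Grid(urban.astype(np.int8), **geo),
    )


def _road_cells(roads, template: Grid) -> np.ndarray:
    """(row, col) array of cells crossed by any road line."""
    from .cost import rasterize_features

    masks = rasterize_features(roads, template)
    mask = np.zeros(template.shape, dtype=bool)
    for m in masks.values():
        mask |= m
    return np.column_stack(np.nonzero(mask))


def _make_facilities(scenario, rng, landcover, roads, urban, population) -> pd.DataFrame:
    nr, nc = landcover.shape
    cs = landcover.cell_size
    n = scenario.n_facilities
    n_tr = scenario.n_transfusing

    road_rc = _road_cells(roads, landcover)
    if n_tr > len(road_rc):
        raise InfeasibleScenarioError(
            f"more transfusing facilities ({n_tr}) than road cells ({len(road_rc)})"
        )
    on_urban = urban[road_rc[:, 0], road_rc[:, 1]]
    urban_pool = road_rc[on_urban]
    rural_pool = road_rc[~on_urban]
    n_urban_tr = min(round(scenario.urban_fraction * n_tr), len(urban_pool))
    if scenario.urban_fraction >= 1.0 and len(urban_pool) >= n_tr:
        n_urban_tr = n_tr
    n_rural_tr = n_tr - n_urban_tr
    if n_rural_tr > len(rural_pool):
        n_urban_tr = n_tr - len(rural_pool)
        n_rural_tr = len(rural_pool)
    picks = []
    if n_urban_tr:
        picks.append(urban_pool[rng.choice(len(urban_pool), n_urban_tr, replace=False)])
    if n_rural_tr:
        picks.append(rural_pool[rng.choice(len(rural_pool), n_rural_tr, replace=False)])
    tr_rc = np.vstack(picks)

    # non-transfusing facilities follow population density
    pw = np.asarray(population.data).ravel()
    other_flat = rng.choice(nr * nc, size=n - n_tr, replace=True, p=pw / pw.sum())
    other_rc = np.column_stack(np.unravel_index(other_flat, (nr, nc)))
    rc = np.vstack([tr_rc, other_rc])
    jitter = rng.uniform(0.25, 0.75, size=rc.shape)
    x = (rc[:, 1] + jitter[:, 1]) * cs
    y = nr * cs - (rc[:, 0] + jitter[:, 0]) * cs

    transfusing = np.zeros(n, dtype=bool)
    transfusing[:n_tr] = True
    # levels: ~81% dispensaries (level 2, never transfusing); one level-4 referral
    level = np.full(n, 2, dtype=int)
    n_hosp = max(n_tr, round(0.19 * n))
    level[:n_hosp] = 3
    level[0] = 4
    in_urban = urban[rc[:, 0], rc[:, 1]]

    beds = np.zeros(n, dtype=int)
    hosp = level >= 3
    base = rng.lognormal(mean=np.log(40.0), sigma=0.6, size=n)
    base[in_urban] *= 2.5
    beds[hosp] = np.clip(np.round(base[hosp]), 10, 250).astype(int)
    beds[~hosp] = rng.integers(0, 8, size=(~hosp).sum())

    # total inpatient admissions over the 4-year reporting window
    # (~150 admissions per bed-year, log-normal facility effect)
    admissions = np.zeros(n, dtype=int)
    admissions[hosp] = np.round(
        beds[hosp] * 600.0 * np.exp(rng.normal(0.0, 0.3, hosp.sum()))
    ).astype(int)

    units_received = np.zeros(n, dtype=int)
    eps = rng.normal(0.0, scenario.blood_noise_sd, n)
    units_received[transfusing] = np.maximum(
        1,
        np.round(
            scenario.blood_units_per_bed * beds[transfusing] * np.exp(eps[transfusing])
        ).astype(int),
    )
    units_transfused = np.zeros(n, dtype=int)
    units_transfused[transfusing] = np.maximum(
        1,
        np.round(
            units_received[transfusing] * rng.uniform(1.0, 1.6, transfusing.sum())
        ).astype(int),
    )

    authority = rng.choice(
        ["ministry_of_health", "mission_ngo", "private"], size=n, p=[0.57, 0.11, 0.32]
    )
    return pd.DataFrame(
        {
            "id": [f"F{i:03d}" for i in range(n)],
            "name": [f"Facility {i:03d}" for i in range(n)],
            "x": x,
            "y": y,
            "level": level,
            "managing_authority": authority,
            "transfusing": transfusing,
            "beds": beds,
            "admissions": admissions,
            "units_received": units_received,
            "units_transfused": units_transfused,
        }
    )


def adjust_population(
    pop: Grid, census_total: float, growth_rate: float, years: int
) -> Grid:
    """Match a population grid to a census total and project it forward.

    The grid is rescaled by a single scalar so that it sums to
    ``census_total * (1 + growth_rate) ** years``; the spatial pattern is
    untouched (intercensal-projection convention).
    """
    if growth_rate <= -1:
        raise ValueError("growth_rate must exceed -1")
    data = np.asarray(pop.data, dtype=float)
    total = data.sum()
    if total <= 0:
        raise ValueError("population grid sums to zero; cannot rescale")
    target = census_total * (1.0 + growth_rate) ** years
    return pop.copy_with(data * (target / total))


_TABLE1_RESOURCE = "bungoma_transfusing_facilities.csv"


def load_table1() -> pd.DataFrame:
    """The packaged table of the 15 transfusing hospitals of Bungoma County.

    Columns: facility, beds, competing_transfusing (count of alternative
    transfusing hospitals in the 1-h catchment), low_level (non-transfusing
    level-3/4 facilities in the catchment), units_received, units_transfused
    (blood units, 2018-2021), market_share_pct and sci (the published
    competition metrics, treated as given data). Transcribed once from the
    published table; the received/transfused columns sum to 16,662 and
    22,843 and the market shares to 100.
    """
    ref = importlib.resources.files("bloodaccess") / "data" / _TABLE1_RESOURCE
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
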