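"""Least-cost travel time over the merged cost surface.

Cells are nodes of an 8-connected graph; the directed edge time from cell a
to cell b is the center-to-center distance times the mean of the two cells'
time-per-metre, where a walking cell's time-per-metre is corrected for the
signed slope of the move (Tobler, normalised) and motorised cells ignore
slope. Travel times to the nearest facility are exact single-source-set
shortest paths (Dijkstra on a sparse graph), reported in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .cost import MergedCostGrid, tobler_factor
from .grid import Grid

__all__ = [
    "CostGraph",
    "build_cost_graph",
    "accumulate_cost",
    "od_matrix",
    "catchment_population",
    "UNREACHABLE",
]

UNREACHABLE = np.inf

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CostGraph:
    """Sparse directed travel-time graph over traversable cells.

    ``transpose`` holds edge times reversed so that Dijkstra from facility
    nodes yields the time *to* the facility along forward edges (the two
    differ only where walking slope makes edges asymmetric).
    """

    grid: Grid  # geometry template (speed grid)
    node_of_cell: np.ndarray  # flat cell index -> node id, -1 if not traversable
    cell_of_node: np.ndarray  # node id -> flat cell index
    transpose: "coo_matrix"

    def node_at(self, x, y) -> np.ndarray:
        row, col = self.grid.index_of(x, y)
        flat = row * self.grid.shape[1] + col
        return self.node_of_cell[flat]


def build_cost_graph(cost: MergedCostGrid, dem: Grid | None = None) -> CostGraph:
    """Assemble the 8-connected directed graph of per-move travel minutes."""
    if cost.speed is None:
        raise ValueError("cost grid has no speeds; run assign_speeds first")
    speed = np.asarray(cost.speed.data, dtype=float)
    mode = np.asarray(cost.mode.data) if cost.mode is not None else np.ones_like(speed)
    if dem is not None and not cost.speed.same_geometry(dem):
        raise ValueError("DEM does not share the cost grid geometry")
    elev = np.asarray(dem.data, dtype=float) if dem is not None else None

    nr, nc = speed.shape
    traversable = speed > 0
    node_of_cell = np.full(nr * nc, -1, dtype=np.int64)
    cells = np.flatnonzero(traversable.ravel())
    node_of_cell[cells] = np.arange(cells.size)
    n_nodes = cells.size

    cell_m = cost.cell_size
    # minutes per metre on each cell at base speed: 60 / (1000 * v_kmh)
    base_tpm = np.where(traversable, 0.06 / np.where(traversable, speed, 1.0), np.nan)

    src_list, dst_list, w_list = [], [], []
    rows, cols = np.nonzero(traversable)
    for dr, dc in _OFFSETS:
        r2 = rows + dr
        c2 = cols + dc
        ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
        r1, c1 = rows[ok], cols[ok]
        r2, c2 = r2[ok], c2[ok]
        ok2 = traversable[r2, c2]
        r1, c1, r2, c2 = r1[ok2], c1[ok2], r2[ok2], c2[ok2]
        if r1.size == 0:
            continue
        dist = cell_m * (np.sqrt(2.0) if dr and dc else 1.0)
        tpm_a = base_tpm[r1, c1].copy()
        tpm_b = base_tpm[r2, c2].copy()
        if elev is not None:
            s = (elev[r2, c2] - elev[r1, c1]) / dist
            factor = tobler_factor(s)
            walk_a = mode[r1, c1] == 1
            walk_b = mode[r2, c2] == 1
            tpm_a[walk_a] /= factor[walk_a]
            tpm_b[walk_b] /= factor[walk_b]
        w = dist * 0.5 * (tpm_a + tpm_b)
        src_list.append(node_of_cell[r1 * nc + c1])
        dst_list.append(node_of_cell[r2 * nc + c2])
        w_list.append(w)

    src = np.concatenate(src_list) if src_list else np.empty(0, dtype=np.int64)
    dst = np.concatenate(dst_list) if dst_list else np.empty(0, dtype=np.int64)
    w = np.concatenate(w_list) if w_list else np.empty(0)
    transpose = coo_matrix((w, (dst, src)), shape=(n_nodes, n_nodes)).tocsr()
    return CostGraph(
        grid=cost.speed,
        node_of_cell=node_of_cell,
        cell_of_node=cells,
        transpose=transpose,
    )


def _origin_nodes(graph: CostGraph, origins: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Map origin facilities (x, y) to graph nodes, failing on impassable cells."""
    if isinstance(origins, pd.DataFrame):
        xs = origins["x"].to_numpy(float)
        ys = origins["y"].to_numpy(float)
        ids = origins["id"].tolist() if "id" in origins else list(origins.index)
    else:
        pts = np.atleast_2d(np.asarray(origins, dtype=float))
        xs, ys = pts[:, 0], pts[:, 1]
        ids = list(range(len(xs)))
    if len(xs) == 0:
        raise ValueError("empty origin set")
    nodes = graph.node_at(xs, ys)
    bad = np.flatnonzero(nodes < 0)
    if bad.size:
        raise ValueError(
            f"origin(s) on impassable cells: {[ids[i] for i in bad.tolist()]}"
        )
    return nodes


def _times_from_nodes(graph: CostGraph, nodes: np.ndarray) -> np.ndarray:
    """Minutes from every traversable node to the nearest of ``nodes``."""
    return dijkstra(graph.transpose, directed=True, indices=nodes, min_only=True)


def accumulate_cost(
    cost: MergedCostGrid,
    origins,
    dem: Grid | None = None,
    graph: CostGraph | None = None,
) -> Grid:
    """Travel-time raster (minutes to the nearest origin facility).

    Unreachable and impassable cells are nodata; origin cells are exactly 0.
    """
    graph = graph or build_cost_graph(cost, dem)
    nodes = _origin_nodes(graph, origins)
    times = _times_from_nodes(graph, nodes)
    nr, nc = graph.grid.shape
    out = np.full(nr * nc, np.nan)
    out[graph.cell_of_node] = np.where(np.isinf(times), np.nan, times)
    tt = graph.grid.copy_with(out.reshape(nr, nc))
    tt.nodata = -9999.0
    return tt


def od_matrix(
    cost: MergedCostGrid,
    facilities: pd.DataFrame,
    ea_centroids: pd.DataFrame,
    dem: Grid | None = None,
    graph: CostGraph | None = None,
) -> pd.DataFrame:
    """Origin-destination travel-time matrix T_ij in minutes.

    Rows are EA centroids (index = ea id), columns are facilities (facility
    id); each column is the facility's single-origin accumulation sampled at
    the centroids. Centroids on impassable/nodata cells get +inf (flagged
    unreachable, never dropped).
    """
    graph = graph or build_cost_graph(cost, dem)
    fac_nodes = _origin_nodes(graph, facilities)
    ex = ea_centroids["x"].to_numpy(float)
    ey = ea_centroids["y"].to_numpy(float)
    ea_nodes = graph.node_at(ex, ey)
    fac_ids = facilities["id"].tolist() if "id" in facilities else list(facilities.index)
    ea_ids = ea_centroids["id"].tolist() if "id" in ea_centroids else list(ea_centroids.index)

    T = np.full((len(ea_ids), len(fac_ids)), UNREACHABLE)
    reach = ea_nodes >= 0
    for j, node in enumerate(fac_nodes):
        times = _times_from_nodes(graph, np.array([node]))
        T[reach, j] = times[ea_nodes[reach]]
    return pd.DataFrame(T, index=pd.Index(ea_ids, name="ea_id"), columns=fac_ids)


def catchment_population(
    tt: Grid,
    pop: Grid,
    zones: Grid,
    bands: list[float] = (30.0, 60.0),
) -> pd.DataFrame:
    """Persons per zone per travel-time band, plus a county total row.

    ``zones`` is an integer zone-label grid (nodata outside the county).
    Bands ``[30, 60]`` produce persons within (0, 30], (30, 60] and beyond 60
    minutes; cells with no finite travel time (unreachable or impassable)
    count in the open last band, i.e. as marginalised. Bands partition each
    zone's population exactly.
    """
    bands = list(bands)
    if any(b2 <= b1 for b1, b2 in zip(bands, bands[1:])) or not bands:
        raise ValueError("bands must be a non-empty strictly increasing sequence")
    if not (tt.same_geometry(pop) and tt.same_geometry(zones)):
        raise ValueError("travel time, population and zone grids are misaligned")

    t = np.asarray(tt.data, dtype=float).ravel()
    p = np.asarray(pop.data, dtype=float).ravel()
    z = np.asarray(zones.data).ravel()
    valid = (z != zones.nodata) & (p > 0)

    edges = [0.0] + bands
    labels = [f"within_{int(b)}min" if b == int(b) else f"within_{b}min" for b in bands]
    labels.append(f"beyond_{int(bands[-1])}min" if bands[-1] == int(bands[-1]) else f"beyond_{bands[-1]}min")

    zone_ids = sorted(int(v) for v in np.unique(z[valid]))
    table = pd.DataFrame(0.0, index=pd.Index(zone_ids + ["county"], name="zone"), columns=labels)
    tv = t[valid]
    pv = p[valid]
    zv = z[valid]
    finite = np.isfinite(tv)
    band_idx = np.full(tv.shape, len(bands))  # default: beyond last band
    band_idx[finite] = np.searchsorted(np.asarray(bands), tv[finite], side="left")
    # searchsorted gives 0 for t <= bands[0] (left side: t < b -> 0; t == b -> 0)
    band_idx[finite & (tv > bands[-1])] = len(bands)
    for zi in zone_ids:
        sel = zv == zi
        for b in range(len(labels)):
            table.loc[zi, labels[b]] = pv[sel & (band_idx == b)].sum()
    table.loc["county"] = table.iloc[:-1].sum(axis=0)
    table["total"] = table.sum(axis=1)
    return table
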