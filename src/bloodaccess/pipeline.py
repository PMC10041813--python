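"""End-to-end orchestration: simulate, friction, travel time, 3-SFCA,
competition, validation.

Each stage reads the standard-format artifacts of the previous one from the
run directory and writes its own, so the stages compose exactly like the
single :func:`run_pipeline` call. Runs are deterministic given the config:
re-running with the same config reproduces identical artifact files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .accessibility import FloatingCatchmentModel, compare_marginalization
from .competition import SpatialCompetitionModel
from .config import RunConfig
from .cost import MergedCostGrid, assign_speeds, merge_layers
from .grid import Grid, read_ascii_grid, write_ascii_grid
from .synthetic import generate_county, load_table1
from .traveltime import accumulate_cost, build_cost_graph, catchment_population, od_matrix
from .validation import pearson_validate

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_friction",
    "stage_traveltime",
    "stage_fca",
    "stage_compete",
    "stage_validate",
]

log = logging.getLogger("bloodaccess")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_inputs(stage: str, paths) -> None:
    for p in paths:
        p = Path(p)
        if p.exists():
            log.info("%s: input %s sha256=%s", stage, p.name, _checksum(p))


def _csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate the synthetic county and write its layers."""
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_county(config.scenario)
    write_ascii_grid(bundle.landcover, outdir / "landcover.asc")
    write_ascii_grid(bundle.dem, outdir / "dem.asc")
    write_ascii_grid(bundle.population, outdir / "population.asc")
    write_ascii_grid(bundle.ea_labels, outdir / "ea_labels.asc")
    write_ascii_grid(bundle.subcounty_labels, outdir / "subcounty_labels.asc")
    write_ascii_grid(bundle.urban_mask, outdir / "urban_mask.asc")
    gio.write_geojson(bundle.roads, outdir / "roads.geojson")
    gio.write_geojson(bundle.barriers, outdir / "barriers.geojson")
    _csv(bundle.facilities, outdir / "facilities.csv", index=False)
    _csv(bundle.ea_centroids, outdir / "ea_centroids.csv", index=False)
    log.info("simulate: %d facilities, %d EAs", len(bundle.facilities), len(bundle.ea_centroids))


def stage_friction(config: RunConfig, outdir: Path) -> MergedCostGrid:
    """Merge land cover, roads and barriers; assign scenario speeds."""
    paths = [outdir / "landcover.asc", outdir / "roads.geojson", outdir / "barriers.geojson"]
    _log_inputs("friction", paths)
    try:
        landcover = read_ascii_grid(paths[0])
        roads = gio.read_geojson(paths[1])
        barriers = gio.read_geojson(paths[2])
    except FileNotFoundError as e:
        raise StageError(f"friction: missing input {e.filename}") from e
    merged = merge_layers(landcover, roads, barriers)
    merged = assign_speeds(merged, config.travel)
    write_ascii_grid(merged.class_grid, outdir / "merged_classes.asc")
    write_ascii_grid(merged.speed, outdir / "speed.asc")
    write_ascii_grid(merged.mode, outdir / "mode.asc")
    return merged


def _load_cost(outdir: Path) -> MergedCostGrid:
    cls = read_ascii_grid(outdir / "merged_classes.asc")
    speed = read_ascii_grid(outdir / "speed.asc")
    mode = read_ascii_grid(outdir / "mode.asc")
    return MergedCostGrid(class_grid=cls, speed=speed, mode=mode)


def stage_traveltime(config: RunConfig, outdir: Path) -> None:
    """Joint travel-time raster, EA and facility OD matrices, zonal bands."""
    _log_inputs("traveltime", [outdir / "speed.asc", outdir / "facilities.csv"])
    cost = _load_cost(outdir)
    dem = read_ascii_grid(outdir / "dem.asc")
    facilities = pd.read_csv(outdir / "facilities.csv")
    eas = pd.read_csv(outdir / "ea_centroids.csv")
    trans = facilities[facilities["transfusing"]]
    if trans.empty:
        raise StageError("traveltime: no transfusing facilities in register")
    graph = build_cost_graph(cost, dem)
    tt = accumulate_cost(cost, trans, dem, graph=graph)
    write_ascii_grid(tt, outdir / "travel_time.asc")
    T = od_matrix(cost, trans, eas, dem, graph=graph)
    _csv(T, outdir / "od_matrix.csv")
    hosp = facilities[facilities["level"] >= 3]
    fac_T = od_matrix(cost, trans, hosp.rename(columns={"id": "id"}), dem, graph=graph)
    _csv(fac_T, outdir / "fac_od_matrix.csv")
    pop = read_ascii_grid(outdir / "population.asc")
    zones = read_ascii_grid(outdir / "subcounty_labels.asc")
    zonal = catchment_population(tt, pop, zones, config.bands)
    _csv(zonal, outdir / "catchment_population.csv")


def stage_fca(config: RunConfig, outdir: Path) -> None:
    """3-SFCA accessibility per EA plus sub-county aggregation."""
    _log_inputs("fca", [outdir / "od_matrix.csv", outdir / "ea_centroids.csv"])
    T = pd.read_csv(outdir / "od_matrix.csv", index_col="ea_id")
    eas = pd.read_csv(outdir / "ea_centroids.csv").set_index("id")
    facilities = pd.read_csv(outdir / "facilities.csv").set_index("id")
    supply = facilities.loc[T.columns, "admissions"].astype(float)
    model = FloatingCatchmentModel(
        travel_time=T,
        population=eas["population"],
        supply=supply,
        decay=config.decay,
    )
    res = model.fit(class_mode=config.class_mode, thresholds=config.class_thresholds)
    out = res.to_frame()
    out["subcounty"] = eas["subcounty"]
    _csv(out, outdir / "spai.csv", index_label="ea_id")
    agg = res.aggregate(eas["subcounty"])
    _csv(agg, outdir / "subcounty_spai.csv")
    # marginalisation comparison: beyond-1h persons vs low-SPAI persons
    zonal = pd.read_csv(outdir / "catchment_population.csv", index_col="zone")
    beyond_col = [c for c in zonal.columns if c.startswith("beyond_")][0]
    tt_marg = zonal[beyond_col].drop("county").astype(float)
    tt_marg.index = tt_marg.index.astype(int)
    low = res.classes == "low"
    spai_low = eas.loc[low[low].index, ["subcounty", "population"]].groupby("subcounty")["population"].sum()
    comp = compare_marginalization(tt_marg, spai_low)
    _csv(comp, outdir / "marginalization.csv")
    (outdir / "accessibility_summary.txt").write_text(res.summary() + "\n")


def stage_compete(config: RunConfig, outdir: Path) -> None:
    """Spatial competition index and market shares."""
    _log_inputs("compete", [outdir / "fac_od_matrix.csv"])
    fac_T = pd.read_csv(outdir / "fac_od_matrix.csv", index_col="ea_id")
    fac_T.index.name = "id"
    facilities = pd.read_csv(outdir / "facilities.csv")
    model = SpatialCompetitionModel(
        facilities, fac_T,
        threshold=config.t_max,
        variant=config.sci_variant,
        share_basis=config.share_basis,
    )
    res = model.fit()
    _csv(res.table, outdir / "competition.csv")
    (outdir / "competition_summary.txt").write_text(res.summary() + "\n")


def stage_validate(config: RunConfig, outdir: Path, fixture: str | None = None) -> pd.DataFrame:
    """Correlate SCI against blood-unit volumes (synthetic run or fixture)."""
    if fixture == "table1":
        table = load_table1().rename(columns={"facility": "id"}).set_index("id")
    else:
        _log_inputs("validate", [outdir / "competition.csv"])
        table = pd.read_csv(outdir / "competition.csv", index_col="facility")
    rows = []
    for col in ("units_received", "units_transfused"):
        res = pearson_validate(table["sci"], table[col])
        rows.append(
            {
                "variable": col,
                "r": res.r,
                "n": res.n,
                "t": res.t,
                "p": res.p,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
            }
        )
    report = pd.DataFrame(rows).set_index("variable")
    outdir.mkdir(parents=True, exist_ok=True)
    _csv(report, outdir / "validation.csv")
    text = "\n\n".join(
        f"SCI vs {row.Index}:\n"
        + pearson_validate(table["sci"], table[row.Index]).summary()
        for row in report.itertuples()
    )
    (outdir / "validation.txt").write_text(text + "\n")
    return report


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.save(outdir / "resolved_config.yaml")
        for name, stage in (
            ("simulate", stage_simulate),
            ("friction", stage_friction),
            ("traveltime", stage_traveltime),
            ("fca", stage_fca),
            ("compete", stage_compete),
            ("validate", stage_validate),
        ):
            log.info("stage %s: start", name)
            try:
                stage(config, outdir)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - abort names the stage
                raise StageError(f"stage {name} failed: {e}") from e
            log.info("stage %s: done", name)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
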