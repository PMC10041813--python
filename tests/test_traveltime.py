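import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bloodaccess import (
    Grid,
    TravelScenario,
    accumulate_cost,
    assign_speeds,
    build_cost_graph,
    catchment_population,
    merge_layers,
    od_matrix,
)
from conftest import make_cost
from oracles import (
    enumerate_simple_path_times,
    naive_band_tally,
    value_iteration_times,
)


def _origin_df(cost, rc_list):
    g = cost.speed
    rows = np.array([r for r, _ in rc_list])
    cols = np.array([c for _, c in rc_list])
    x, y = g.cell_center(rows, cols)
    return pd.DataFrame({"id": [f"O{i}" for i in range(len(rc_list))], "x": x, "y": y})


def test_uniform_line_closed_form():
    cost = make_cost([[6.0, 6.0, 6.0]])  # 6 km/h = 100 m/min on 100 m cells
    tt = accumulate_cost(cost, _origin_df(cost, [(0, 0)]))
    np.testing.assert_allclose(tt.data, [[0.0, 1.0, 2.0]], atol=1e-12)


def test_diagonal_move_uses_sqrt2_distance():
    cost = make_cost([[6.0, 6.0], [6.0, 6.0]])
    tt = accumulate_cost(cost, _origin_df(cost, [(0, 0)]))
    assert tt.data[1, 1] == pytest.approx(math.sqrt(2.0), rel=1e-12)


def test_origin_on_impassable_cell_is_named():
    cost = make_cost([[4.0, 0.0]])
    with pytest.raises(ValueError, match="O0"):
        accumulate_cost(cost, _origin_df(cost, [(0, 1)]))
    with pytest.raises(ValueError, match="empty origin"):
        accumulate_cost(cost, pd.DataFrame({"id": [], "x": [], "y": []}))


def test_value_iteration_oracle_agrees_with_exhaustive_paths():
    # validates the oracle itself on a grid small enough to enumerate
    rng = np.random.default_rng(11)
    speed = rng.choice([2.0, 4.0, 30.0], size=(2, 3))
    exhaustive = enumerate_simple_path_times(speed.tolist(), (0, 0), 100.0)
    fixpoint = value_iteration_times(speed.tolist(), [(0, 0)], 100.0)
    np.testing.assert_allclose(fixpoint, exhaustive, rtol=1e-12)


@given(st.data())
def test_dijkstra_matches_bruteforce_on_small_grids(data):
    nr = data.draw(st.integers(2, 5), label="rows")
    nc = data.draw(st.integers(2, 5), label="cols")
    vals = data.draw(
        st.lists(
            st.sampled_from([0.0, 1.0, 4.0, 30.0, 80.0]),
            min_size=nr * nc, max_size=nr * nc,
        ),
        label="speeds",
    )
    speed = np.array(vals).reshape(nr, nc)
    open_cells = np.argwhere(speed > 0)
    if len(open_cells) == 0:
        return
    origin = tuple(open_cells[data.draw(st.integers(0, len(open_cells) - 1))])
    cost = make_cost(speed)
    tt = accumulate_cost(cost, _origin_df(cost, [origin]))
    oracle = value_iteration_times(speed.tolist(), [origin], 100.0)
    got = np.where(np.isnan(tt.data), np.inf, tt.data)
    got[speed <= 0] = np.inf
    np.testing.assert_allclose(got, oracle, rtol=1e-9, atol=1e-9)


def test_walking_slope_is_direction_aware():
    speed = np.array([[4.0, 4.0]])
    cost = make_cost(speed)
    dem = cost.speed.copy_with(np.array([[0.0, 10.0]]))  # 10 m rise over 100 m
    down = accumulate_cost(cost, _origin_df(cost, [(0, 0)]), dem=dem)
    up = accumulate_cost(cost, _origin_df(cost, [(0, 1)]), dem=dem)
    assert up.data[0, 1] == 0.0 and down.data[0, 0] == 0.0
    # walking towards the raised origin is slower than the flat case and
    # slower than coming back down
    flat = accumulate_cost(cost, _origin_df(cost, [(0, 1)]))
    assert up.data[0, 0] > flat.data[0, 0]
    assert up.data[0, 0] > down.data[0, 1]


def test_motorised_cells_ignore_slope():
    speed = np.array([[50.0, 50.0]])
    cost = make_cost(speed, modes=np.array([[3, 3]]))
    dem = cost.speed.copy_with(np.array([[0.0, 25.0]]))
    with_dem = accumulate_cost(cost, _origin_df(cost, [(0, 0)]), dem=dem)
    without = accumulate_cost(cost, _origin_df(cost, [(0, 0)]))
    np.testing.assert_allclose(with_dem.data, without.data, rtol=1e-12)


def test_doubling_speeds_halves_times():
    rng = np.random.default_rng(5)
    speed = rng.choice([2.0, 4.0, 30.0], size=(6, 6))
    c1 = make_cost(speed)
    c2 = make_cost(speed * 2.0)
    t1 = accumulate_cost(c1, _origin_df(c1, [(0, 0)]))
    t2 = accumulate_cost(c2, _origin_df(c2, [(0, 0)]))
    np.testing.assert_allclose(t2.data, t1.data / 2.0, rtol=1e-12)


def test_adding_an_origin_never_increases_times():
    rng = np.random.default_rng(6)
    speed = rng.choice([2.0, 4.0, 30.0], size=(8, 8))
    cost = make_cost(speed)
    one = accumulate_cost(cost, _origin_df(cost, [(0, 0)]))
    two = accumulate_cost(cost, _origin_df(cost, [(0, 0), (7, 7)]))
    assert np.all(two.data <= one.data + 1e-12)


def test_joint_raster_is_min_of_single_origin_rasters():
    rng = np.random.default_rng(7)
    speed = rng.choice([2.0, 4.0, 30.0, 80.0], size=(10, 10))
    speed[3, :7] = 0.0
    cost = make_cost(speed)
    origins = [(0, 0), (9, 9), (5, 2)]
    singles = [accumulate_cost(cost, _origin_df(cost, [o])).data for o in origins]
    joint = accumulate_cost(cost, _origin_df(cost, origins)).data
    stacked = np.where(np.isnan(singles), np.inf, singles).min(axis=0)
    np.testing.assert_allclose(
        np.where(np.isnan(joint), np.inf, joint), stacked, rtol=1e-9
    )


def test_od_matrix_consistency_contracts(small_bundle, small_cost, small_graph):
    trans = small_bundle.facilities[small_bundle.facilities["transfusing"]]
    T = od_matrix(small_cost, trans, small_bundle.ea_centroids,
                  small_bundle.dem, graph=small_graph)
    assert T.shape == (len(small_bundle.ea_centroids), len(trans))
    assert (T.to_numpy()[np.isfinite(T.to_numpy())] >= 0).all()
    joint = accumulate_cost(small_cost, trans, small_bundle.dem, graph=small_graph)
    sampled = joint.sample(small_bundle.ea_centroids["x"].to_numpy(),
                           small_bundle.ea_centroids["y"].to_numpy())
    sampled = np.where(np.isnan(sampled), np.inf, sampled)
    np.testing.assert_allclose(T.min(axis=1).to_numpy(), sampled, rtol=1e-9, atol=1e-9)


def test_facility_centroid_zero_time():
    cost = make_cost(np.full((4, 4), 6.0))
    fac = _origin_df(cost, [(2, 2)])
    eas = fac.rename(columns={"id": "id"}).assign(id=["E0"])
    T = od_matrix(cost, fac, eas)
    assert T.iloc[0, 0] == 0.0


def test_zonal_bands_partition_population():
    nr = nc = 12
    rng = np.random.default_rng(9)
    tt = Grid(rng.uniform(0, 90, (nr, nc)), y0=nr * 100.0)
    tt.data[0, :4] = np.nan  # unreachable cells count as marginalised
    pop = Grid(rng.uniform(0, 50, (nr, nc)), y0=nr * 100.0)
    zones = Grid(np.repeat(np.arange(3), nr * nc // 3).reshape(nr, nc), y0=nr * 100.0, nodata=-1)
    table = catchment_population(tt, pop, zones, [30, 60])
    oracle = naive_band_tally(tt.data, pop.data, zones.data, [30, 60], -1)
    labels = ["within_30min", "within_60min", "beyond_60min"]
    for (z, b), persons in oracle.items():
        assert table.loc[z, labels[b]] == pytest.approx(persons, rel=1e-9)
    np.testing.assert_allclose(
        table["total"].drop("county"),
        [pop.data[zones.data == z].sum() for z in range(3)], rtol=1e-9,
    )
    assert table.loc["county", "total"] == pytest.approx(pop.data.sum(), rel=1e-9)
    # threshold nesting: within 30 never exceeds within 60
    cum30 = table["within_30min"]
    cum60 = cum30 + table["within_60min"]
    assert (cum30 <= cum60 + 1e-12).all()


def test_zonal_rejects_bad_inputs():
    tt = Grid(np.zeros((4, 4)), y0=400.0)
    pop = Grid(np.ones((5, 4)), y0=500.0)
    zones = Grid(np.zeros((4, 4)), y0=400.0, nodata=-1)
    with pytest.raises(ValueError, match="misaligned"):
        catchment_population(tt, pop, zones, [30, 60])
    with pytest.raises(ValueError, match="increasing"):
        catchment_population(tt, Grid(np.ones((4, 4)), y0=400.0), zones, [60, 30])
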