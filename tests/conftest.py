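import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bloodaccess import (
    CountyScenario,
    Grid,
    MergedCostGrid,
    TravelScenario,
    assign_speeds,
    build_cost_graph,
    generate_county,
    merge_layers,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")


def make_cost(speeds, cell_size=100.0, modes=None) -> MergedCostGrid:
    """Cost grid straight from a speed array (km/h; 0 = impassable)."""
    speeds = np.asarray(speeds, dtype=float)
    cls = Grid(np.where(speeds > 0, 4, 21).astype(np.int32), cell_size=cell_size,
               y0=speeds.shape[0] * cell_size, nodata=0)
    if modes is None:
        modes = np.where(speeds > 0, 1, 0)
    return MergedCostGrid(
        class_grid=cls,
        speed=cls.copy_with(speeds),
        mode=cls.copy_with(np.asarray(modes, dtype=np.int8)),
    )


SMALL = CountyScenario(
    seed=7,
    grid_shape=(60, 60),
    cell_size=300.0,
    n_subcounties=4,
    n_facilities=40,
    n_transfusing=5,
    n_eas=120,
    total_population=150_000.0,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_county(SMALL)


@pytest.fixture(scope="session")
def small_cost(small_bundle):
    merged = merge_layers(small_bundle.landcover, small_bundle.roads, small_bundle.barriers)
    return assign_speeds(merged, TravelScenario.default())


@pytest.fixture(scope="session")
def small_graph(small_bundle, small_cost):
    return build_cost_graph(small_cost, small_bundle.dem)
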