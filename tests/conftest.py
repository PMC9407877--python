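import numpy as np
import pytest

from eslines.grids import GridSpec
from eslines.synthgen import ForcingStack, LandUseMap, ZoneMap


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=20, cell_size=250.0)


def make_soil(shape, sand=40.0, silt=35.0, clay=25.0, oc=1.0):
    return {
        "sand": np.full(shape, sand),
        "silt": np.full(shape, silt),
        "clay": np.full(shape, clay),
        "oc": np.full(shape, oc),
    }


def make_forcing(
    grid: GridSpec,
    year: int = 2000,
    ppt: float | np.ndarray = 750.0,
    tem: float | np.ndarray = 12.0,
    sol: float | np.ndarray = 45.0,
    ndvi: float | np.ndarray = 0.6,
    dem: np.ndarray | None = None,
    soil: dict | None = None,
    ppt_monthly: np.ndarray | None = None,
) -> ForcingStack:
    """Hand-built forcing stack with uniform monthly decomposition."""
    shape = grid.shape

    def full(v):
        return np.full(shape, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)

    ppt_r = full(ppt)
    if ppt_monthly is None:
        ppt_monthly = np.repeat(ppt_r[None, :, :] / 12.0, 12, axis=0)
    sol_r = full(sol)
    return ForcingStack(
        year=year,
        grid=grid,
        ppt=ppt_r,
        ppt_monthly=ppt_monthly,
        tem=full(tem),
        sol=np.repeat(sol_r[None, :, :], 12, axis=0),
        ndvi=full(ndvi),
        dem=dem if dem is not None else np.zeros(shape),
        soil=soil or make_soil(shape),
        pop=np.full(shape, 10.0),
        gdp=np.full(shape, 1000.0),
    )


@pytest.fixture
def cropland_map(grid) -> LandUseMap:
    return LandUseMap(grid=grid, classes=np.ones(grid.shape, dtype=np.int16))


def make_landuse(grid: GridSpec, classes: np.ndarray) -> LandUseMap:
    return LandUseMap(grid=grid, classes=np.asarray(classes, dtype=np.int16))


def make_zones(grid: GridSpec, zones: np.ndarray, yields: dict[int, float]) -> ZoneMap:
    return ZoneMap(grid=grid, zones=np.asarray(zones), yield_table=yields)
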