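import numpy as np
import pytest

from conftest import make_forcing, make_landuse, make_soil, make_zones
from eslines.errors import IncompleteForcingError, InvalidInputError
from eslines.esmodels import (
    CasaParams,
    RusleFactors,
    RusleParams,
    WaterYieldParams,
    budyko_aet_ratio,
    compute_fp,
    compute_npp,
    compute_rusle_factors,
    compute_sc,
    compute_wy,
    ls_factor,
    monthly_npp,
    rainfall_erosivity,
)


class TestNPP:
    def test_single_month_direct_product(self):
        # APAR 100 MJ m-2 at eps 0.5 g C MJ-1 -> 50 g C m-2 = 0.5 t ha-1
        assert monthly_npp(100.0, 0.5) == pytest.approx(50.0)
        assert monthly_npp(100.0, 0.5) * 0.01 == pytest.approx(0.5)

    def test_ndvi_at_min_gives_zero(self, grid, cropland_map):
        params = CasaParams()
        forcing = make_forcing(grid, ndvi=params.ndvi_min)
        layer = compute_npp(forcing, cropland_map, params)
        np.testing.assert_allclose(layer.values, 0.0)

    def test_linear_in_solar_radiation(self, grid, cropland_map):
        base = make_forcing(grid, sol=40.0)
        doubled = make_forcing(grid, sol=80.0)
        a = compute_npp(base, cropland_map).values
        b = compute_npp(doubled, cropland_map).values
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_zero_on_water_and_urban(self, grid):
        classes = np.ones(grid.shape, dtype=np.int16)
        classes[0, :] = 4  # water
        classes[1, :] = 5  # urban
        layer = compute_npp(make_forcing(grid), make_landuse(grid, classes))
        assert (layer.values[0, :] == 0).all()
        assert (layer.values[1, :] == 0).all()
        assert (layer.values[2:, :] > 0).all()

    def test_missing_month_rejected(self, grid, cropland_map):
        forcing = make_forcing(grid)
        forcing.sol = forcing.sol[:11]
        with pytest.raises(IncompleteForcingError):
            compute_npp(forcing, cropland_map)

    def test_nonnegative_everywhere(self, grid, cropland_map):
        layer = compute_npp(make_forcing(grid, ndvi=0.8, tem=35.0), cropland_map)
        assert (layer.values >= 0).all()


class TestFP:
    def test_two_cell_hand_example(self):
        from eslines.grids import GridSpec

        g = GridSpec(1, 2)
        lu = make_landuse(g, np.array([[1, 1]]))
        zones = make_zones(g, np.array([[1, 1]]), {1: 8.0})
        ndvi = np.array([[0.2, 0.6]])
        fp = compute_fp(ndvi, lu, zones).values
        np.testing.assert_allclose(fp, [[2.0, 6.0]])

    def test_equal_ndvi_equal_split(self, grid, cropland_map):
        zones = make_zones(grid, np.ones(grid.shape, dtype=int), {1: 100.0})
        fp = compute_fp(np.full(grid.shape, 0.5), cropland_map, zones).values
        np.testing.assert_allclose(fp, 100.0 / grid.n_cells)

    def test_zone_conservation(self, grid):
        rng = np.random.default_rng(3)
        classes = rng.choice([1, 2, 4], size=grid.shape, p=[0.6, 0.3, 0.1]).astype(np.int16)
        classes[0, 0] = 1  # ensure cropland in zone 1
        classes[-1, -1] = 1
        zones_arr = np.zeros(grid.shape, dtype=int)
        zones_arr[:, grid.n_cols // 2 :] = 1
        zones_arr += 1
        yields = {1: 250.0, 2: 400.0}
        zones = make_zones(grid, zones_arr, yields)
        fp = compute_fp(rng.uniform(0.1, 0.9, grid.shape), make_landuse(grid, classes), zones)
        for zid, gsum in yields.items():
            assert fp.values[zones_arr == zid].sum() == pytest.approx(gsum, rel=1e-6)

    def test_zone_without_cropland_is_zero_and_warns(self, grid, caplog):
        classes = np.full(grid.shape, 2, dtype=np.int16)  # all forest
        zones = make_zones(grid, np.ones(grid.shape, dtype=int), {1: 50.0})
        with caplog.at_level("WARNING"):
            fp = compute_fp(np.full(grid.shape, 0.5), make_landuse(grid, classes), zones)
        assert (fp.values == 0).all()
        assert any("no cropland" in r.message for r in caplog.records)

    def test_zero_off_cropland(self, grid):
        classes = np.ones(grid.shape, dtype=np.int16)
        classes[5:, :] = 3
        zones = make_zones(grid, np.ones(grid.shape, dtype=int), {1: 10.0})
        fp = compute_fp(np.full(grid.shape, 0.5), make_landuse(grid, classes), zones)
        assert (fp.values[5:, :] == 0).all()


class TestRusle:
    def test_zero_rain_zero_erosivity(self):
        assert rainfall_erosivity(np.zeros((12, 4, 4))).max() == 0.0

    def test_flat_terrain_minimal_ls(self):
        flat = ls_factor(np.zeros((5, 5)), cell_size=250.0)
        ridge = np.tile(np.arange(5.0) * 50.0, (5, 1))
        sloped = ls_factor(ridge, cell_size=250.0)
        assert np.all(flat <= sloped + 1e-12)
        np.testing.assert_allclose(flat, flat[0, 0])

    def test_c_factor_endpoints(self, grid, cropland_map):
        params = RusleParams()
        full_veg = compute_rusle_factors(
            make_forcing(grid, ndvi=params.ndvi_veg), cropland_map, params=params
        )
        bare = compute_rusle_factors(
            make_forcing(grid, ndvi=params.ndvi_soil), cropland_map, params=params
        )
        np.testing.assert_allclose(full_veg.C, params.c_floor)
        np.testing.assert_allclose(bare.C, 1.0)

    def test_factors_in_valid_ranges(self, grid, cropland_map):
        rng = np.random.default_rng(0)
        dem = rng.uniform(0, 500, grid.shape)
        f = compute_rusle_factors(make_forcing(grid, dem=dem), cropland_map)
        for name in ("R", "K", "LS", "C", "P"):
            assert (getattr(f, name) >= 0).all(), name
        assert (f.C <= 1).all() and (f.P <= 1).all()

    def test_sc_hand_arithmetic(self):
        shape = (3, 3)
        factors = RusleFactors(
            R=np.full(shape, 100.0),
            K=np.full(shape, 0.3),
            LS=np.full(shape, 2.0),
            C=np.full(shape, 0.2),
            P=np.full(shape, 1.0),
        )
        sc = compute_sc(factors).values
        np.testing.assert_allclose(sc, 48.0)  # Ap=60, Ar=12

    def test_sc_zero_when_unprotected(self):
        shape = (2, 2)
        ones = np.ones(shape)
        sc = compute_sc(RusleFactors(R=ones * 50, K=ones * 0.2, LS=ones, C=ones, P=ones))
        np.testing.assert_allclose(sc.values, 0.0)

    def test_sc_equals_potential_at_full_cover(self):
        shape = (2, 2)
        ones = np.ones(shape)
        sc = compute_sc(
            RusleFactors(R=ones * 50, K=ones * 0.2, LS=ones * 2, C=ones * 0, P=ones)
        )
        np.testing.assert_allclose(sc.values, 50 * 0.2 * 2)

    def test_sc_monotone_in_c_and_p(self):
        shape = (2, 2)
        ones = np.ones(shape)
        base = dict(R=ones * 80, K=ones * 0.25, LS=ones * 1.5)
        lo = compute_sc(RusleFactors(**base, C=ones * 0.2, P=ones * 0.5)).values
        hi_c = compute_sc(RusleFactors(**base, C=ones * 0.4, P=ones * 0.5)).values
        hi_p = compute_sc(RusleFactors(**base, C=ones * 0.2, P=ones * 0.8)).values
        assert np.all(hi_c <= lo) and np.all(hi_p <= lo)

    def test_negative_factor_rejected(self):
        ones = np.ones((2, 2))
        with pytest.raises(InvalidInputError):
            compute_sc(RusleFactors(R=-ones, K=ones, LS=ones, C=ones * 0.5, P=ones))


class TestWY:
    def test_zero_pet_yields_all_rain(self, grid, cropland_map):
        params = WaterYieldParams(et0=np.zeros(grid.shape), awc=np.full(grid.shape, 100.0))
        forcing = make_forcing(grid, ppt=800.0)
        wy = compute_wy(forcing, cropland_map, params).values
        np.testing.assert_allclose(wy, 800.0, rtol=1e-6)

    def test_budyko_worked_example(self, grid, cropland_map):
        # PPT 1000, PET 500, w = 2 (awc*z/ppt = 0.75 -> awc = 100, z = 7.5)
        params = WaterYieldParams(
            kc_table={1: 1.0},
            z=7.5,
            awc=np.full(grid.shape, 100.0),
            et0=np.full(grid.shape, 500.0),
        )
        wy = compute_wy(make_forcing(grid, ppt=1000.0), cropland_map, params).values
        expected = 1000.0 * (np.sqrt(1.25) - 0.5)  # (1 - (1.5 - sqrt(1.25))) * 1000
        np.testing.assert_allclose(wy, expected, rtol=1e-9)
        assert wy[0, 0] == pytest.approx(618.03, abs=0.01)

    def test_energy_limited_asymptote(self, grid, cropland_map):
        # w -> large: AET -> PET, WY -> PPT - PET
        params = WaterYieldParams(
            kc_table={1: 1.0},
            z=7.5,
            awc=np.full(grid.shape, 1e7),
            et0=np.full(grid.shape, 500.0),
        )
        wy = compute_wy(make_forcing(grid, ppt=1000.0), cropland_map, params).values
        np.testing.assert_allclose(wy, 500.0, rtol=1e-6)

    def test_zero_ppt_convention(self, grid, cropland_map):
        ppt = np.full(grid.shape, 700.0)
        ppt[0, 0] = 0.0
        wy = compute_wy(make_forcing(grid, ppt=ppt), cropland_map).values
        assert wy[0, 0] == 0.0
        assert (wy >= 0).all()

    def test_bounds_and_monotonicity_in_pet(self, grid, cropland_map):
        rng = np.random.default_rng(1)
        ppt = rng.uniform(300, 1200, grid.shape)
        et0 = rng.uniform(200, 900, grid.shape)
        awc = np.full(grid.shape, 120.0)
        lo = compute_wy(
            make_forcing(grid, ppt=ppt),
            cropland_map,
            WaterYieldParams(kc_table={1: 1.0}, awc=awc, et0=et0),
        ).values
        hi = compute_wy(
            make_forcing(grid, ppt=ppt),
            cropland_map,
            WaterYieldParams(kc_table={1: 1.0}, awc=awc, et0=et0 * 1.2),
        ).values
        assert (lo >= 0).all() and (lo <= ppt + 1e-9).all()
        assert (hi <= lo + 1e-9).all()

    def test_aet_ratio_monotone_in_aridity(self):
        r = np.linspace(0.01, 3, 50)
        ratios = budyko_aet_ratio(r, np.full_like(r, 2.0))
        assert (np.diff(ratios) > 0).all()
        assert (ratios <= 1).all() and (ratios >= 0).all()
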