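import calendar

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grassnpp.casa_core import (EPS_MAX_GRASSLAND, EPS_MAX_SHRUB, FparConstants,
                                VegClassParams, calibrate_class_bounds,
                                compute_apar, compute_fpar, compute_ndvi,
                                compute_npp_month, compute_sr, composite_monthly,
                                fpar_from_ndvi, fpar_from_sr, light_use_efficiency,
                                moisture_stress, run_casa, soil_moisture_et,
                                temp_stress_1, temp_stress_2, thornthwaite_pet)
from grassnpp.climate_fields import MonthlyClimateField, day_length_hours
from grassnpp.errors import ConfigError, DataValidationError
from grassnpp.raster_io import MonthlyStack, RasterGrid

PARAMS = VegClassParams(class_id=1, ndvi_min=0.1, ndvi_max=0.8,
                        sr_min=(1 + 0.1) / (1 - 0.1), sr_max=(1 + 0.8) / (1 - 0.8),
                        eps_max=EPS_MAX_GRASSLAND)
C = FparConstants()


class TestIndices:
    @pytest.mark.parametrize("red,nir,expected", [
        (0.08, 0.24, 0.5),
        (0.1, 0.1, 0.0),
        (0.2, 0.6, 0.5),
    ])
    def test_ndvi_values(self, red, nir, expected):
        assert compute_ndvi(red, nir) == pytest.approx(expected)

    def test_ndvi_degenerate_is_nodata(self):
        assert np.isnan(compute_ndvi(0.0, 0.0))

    @pytest.mark.parametrize("ndvi,expected", [(0.0, 1.0), (0.5, 3.0), (-1.0, 0.0)])
    def test_sr_values(self, ndvi, expected):
        assert compute_sr(ndvi) == pytest.approx(expected)

    def test_sr_at_one_is_nodata(self):
        assert np.isnan(compute_sr(1.0))

    @given(st.floats(-1, 0.99), st.floats(1e-6, 0.01))
    @settings(max_examples=50, derandomize=True)
    def test_sr_strictly_monotone(self, ndvi, step):
        hi = min(ndvi + step, 0.999)
        assert compute_sr(hi) > compute_sr(ndvi)

    def test_composite_is_per_pixel_maximum(self):
        layers = np.array([[[0.2]], [[0.5]], [[0.3]]])
        assert composite_monthly(layers)[0, 0] == 0.5
        same = np.array([[[0.4]], [[0.4]]])
        assert composite_monthly(same)[0, 0] == 0.4

    def test_composite_all_nodata_stays_nodata(self):
        layers = np.full((3, 1, 1), np.nan)
        assert np.isnan(composite_monthly(layers)[0, 0])
        partial = np.array([[[np.nan]], [[0.2]]])
        assert composite_monthly(partial)[0, 0] == 0.2


class TestFpar:
    def test_bounds_map_to_fpar_constants(self):
        assert fpar_from_ndvi(PARAMS.ndvi_min, PARAMS) == pytest.approx(0.001)
        assert fpar_from_ndvi(PARAMS.ndvi_max, PARAMS) == pytest.approx(0.95)
        assert fpar_from_sr(PARAMS.sr_min, PARAMS) == pytest.approx(0.001)
        assert fpar_from_sr(PARAMS.sr_max, PARAMS) == pytest.approx(0.95)

    def test_midpoint(self):
        mid = (PARAMS.ndvi_min + PARAMS.ndvi_max) / 2
        assert fpar_from_ndvi(mid, PARAMS) == pytest.approx((0.001 + 0.95) / 2)

    @given(st.floats(-1, 1))
    @settings(max_examples=100, derandomize=True)
    def test_always_within_constants_even_adversarial(self, ndvi):
        f = fpar_from_ndvi(ndvi, PARAMS)
        assert 0.001 <= f <= 0.95
        sr = compute_sr(min(ndvi, 0.999))
        assert 0.001 <= fpar_from_sr(sr, PARAMS) <= 0.95

    def test_mean_of_estimates(self):
        assert compute_fpar(0.2, 0.4) == pytest.approx(0.3)
        assert compute_fpar(0.3, 0.3) == 0.3
        assert compute_fpar(0.001, 0.95) == pytest.approx(0.4755)


class TestCalibration:
    def test_percentile_oracle_uniform(self, rng):
        ndvi = rng.uniform(0.1, 0.9, size=(5, 12, 6, 6))
        landcover = np.ones((6, 6), dtype=int)
        params = calibrate_class_bounds(ndvi, landcover, {1: 0.542})
        lo, hi = np.percentile(ndvi.ravel(), [5, 95])
        assert params[1].ndvi_min == pytest.approx(lo)
        assert params[1].ndvi_max == pytest.approx(hi)
        # expected location for U(0.1, 0.9): 5th pct ~0.14, 95th ~0.86
        assert params[1].ndvi_min == pytest.approx(0.14, abs=0.01)
        assert params[1].ndvi_max == pytest.approx(0.86, abs=0.01)

    def test_sr_bounds_are_sr_of_ndvi_bounds(self, rng):
        ndvi = rng.uniform(0.1, 0.9, size=(3, 12, 4, 4))
        params = calibrate_class_bounds(ndvi, np.ones((4, 4), dtype=int), {1: 0.5})
        p = params[1]
        assert p.sr_min == pytest.approx(float(compute_sr(p.ndvi_min)))
        assert p.sr_max == pytest.approx(float(compute_sr(p.ndvi_max)))

    def test_constant_ndvi_rejected_as_degenerate(self):
        ndvi = np.full((3, 12, 4, 4), 0.5)
        with pytest.raises(DataValidationError, match="degenerate"):
            calibrate_class_bounds(ndvi, np.ones((4, 4), dtype=int), {1: 0.5})

    def test_too_few_samples_names_class(self):
        ndvi = np.full((1, 12, 2, 2), np.nan)
        ndvi[0, 0, 0, 0] = 0.5
        with pytest.raises(DataValidationError, match="class 1"):
            calibrate_class_bounds(ndvi, np.ones((2, 2), dtype=int), {1: 0.5})


class TestStressScalars:
    def test_teps1_quadratic(self):
        assert temp_stress_1(20.0) == pytest.approx(1.0)
        assert temp_stress_1(0.0) == pytest.approx(0.8)

    def test_teps1_deep_cold_cutoff(self):
        assert temp_stress_1(20.0, t_month=-15.0) == 0.0
        assert temp_stress_1(20.0, t_month=-10.0) == 0.0
        assert temp_stress_1(20.0, t_month=-9.9) == pytest.approx(1.0)

    def test_teps2_formula_at_optimum(self):
        t_opt = 18.0
        expected = 1.1814 / (1 + np.exp(0.2 * (-10))) / (1 + np.exp(0.3 * (-10)))
        assert temp_stress_2(t_opt, t_opt) == pytest.approx(expected)

    def test_teps2_cold_limit_zero(self):
        assert temp_stress_2(-80.0, 20.0) == pytest.approx(0.0, abs=1e-6)

    def test_teps2_hot_below_optimum_value(self):
        t_opt = 20.0
        assert temp_stress_2(t_opt + 13, t_opt) < temp_stress_2(t_opt, t_opt)

    @pytest.mark.parametrize("eet,pet,expected", [
        (50.0, 50.0, 1.0), (0.0, 50.0, 0.5), (25.0, 50.0, 0.75), (10.0, 0.0, 0.5),
    ])
    def test_moisture_stress(self, eet, pet, expected):
        assert moisture_stress(eet, pet) == pytest.approx(expected)

    def test_lue_paper_constants(self):
        assert light_use_efficiency(1, 1, 1, EPS_MAX_GRASSLAND) == pytest.approx(0.542)
        assert light_use_efficiency(1, 1, 1, EPS_MAX_SHRUB) == pytest.approx(0.429)
        assert light_use_efficiency(0, 1, 1, EPS_MAX_GRASSLAND) == 0.0

    def test_apar(self):
        assert compute_apar(100.0, 0.5) == pytest.approx(25.0)
        assert compute_apar(100.0, 0.0) == 0.0
        assert compute_apar(80.0, 1.0) == pytest.approx(40.0)

    def test_npp_month(self):
        assert compute_npp_month(25.0, 0.542) == pytest.approx(13.55)
        assert compute_npp_month(25.0, 0.0) == 0.0
        assert np.isnan(compute_npp_month(np.nan, 0.5))


# ---------------------------------------------------------------------------
# Scalar reference implementation of the full chain (independent of the
# vectorised driver): plain python loops per pixel.

def _scalar_reference_npp(ndvi, temp, precip, sol, landcover, params,
                          latitude, capacity):
    ny = ndvi.shape[0]
    rows, cols = ndvi.shape[2], ndvi.shape[3]
    npp = np.full(ndvi.shape, np.nan)
    years = list(range(2001, 2001 + ny))
    for r in range(rows):
        for c in range(cols):
            cid = landcover[r, c]
            if cid not in params:
                continue
            p = params[cid]
            soil = capacity * 0.5
            for yi, year in enumerate(years):
                t12 = temp[yi, :, r, c]
                i_heat = sum((max(t, 0.0) / 5.0) ** 1.514 for t in t12)
                a = (6.75e-7 * i_heat ** 3 - 7.71e-5 * i_heat ** 2
                     + 1.792e-2 * i_heat + 0.49239)
                t_opt = t12[int(np.argmax(ndvi[yi, :, r, c]))]
                for m in range(12):
                    t = t12[m]
                    if t > 0 and i_heat > 0:
                        n_days = calendar.monthrange(year, m + 1)[1]
                        corr = day_length_hours(latitude, year, m + 1) / 12 * n_days / 30
                        pet = 16.0 * (10.0 * t / i_heat) ** a * corr
                    else:
                        pet = 0.0
                    pr = precip[yi, m, r, c]
                    eet = min(pet, pr + soil)
                    soil = min(max(soil + pr - eet, 0.0), capacity)
                    w = 0.5 + 0.5 * min(max(eet / pet, 0.0), 1.0) if pet > 0 else 0.5
                    te1 = max(0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2, 0.0)
                    if t <= -10:
                        te1 = 0.0
                    raw = lambda x: 1.1814 / (1 + np.exp(0.2 * (t_opt - 10 - x))) \
                        / (1 + np.exp(0.3 * (-t_opt - 10 + x)))
                    te2 = min(raw(t), raw(t_opt)) if t > t_opt + 10 else raw(t)
                    n = ndvi[yi, m, r, c]
                    sr = (1 + n) / (1 - n)
                    f1 = min(max((n - p.ndvi_min) / (p.ndvi_max - p.ndvi_min)
                                 * (0.95 - 0.001) + 0.001, 0.001), 0.95)
                    f2 = min(max((sr - p.sr_min) / (p.sr_max - p.sr_min)
                                 * (0.95 - 0.001) + 0.001, 0.001), 0.95)
                    fpar = (f1 + f2) / 2
                    eps = te1 * te2 * w * p.eps_max
                    value = max(sol[yi, m, r, c] * fpar * 0.5 * eps, 0.0)
                    npp[yi, m, r, c] = 0.0 if (m + 1) in (12, 1, 2) else value
    return npp


def _toy_inputs(rng, rows=10, cols=10, ny=2):
    grid = RasterGrid(rows=rows, cols=cols, origin_y=rows * 500.0)
    years = list(range(2001, 2001 + ny))
    season = -np.cos(2 * np.pi * (np.arange(1, 13) - 0.5) / 12)
    temp = (3.0 + 19 * season[None, :, None, None]
            + rng.normal(0, 1, size=(ny, 12, rows, cols)))
    precip = np.clip(rng.gamma(2.0, 15.0, size=(ny, 12, rows, cols)), 0, None)
    sol = 300 + 200 * season[None, :, None, None] + rng.uniform(0, 30, (ny, 12, rows, cols))
    ndvi = np.clip(0.45 + 0.35 * season[None, :, None, None]
                   + rng.normal(0, 0.05, size=(ny, 12, rows, cols)), 0.02, 0.92)
    landcover = rng.choice([0, 1, 2], size=(rows, cols), p=[0.1, 0.7, 0.2])
    climate = MonthlyClimateField(
        temperature=MonthlyStack(grid, years, temp, "temperature", "degC"),
        precipitation=MonthlyStack(grid, years, precip, "precipitation", "mm"),
        solar=MonthlyStack(grid, years, np.clip(sol, 0, None), "solar"))
    stack = MonthlyStack(grid, years, ndvi, "ndvi")
    params = {
        1: VegClassParams(1, 0.1, 0.8, (1.1) / (0.9), 1.8 / 0.2, EPS_MAX_GRASSLAND),
        2: VegClassParams(2, 0.1, 0.8, (1.1) / (0.9), 1.8 / 0.2, EPS_MAX_SHRUB),
    }
    return stack, climate, landcover, params


class TestFullChain:
    def test_vectorised_equals_scalar_reference(self, rng):
        stack, climate, landcover, params = _toy_inputs(rng)
        series = run_casa(stack, climate, landcover, params, latitude=44.0,
                          bucket_capacity=100.0)
        ref = _scalar_reference_npp(stack.data, climate.temperature.data,
                                    climate.precipitation.data,
                                    climate.solar.data, landcover, params,
                                    44.0, 100.0)
        np.testing.assert_allclose(series.monthly.data, ref, atol=1e-9)

    def test_npp_nonnegative_and_winter_zero(self, rng):
        stack, climate, landcover, params = _toy_inputs(rng)
        series = run_casa(stack, climate, landcover, params)
        data = series.monthly.data
        assert np.nanmin(data) >= 0.0
        for m in (12, 1, 2):
            layer = data[:, m - 1]
            assert np.all(layer[np.isfinite(layer)] == 0.0)

    def test_nonveg_pixels_are_nodata(self, rng):
        stack, climate, landcover, params = _toy_inputs(rng)
        series = run_casa(stack, climate, landcover, params)
        assert np.isnan(series.monthly.data[..., landcover == 0]).all()

    def test_npp_proportional_to_eps_max(self, rng):
        """With identical inputs and bounds, grass:shrub NPP = 0.542:0.429."""
        stack, climate, _, params = _toy_inputs(rng, rows=2, cols=2)
        grass = run_casa(stack, climate, np.full((2, 2), 1), params)
        shrub = run_casa(stack, climate, np.full((2, 2), 2), params)
        g = grass.monthly.data
        s = shrub.monthly.data
        active = np.isfinite(g) & (g > 0)
        np.testing.assert_allclose(g[active] / s[active],
                                   EPS_MAX_GRASSLAND / EPS_MAX_SHRUB, rtol=1e-12)

    def test_apar_bounded_by_half_sol(self, rng):
        stack, climate, landcover, params = _toy_inputs(rng)
        series = run_casa(stack, climate, landcover, params, keep_diagnostics=True)
        apar = series.diagnostics["apar"]
        ok = np.isfinite(apar)
        assert np.all(apar[ok] <= 0.5 * climate.solar.data[ok] + 1e-12)

    def test_year_mismatch_rejected(self, rng):
        stack, climate, landcover, params = _toy_inputs(rng)
        bad = MonthlyStack(stack.grid, [1999, 2000], stack.data, "ndvi")
        with pytest.raises(DataValidationError, match="years"):
            run_casa(bad, climate, landcover, params)


class TestBucket:
    def test_eet_never_exceeds_pet_or_supply(self, rng):
        precip = rng.gamma(2.0, 15.0, size=(24, 4))
        pet = rng.uniform(0, 120, size=(24, 4))
        eet = soil_moisture_et(precip, pet, capacity=100.0)
        assert np.all(eet <= pet + 1e-12)
        assert np.all(eet >= 0)

    def test_wet_regime_meets_demand(self):
        precip = np.full((12, 1), 200.0)
        pet = np.full((12, 1), 50.0)
        np.testing.assert_allclose(soil_moisture_et(precip, pet), pet)

    def test_thornthwaite_zero_below_freezing(self):
        temp = np.full((12, 1), -5.0)
        assert thornthwaite_pet(temp, 44.0, 2001).max() == 0.0
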