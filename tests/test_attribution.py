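import numpy as np
import pytest

from grassnpp.climate_attribution import (correlation_map, county_table,
                                          map_summary, partial_r, pearson_r)
from grassnpp.errors import ConfigError, DataValidationError
from grassnpp.synthetic import CLASS_NONVEG, WorldConfig, make_world

COUNTY_COLUMNS = ["AP", "AMT", "SpP", "SpMT", "SuP", "SuMT", "AuP", "AuMT"]


def random_trivariate(rng, n=13):
    """Random 3-variable sample with a valid, non-degenerate correlation matrix."""
    mixing = rng.normal(size=(3, 3))
    data = rng.normal(size=(n, 3)) @ mixing.T
    return data


def residual_partial_oracle(data):
    """Correlation of OLS residuals of x1|x3 and x2|x3 (independent route)."""
    x1, x2, x3 = data[:, 0], data[:, 1], data[:, 2]
    x3c = np.column_stack([np.ones_like(x3), x3])
    b1 = np.linalg.lstsq(x3c, x1, rcond=None)[0]
    b2 = np.linalg.lstsq(x3c, x2, rcond=None)[0]
    r1 = x1 - x3c @ b1
    r2 = x2 - x3c @ b2
    return np.corrcoef(r1, r2)[0, 1]


class TestPearson:
    def test_identity_and_affine(self, rng):
        x = rng.normal(size=13)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=13), rng.normal(size=13)
        assert pearson_r(x, y) == pearson_r(y, x)

    def test_degenerate_series(self, rng):
        assert np.isnan(pearson_r(np.full(13, 2.0), rng.normal(size=13)))
        with pytest.raises(DataValidationError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


class TestPartial:
    def test_uncorrelated_control_leaves_r12(self):
        assert partial_r(0.6, 0.0, 0.0) == pytest.approx(0.6)

    def test_fully_mediated_is_zero(self):
        assert partial_r(0.7 * 0.5, 0.7, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_collinear_control_is_nodata(self):
        assert np.isnan(partial_r(0.5, 1.0, 0.3))

    def test_swapping_targets_is_invariant(self, rng):
        data = random_trivariate(rng)
        r12 = pearson_r(data[:, 0], data[:, 1])
        r13 = pearson_r(data[:, 0], data[:, 2])
        r23 = pearson_r(data[:, 1], data[:, 2])
        assert partial_r(r12, r13, r23) == pytest.approx(partial_r(r12, r23, r13))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = random_trivariate(rng)
        r12 = pearson_r(data[:, 0], data[:, 1])
        r13 = pearson_r(data[:, 0], data[:, 2])
        r23 = pearson_r(data[:, 1], data[:, 2])
        assert partial_r(r12, r13, r23) == pytest.approx(
            residual_partial_oracle(data), abs=1e-10)


class TestCorrelationMap:
    def test_noiseless_pure_precip_coupling_gives_r_one(self):
        world = make_world(WorldConfig(seed=2, grid_shape=(8, 8), n_years=6,
                                       noise_sd=0.0, npp_temp_coupling=0.0))
        veg = world.landcover != CLASS_NONVEG
        annual = world.truth.npp_monthly.data.sum(axis=1)
        precip = world.precipitation.data.sum(axis=1)
        amap = correlation_map(annual, precip)
        np.testing.assert_allclose(amap.r[veg], 1.0, atol=1e-9)

    def test_temp_partial_near_zero_when_mediated(self):
        world = make_world(WorldConfig(seed=2, grid_shape=(20, 20)))
        veg = world.landcover != CLASS_NONVEG
        annual = world.truth.npp_monthly.data.sum(axis=1)
        precip = world.precipitation.data.sum(axis=1)
        temp = world.temperature.data.mean(axis=1)
        amap = correlation_map(annual, temp, control=precip,
                               target="temperature", controlled="precipitation")
        assert np.median(np.abs(amap.r[veg])) < 0.3

    def test_constant_pixel_is_nodata(self, rng):
        npp = rng.normal(size=(6, 3, 3))
        npp[:, 0, 0] = 5.0
        amap = correlation_map(npp, rng.normal(size=(6, 3, 3)))
        assert np.isnan(amap.r[0, 0])
        assert np.isfinite(amap.r[1:]).all()

    def test_partial_needs_enough_years(self, rng):
        stacks = rng.normal(size=(3, 2, 2))
        with pytest.raises(DataValidationError):
            correlation_map(stacks, stacks + 1, control=stacks * 2)

    def test_partial_records_controlled_variable(self, rng):
        npp = rng.normal(size=(8, 2, 2))
        amap = correlation_map(npp, rng.normal(size=(8, 2, 2)),
                               control=rng.normal(size=(8, 2, 2)),
                               target="temperature", controlled="precipitation")
        assert amap.kind == "partial" and amap.controlled == "precipitation"


class TestCountyTable:
    def test_nine_counties_by_eight_coefficients(self, demo_world):
        table = county_table(demo_world.truth.npp_monthly.data,
                             demo_world.precipitation.data,
                             demo_world.temperature.data,
                             demo_world.counties, demo_world.config.years)
        assert len(table) == 9
        for col in COUNTY_COLUMNS:
            assert col in table.columns
            assert col + "_sig" in table.columns

    def test_single_pixel_county_equals_pixel_r(self, small_world):
        counties = np.zeros_like(small_world.counties)
        counties[4, 4] = 1
        table = county_table(small_world.truth.npp_monthly.data,
                             small_world.precipitation.data,
                             small_world.temperature.data,
                             counties, small_world.config.years)
        npp_series = small_world.truth.npp_monthly.data[:, :, 4, 4].sum(axis=1)
        precip_series = small_world.precipitation.data[:, :, 4, 4].sum(axis=1)
        assert table["AP"].iloc[0] == pytest.approx(
            pearson_r(npp_series, precip_series), abs=1e-12)

    def test_identical_counties_identical_rows(self, rng):
        npp = np.tile(rng.normal(10, 2, size=(4, 12, 1, 1)), (1, 1, 4, 4))
        precip = np.tile(rng.normal(30, 5, size=(4, 12, 1, 1)), (1, 1, 4, 4))
        temp = np.tile(rng.normal(5, 2, size=(4, 12, 1, 1)), (1, 1, 4, 4))
        counties = np.repeat(np.arange(1, 3), 8).reshape(4, 4)
        table = county_table(npp, precip, temp, counties, [2001, 2002, 2003, 2004])
        for col in COUNTY_COLUMNS:
            assert table[col].iloc[0] == pytest.approx(table[col].iloc[1])


class TestMapSummary:
    def _map(self, r):
        from grassnpp.climate_attribution import AttributionMap
        return AttributionMap(r=r, p=np.full_like(r, 0.5), n_years=13,
                              kind="correlation", target="precipitation")

    def test_all_positive(self):
        s = map_summary(self._map(np.full((4, 4), 0.8)))
        assert s["frac_positive"] == 1.0 and s["frac_negative"] == 0.0

    def test_half_and_half(self):
        r = np.concatenate([np.full(8, 0.5), np.full(8, -0.5)]).reshape(4, 4)
        s = map_summary(self._map(r))
        assert s["frac_positive"] == 0.5 and s["frac_negative"] == 0.5

    def test_fractions_partition_valid_pixels(self, rng):
        r = rng.uniform(-1, 1, size=(6, 6))
        r[0, 0] = np.nan
        s = map_summary(self._map(r))
        zero_frac = (r[np.isfinite(r)] == 0).mean()
        assert s["frac_positive"] + s["frac_negative"] + zero_frac == pytest.approx(1.0)
        assert sum(s["hist_counts"]) == s["n_valid"]
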