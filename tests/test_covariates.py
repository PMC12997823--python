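"""Covariate derivation: Shannon focal diversity, TRI, water proximity,
resampling, seasons and moon illumination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rsfkit.covariates import (
    CovariateGrid,
    MoonSeries,
    proximity_to_water,
    read_ascii_grid,
    resample_to_common_grid,
    season_of,
    shannon_focal,
    synthetic_moon_series,
    terrain_ruggedness,
    write_ascii_grid,
)

from ._oracles import brute_force_distance, brute_force_shannon_focal, brute_force_tri


def grid(values, cell=30.0, name="g", **kw):
    return CovariateGrid(name=name, origin=(0.0, 0.0), cell_size=cell,
                         values=np.asarray(values, dtype=float), **kw)


# ---------------------------------------------------------------------
# Shannon focal diversity
# ---------------------------------------------------------------------

class TestShannonFocal:
    def test_single_class_window_is_zero(self):
        g = grid(np.ones((9, 9)), categorical=True)
        out = shannon_focal(g, radius=90.0)
        assert np.allclose(out.values, 0.0)

    def test_two_equal_classes_give_ln2(self):
        # exactly two valid cells in the buffer, one per class
        vals = np.full((5, 5), np.nan)
        vals[2, 2], vals[2, 3] = 0.0, 1.0
        out = shannon_focal(grid(vals, categorical=True), radius=45.0)
        assert out.values[2, 2] == pytest.approx(np.log(2.0), abs=1e-9)

    def test_window_proportions_from_stripes(self):
        # vertical stripes 0101...: the 9-cell window (radius 1.5 cells,
        # diagonals included) holds the centre column vs both neighbours 3:6
        vals = np.tile([0.0, 1.0], (12, 6))
        out = shannon_focal(grid(vals, categorical=True), radius=45.0)
        p = np.array([1 / 3, 2 / 3])
        assert out.values[5, 5] == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-9)

    def test_uneven_proportions_match_direct_entropy(self):
        # one 8-cell window engineered to proportions (1/2, 1/4, 1/8, 1/8)
        vals = np.full((5, 5), np.nan)
        window = [0, 0, 0, 0, 1, 1, 2, 3]  # 8 valid cells inside the buffer
        coords = [(2, 2), (2, 1), (2, 3), (1, 2), (3, 2), (1, 1), (1, 3), (3, 1)]
        for c, (i, j) in zip(window, coords):
            vals[i, j] = c
        g = grid(vals, categorical=True)
        out = shannon_focal(g, radius=45.0)
        # independent evaluation of -sum p ln p
        expected = -(0.5 * np.log(0.5) + 0.25 * np.log(0.25) + 2 * 0.125 * np.log(0.125))
        assert expected == pytest.approx(1.2130, abs=5e-4)
        assert out.values[2, 2] == pytest.approx(expected, abs=1e-9)

    def test_all_nodata_window_yields_nodata(self):
        vals = np.full((7, 7), np.nan)
        vals[0, 0] = 1.0
        out = shannon_focal(grid(vals, categorical=True), radius=31.0)
        assert np.isnan(out.values[5, 5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 4, size=(24, 24)).astype(float)
        vals[rng.uniform(size=vals.shape) < 0.05] = np.nan
        g = grid(vals, categorical=True)
        out = shannon_focal(g, radius=100.0)
        targets = [(i, j) for i in range(0, 24, 5) for j in range(0, 24, 5)]
        oracle = brute_force_shannon_focal(vals, 30.0, 100.0, rows_cols=targets)
        for (i, j), h in oracle.items():
            assert out.values[i, j] == pytest.approx(h, abs=1e-9), (i, j)

    def test_bounded_by_log_class_count(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 5, size=(20, 20)).astype(float)
        out = shannon_focal(grid(vals, categorical=True), radius=95.0)
        assert np.nanmax(out.values) <= np.log(5) + 1e-12

    def test_fractional_weights_close_to_centre_rule(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 3, size=(15, 15)).astype(float)
        g = grid(vals, categorical=True)
        a = shannon_focal(g, radius=100.0)
        b = shannon_focal(g, radius=100.0, fractional=True)
        assert np.nanmean(np.abs(a.values - b.values)) < 0.2


# ---------------------------------------------------------------------
# Terrain ruggedness
# ---------------------------------------------------------------------

class TestTerrainRuggedness:
    def test_flat_dem_is_zero(self):
        out = terrain_ruggedness(grid(np.full((6, 6), 123.0)))
        assert np.allclose(out.values, 0.0)

    def test_single_bump_is_sqrt8(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 1.0
        out = terrain_ruggedness(grid(vals))
        assert out.values[2, 2] == pytest.approx(np.sqrt(8.0))

    def test_inclined_plane_interior(self):
        s = 2.5
        vals = np.tile(np.arange(8) * s, (8, 1))
        out = terrain_ruggedness(grid(vals))
        # six neighbours differ by +-s, two by 0
        assert np.allclose(out.values[1:-1, 1:-1], s * np.sqrt(6.0))

    def test_matches_brute_force_with_nodata(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(12, 12)) * 10
        vals[rng.uniform(size=vals.shape) < 0.1] = np.nan
        out = terrain_ruggedness(grid(vals))
        oracle = brute_force_tri(vals)
        assert np.allclose(out.values, oracle, equal_nan=True)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-1e4, 1e4), seed=st.integers(0, 100))
    def test_translation_invariance(self, shift, seed):
        vals = np.random.default_rng(seed).normal(size=(6, 6))
        a = terrain_ruggedness(grid(vals)).values
        b = terrain_ruggedness(grid(vals + shift)).values
        assert np.allclose(a, b, atol=1e-7)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            terrain_ruggedness(grid(np.zeros((2, 5))))


# ---------------------------------------------------------------------
# Proximity to water
# ---------------------------------------------------------------------

class TestProximityToWater:
    def test_river_cell_is_zero_and_axis_distance(self):
        vals = np.zeros((7, 7))
        vals[:, 0] = 1.0  # straight river along the west edge
        out = proximity_to_water(grid(vals, categorical=True))
        assert out.values[3, 0] == 0.0
        assert out.values[3, 3] == pytest.approx(90.0)  # 3 cells east at 30 m

    def test_345_triangle(self):
        vals = np.zeros((8, 8))
        vals[1, 1] = 1.0
        out = proximity_to_water(grid(vals, categorical=True))
        assert out.values[5, 4] == pytest.approx(150.0)  # offset (4, 3) cells

    def test_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(11)
        vals = (rng.uniform(size=(40, 40)) < 0.03).astype(float)
        vals[0, 0] = 1.0
        out = proximity_to_water(grid(vals, categorical=True))
        assert np.allclose(out.values, brute_force_distance(vals == 1, 30.0))

    def test_no_water_raises(self):
        with pytest.raises(ValueError, match="no water"):
            proximity_to_water(grid(np.zeros((4, 4)), categorical=True))


# ---------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------

class TestResample:
    def test_identity_at_target_resolution(self):
        vals = np.random.default_rng(0).normal(size=(10, 10))
        g = grid(vals, cell=30.0)
        (out,) = resample_to_common_grid([g], cell_size=30.0)
        assert np.allclose(out.values, vals)
        assert out.origin == g.origin

    def test_constant_grid_stays_constant(self):
        g = grid(np.full((6, 6), 7.5), cell=45.0)
        (out,) = resample_to_common_grid([g], cell_size=30.0)
        assert np.allclose(out.values, 7.5)

    def test_linear_ramp_bilinear_midpoints(self):
        # 60 m ramp in x: value = x-coordinate of the cell centre / 60
        vals = np.tile(np.arange(8, dtype=float), (8, 1))
        g = grid(vals, cell=60.0)
        (out,) = resample_to_common_grid([g], cell_size=30.0)
        xs, _ = out.cell_centers()
        expected = (xs - 30.0) / 60.0  # exact linear interpolation of the ramp
        interior = slice(1, -1)
        assert np.allclose(out.values[4, interior], expected[interior])

    def test_categorical_uses_nearest_neighbour(self):
        vals = np.array([[0.0, 1.0], [2.0, 3.0]])
        g = grid(vals, cell=60.0, categorical=True)
        (out,) = resample_to_common_grid([g], cell_size=30.0)
        assert set(np.unique(out.values)) <= {0.0, 1.0, 2.0, 3.0}

    def test_disjoint_extents_raise(self):
        a = grid(np.zeros((4, 4)))
        b = CovariateGrid(name="b", origin=(10_000.0, 10_000.0), cell_size=30.0,
                          values=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            resample_to_common_grid([a, b])


# ---------------------------------------------------------------------
# Seasons and moon
# ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "ts,season",
    [
        ("2017-01-15", "short_dry"),
        ("2017-04-01", "long_rain"),
        ("2017-07-20", "long_dry"),
        ("2017-12-31", "short_rain"),
    ],
)
def test_season_calendar(ts, season):
    assert season_of(ts) == season


class TestMoon:
    def test_cosine_series_endpoints(self):
        # 28-day synodic period so that half/quarter periods land on dates
        s = synthetic_moon_series("2017-01-01", "2017-03-01", "2017-01-01",
                                  synodic_days=28.0)
        assert s.at("2017-01-01 13:00") == pytest.approx(0.0, abs=1e-9)
        assert s.at("2017-01-15 02:00") == pytest.approx(100.0)  # half period
        assert s.at("2017-01-08") == pytest.approx(50.0)  # quarter period

    def test_true_synodic_matches_cosine_form(self):
        s = synthetic_moon_series("2017-01-01", "2017-04-01", "2017-01-01")
        for d in (0, 5, 17, 40):
            expected = 50.0 * (1 - np.cos(2 * np.pi * d / 29.53))
            got = s.at(pd.Timestamp("2017-01-01") + pd.Timedelta(days=d))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_step_constant_within_day(self):
        s = synthetic_moon_series("2017-01-01", "2017-02-01", "2017-01-01")
        assert s.at("2017-01-10 00:30") == s.at("2017-01-10 23:30")

    def test_out_of_span_raises(self):
        s = synthetic_moon_series("2017-01-01", "2017-02-01", "2017-01-01")
        with pytest.raises(ValueError, match="span"):
            s.at("2017-03-01")

    def test_csv_round_trip(self, tmp_path):
        s = synthetic_moon_series("2017-01-01", "2017-02-01", "2017-01-01")
        p = tmp_path / "moon.csv"
        s.to_csv(p)
        s2 = MoonSeries.from_csv(p)
        assert s2.at("2017-01-21") == pytest.approx(s.at("2017-01-21"))


def test_ascii_grid_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(7, 5))
    vals[0, 0] = np.nan
    g = CovariateGrid(name="WC", origin=(500.0, -250.0), cell_size=30.0, values=vals)
    p = tmp_path / "wc.asc"
    write_ascii_grid(g, p)
    g2 = read_ascii_grid(p, name="WC")
    assert g2.origin == g.origin and g2.cell_size == g.cell_size
    assert np.allclose(g2.values, g.values, atol=1e-5, equal_nan=True)


def test_grid_invariants_rejected():
    with pytest.raises(ValueError):
        CovariateGrid(name="g", origin=(0, 0), cell_size=0.0, values=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        CovariateGrid(name="g", origin=(0, 0), cell_size=30.0, values=np.zeros(3))


class TestRasterizeLines:
    def test_axis_aligned_line_marks_row(self):
        from rsfkit.covariates import rasterize_lines

        tmpl = grid(np.zeros((10, 10)))
        out = rasterize_lines([[(0.0, 105.0), (299.0, 105.0)]], tmpl)
        assert out.values[3, :10].sum() == 10  # row of y=105 m at 30 m cells
        assert out.values.sum() == 10

    def test_geojson_multilinestring(self):
        from rsfkit.covariates import proximity_to_water, rasterize_lines

        tmpl = grid(np.zeros((10, 10)))
        gj = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": {
                    "type": "MultiLineString",
                    "coordinates": [[(15.0, 0.0), (15.0, 299.0)]],
                }}
            ],
        }
        out = rasterize_lines(gj, tmpl)
        assert out.values[:, 0].sum() == 10
        # rasterized mask feeds the distance operation directly
        d = proximity_to_water(out)
        assert d.values[5, 3] == pytest.approx(90.0)
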