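"""Synthetic world: landscape generation, MCPs and track simulation."""

import numpy as np
import pandas as pd
import pytest
import shapely

from rsfkit.covariates import SEASONS
from rsfkit.synthetic import (
    TruthConfig,
    generate_landscape,
    mcp,
    mcp_area_km2,
    simulate_tracks,
)

from ._oracles import brute_force_hull, brute_force_shannon_focal
from .conftest import EXTENT, make_truth


class TestGenerateLandscape:
    def test_same_seed_is_identical(self):
        a = generate_landscape((0, 0, 10_500, 10_500), cell_size=150, seed=5)
        b = generate_landscape((0, 0, 10_500, 10_500), cell_size=150, seed=5)
        for k in a.grids:
            assert np.array_equal(a.grids[k].values, b.grids[k].values, equal_nan=True), k
        assert a.core.equals(b.core)

    def test_invariant_ranges(self, land):
        assert land.grids["WC"].values.min() >= 0
        assert land.grids["WC"].values.max() <= 100
        assert np.nanmin(land.grids["TRI"].values) >= 0
        assert np.nanmin(land.grids["SVD"].values) >= 0
        assert np.nanmin(land.grids["ProxW"].values) >= 0
        for s in SEASONS:
            nd = land.grids[f"NDVI_{s}"].values
            assert nd.min() >= -1 and nd.max() <= 1
        assert len(np.unique(land.grids["LANDCOVER"].values)) >= 4

    def test_areas_tile_the_extent(self, land):
        total = shapely.unary_union(list(land.areas.values()))
        assert total.area == pytest.approx(12_000.0**2, rel=1e-9)
        assert len(land.areas) >= 4  # protected core + >= 3 buffer areas

    def test_svd_matches_focal_shannon_oracle(self, land):
        lc = land.grids["LANDCOVER"].values
        targets = [(30, 40), (100, 100), (150, 60), (60, 170)]
        oracle = brute_force_shannon_focal(lc, 60.0, 1000.0, rows_cols=targets)
        for (i, j), h in oracle.items():
            assert land.grids["SVD"].values[i, j] == pytest.approx(h, abs=1e-9)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="10 x 10 km"):
            generate_landscape((0, 0, 5_000, 20_000), cell_size=100, seed=0)


class TestMCP:
    def test_unit_square_area(self):
        pts = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        assert mcp_area_km2(pts) == pytest.approx(1.0)

    def test_interior_point_does_not_change_hull(self):
        pts = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        assert mcp(pts).equals(mcp(pts + [(500, 500)]))

    def test_matches_cubic_oracle_on_point_cloud(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, size=(60, 2))
        hull = mcp(pts)
        vertices = {tuple(np.round(c, 9)) for c in np.asarray(hull.exterior.coords)[:-1]}
        assert vertices == brute_force_hull(pts)

    @pytest.mark.parametrize("pts", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2)]])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(ValueError):
            mcp(pts)


class TestSimulateTracks:
    def test_reproducible_under_seed(self, land, moon):
        t1 = simulate_tracks(land, make_truth(n_individuals=2, fixes_per_individual=50), moon)
        t2 = simulate_tracks(land, make_truth(n_individuals=2, fixes_per_individual=50), moon)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.relocations, b.relocations)

    def test_track_invariants(self, tracks):
        xmin, ymin, xmax, ymax = EXTENT
        for t in tracks:
            ts = pd.DatetimeIndex(t.relocations["timestamp"])
            assert (np.diff(ts.view("int64")) == 3_600_000_000_000).all()  # hourly
            assert t.relocations["x"].between(xmin, xmax).all()
            assert t.relocations["y"].between(ymin, ymax).all()
            pts = shapely.points(t.relocations["x"], t.relocations["y"])
            assert shapely.covers(t.mcp.buffer(1e-6), pts).all()

    def test_null_truth_matches_availability(self, land, moon):
        """With all coefficients zero, used-point covariate means equal
        the within-kernel availability means up to Monte-Carlo error."""
        truth = make_truth(
            beta_landscape={}, beta_within={}, delta_outside={},
            n_individuals=4, fixes_per_individual=800, seed=3,
        )
        tracks = simulate_tracks(land, truth, moon)
        for t in tracks:
            # compare to uniform draws in the same MCP
            rng = np.random.default_rng(1)
            from rsfkit.sampling import uniform_points_in_polygon

            ref = uniform_points_in_polygon(t.mcp, 4000, rng)
            used = land.extract(t.relocations["x"], t.relocations["y"])
            avail = land.extract(ref[:, 0], ref[:, 1])
            for c in ("WC", "TRI"):
                zdiff = (used[c].mean() - avail[c].mean()) / avail[c].std()
                assert abs(zdiff) < 0.2, (t.individual_id, c, zdiff)

    def test_positive_selection_shifts_used_mean(self, land, moon):
        truth = make_truth(
            beta_landscape={}, beta_within={"WC": 1.0}, delta_outside={},
            n_individuals=3, fixes_per_individual=500, seed=4,
        )
        tracks = simulate_tracks(land, truth, moon)
        from rsfkit.sampling import uniform_points_in_polygon

        for t in tracks:
            ref = uniform_points_in_polygon(t.mcp, 3000, np.random.default_rng(0))
            used_wc = land.extract(t.relocations["x"], t.relocations["y"])["WC"].mean()
            avail_wc = land.extract(ref[:, 0], ref[:, 1])["WC"].mean()
            assert used_wc > avail_wc

    def test_mcp_area_tracks_kernel_scale(self, land, moon):
        """MCP area grows with the squared kernel scale (rank correlation)."""
        scales = [700.0, 1000.0, 1300.0, 1600.0, 1900.0]
        areas = []
        for i, s in enumerate(scales):
            truth = make_truth(n_individuals=1, fixes_per_individual=300,
                               home_range_scale=s, seed=20 + i)
            areas.append(simulate_tracks(land, truth, moon)[0].mcp_area_km2)
        from scipy.stats import spearmanr

        rho = spearmanr(np.array(scales) ** 2, areas).statistic
        assert rho > 0.9

    def test_acceptance_collapse_names_coefficient(self, land, moon):
        truth = make_truth(beta_within={"WC": 30.0}, n_individuals=1,
                           fixes_per_individual=40, seed=6)
        with pytest.raises(RuntimeError, match="WC"):
            simulate_tracks(land, truth, moon, max_rounds=25)

    def test_diel_modulation_is_covariate_specific(self, land, moon):
        """A noon-peak amplitude on WC produces an hourly cosine pattern in
        the WC selection differential and leaves TRI flat."""
        truth = make_truth(
            beta_landscape={}, beta_within={}, delta_outside={},
            diel_amplitude={"WC": (1.2, "single")},
            n_individuals=4, fixes_per_individual=1200, seed=7,
        )
        tracks = simulate_tracks(land, truth, moon)
        from rsfkit.sampling import uniform_points_in_polygon
        from rsfkit.synthetic import local_hour
        from rsfkit.temporal import raised_cosine_regression

        diffs = {c: np.zeros(24) for c in ("WC", "TRI")}
        for t in tracks:
            ref = uniform_points_in_polygon(t.mcp, 3000, np.random.default_rng(2))
            avail = land.extract(ref[:, 0], ref[:, 1])
            used = land.extract(t.relocations["x"], t.relocations["y"])
            hours = local_hour(t.relocations["timestamp"].to_numpy())
            for c in diffs:
                sd = avail[c].std()
                for h in range(24):
                    diffs[c][h] += (used[c][hours == h].mean() - avail[c].mean()) / sd
        wc = raised_cosine_regression(diffs["WC"], "single")
        tri = raised_cosine_regression(diffs["TRI"], "single")
        assert wc.p < 1e-4 and wc.slope > 0
        assert tri.F < wc.F / 10


class TestTruthConfig:
    def test_yaml_round_trip(self, tmp_path):
        t = TruthConfig(
            n_individuals=3, fixes_per_individual=10,
            diel_amplitude={"WC": (0.5, "single")}, lunar_amplitude={"WC": -0.2},
        )
        p = tmp_path / "truth.yaml"
        t.to_yaml(p)
        t2 = TruthConfig.from_yaml(p)
        assert t2 == t

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            TruthConfig(beta_within={"XX": 1.0})

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(n_individuals=0)
        with pytest.raises(ValueError):
            TruthConfig(fix_interval_hours=0.0)


def test_tracks_csv_round_trip(tracks, land, tmp_path):
    from rsfkit.synthetic import tracks_from_csv, tracks_to_csv

    p = tmp_path / "tracks.csv"
    tracks_to_csv(tracks, p)
    back = tracks_from_csv(p, land)
    assert [t.individual_id for t in back] == [t.individual_id for t in tracks]
    for a, b in zip(tracks, back):
        assert b.n_fixes == a.n_fixes
        assert b.mcp.equals_exact(a.mcp, 1e-6)
        assert b.area_id in land.areas or b.area_id == a.area_id
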