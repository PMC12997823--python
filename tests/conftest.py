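"""Shared scaled study-world fixtures.

The scaled conditions (8 individuals x 1,000 hourly fixes on a 12 km /
60 m landscape, home-range kernel sigma 1.5 km truncated at 0.5 sigma)
are the package's standard test world; heavier experiments build their
own worlds locally.
"""

import warnings

import pytest
from shapely.geometry import box

from rsfkit import sampling
from rsfkit.covariates import synthetic_moon_series
from rsfkit.synthetic import TruthConfig, generate_landscape, simulate_tracks

EXTENT = (0.0, 0.0, 12_000.0, 12_000.0)
CELL = 60.0


@pytest.fixture(scope="session")
def land():
    return generate_landscape(EXTENT, cell_size=CELL, seed=1)


@pytest.fixture(scope="session")
def moon():
    return synthetic_moon_series("2016-04-20", "2018-03-01", new_moon_epoch="2016-04-27")


def make_truth(**kw) -> TruthConfig:
    base = dict(
        n_individuals=8,
        fixes_per_individual=1000,
        home_range_scale=1500.0,
        seed=42,
    )
    base.update(kw)
    return TruthConfig(**base)


@pytest.fixture(scope="session")
def tracks(land, moon):
    return simulate_tracks(land, make_truth(), moon)


@pytest.fixture(scope="session")
def sampled(land, moon, tracks):
    """Availability draws plus both analysis tables for the test world."""
    n_reloc = sum(t.n_fixes for t in tracks)
    n_avail = sampling.availability_count(n_reloc)
    counts = {t.individual_id: t.n_fixes for t in tracks}
    region_pts = sampling.draw_available(box(*EXTENT), n_avail, seed=7)
    mcp_pts = sampling.draw_available(
        {t.individual_id: t.mcp for t in tracks}, n_avail, seed=8, relocation_counts=counts
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        landscape_table, land_info = sampling.build_landscape_table(
            region_pts, mcp_pts, land, seed=9, relocation_counts=counts
        )
        homerange_table, hr_info = sampling.build_homerange_table(
            mcp_pts, tracks, land, moon, seed=10
        )
    return {
        "region_pts": region_pts,
        "mcp_pts": mcp_pts,
        "landscape": landscape_table,
        "landscape_info": land_info,
        "homerange": homerange_table,
        "homerange_info": hr_info,
        "counts": counts,
        "n_avail": n_avail,
    }
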