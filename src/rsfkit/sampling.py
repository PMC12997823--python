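"""Two-level use-availability sampling design.

Landscape level (second-order selection): available points are uniform
random draws across the study region; used points are a seeded 10%
subsample of uniform random points drawn within the individuals' 100%
MCPs (home-range placement is the "use" signal).

Home-range level (third-order selection): available points are all MCP
random points (counts proportional to each individual's relocations);
used points are a seeded 1/24 subsample of all relocations.

Hourly tables: for each local hour h, available = all MCP random points,
used = every relocation whose local hour is h, giving 24 split designs
that are disjoint and exhaustive in the used rows.

The total number of random points follows the published rule: ten times
the average number of relocations per hour of day, i.e.
``round(10 * n_relocations / 24)``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .covariates import MoonSeries, season_of
from .synthetic import COVARIATES, Landscape, Track, local_hour, LOCAL_UTC_OFFSET_HOURS

__all__ = [
    "availability_count",
    "draw_available",
    "uniform_points_in_polygon",
    "build_landscape_table",
    "build_homerange_table",
    "build_hourly_tables",
    "TABLE_COLUMNS",
]

#: canonical use-availability table column order (CSV round-trip)
TABLE_COLUMNS = [
    "response", "WC", "SVD", "NDVI", "ProxW", "TRI",
    "in_out", "moon_pct", "hour", "season", "year",
    "area_id", "individual_id", "level",
]


def availability_count(n_relocations: int) -> int:
    """Random points to draw: round(10 * n / 24), half rounded to even.

    For the published 211,767 relocations this is 10 x 8823.6 = 88,236.
    """
    if n_relocations < 0:
        raise ValueError("relocation count must be non-negative")
    return int(round(10.0 * n_relocations / 24.0))


def uniform_points_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    """n uniform points inside a polygon (rejection from the bounding box)."""
    if n == 0:
        return np.empty((0, 2))
    if poly.area <= 0:
        raise ValueError("cannot draw points in a zero-area polygon")
    xmin, ymin, xmax, ymax = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(int(1.5 * (n - len(pts)) * (xmax - xmin) * (ymax - ymin) / poly.area), 64)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        inside = shapely.covers(poly, shapely.points(cand[:, 0], cand[:, 1]))
        pts = np.vstack([pts, cand[inside]])
    return pts[:n]


def _proportional_counts(weights: Sequence[float], n: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to n
    (largest-remainder method)."""
    w = np.asarray(weights, dtype=float)
    exact = n * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:rem]] += 1
    return base


def draw_available(
    region: Polygon | Mapping[str, Polygon],
    n: int,
    seed: int,
    relocation_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Draw uniform random available points.

    With a single polygon, points are uniform over the study region and
    the frame has columns x, y. With a mapping individual -> MCP
    polygon, per-individual counts are proportional to
    ``relocation_counts`` (balanced design) and the frame carries
    ``individual_id``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(region, Polygon):
        pts = uniform_points_in_polygon(region, n, rng)
        return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
    ids = list(region)
    if relocation_counts is None:
        weights = [1.0] * len(ids)
    else:
        weights = [relocation_counts[i] for i in ids]
    counts = _proportional_counts(weights, n)
    frames = []
    for ind, c in zip(ids, counts):
        pts = uniform_points_in_polygon(region[ind], int(c), rng)
        frames.append(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "individual_id": ind}))
    return pd.concat(frames, ignore_index=True)


def _finalize(df: pd.DataFrame, level: str) -> tuple[pd.DataFrame, int]:
    """Order columns, drop rows with missing covariates, count the drops."""
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["level"] = level
    n0 = len(df)
    df = df.dropna(subset=list(COVARIATES)).reset_index(drop=True)
    return df[TABLE_COLUMNS], n0 - len(df)


def _extract_at(land: Landscape, x, y, season=None) -> pd.DataFrame:
    cov = land.extract(x, y, season=season)
    cov["in_out"] = np.where(land.in_core(x, y), "inside", "outside")
    cov["area_id"] = land.area_of(x, y)
    cov["x"] = np.asarray(x, float)
    cov["y"] = np.asarray(y, float)
    return cov


def build_landscape_table(
    region_points: pd.DataFrame,
    mcp_points: pd.DataFrame,
    land: Landscape,
    seed: int,
    used_fraction: float = 0.10,
    relocation_counts: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Landscape-level table: all region points available, a seeded 10%
    subsample of the MCP points used.

    Available rows carry season-free NDVI (mean of the seasonal layers;
    no timestamp exists at this level) and are assigned individual ids
    proportional to relocation counts so the individual random intercept
    has support on every row.
    """
    if len(region_points) == 0 or len(mcp_points) == 0:
        raise ValueError("both point sets must be non-empty")
    rng = np.random.default_rng(seed)
    n_used = int(round(used_fraction * len(mcp_points)))
    if n_used == 0:
        raise ValueError("used subsample is empty; increase the MCP point count")
    idx = rng.choice(len(mcp_points), size=n_used, replace=False)
    used_pts = mcp_points.iloc[np.sort(idx)]

    avail = _extract_at(land, region_points["x"].to_numpy(), region_points["y"].to_numpy())
    avail["response"] = 0
    if "individual_id" in region_points.columns:
        avail["individual_id"] = region_points["individual_id"].to_numpy()
    elif relocation_counts:
        ids = list(relocation_counts)
        w = np.array([relocation_counts[i] for i in ids], dtype=float)
        avail["individual_id"] = rng.choice(ids, size=len(avail), p=w / w.sum())
    else:
        avail["individual_id"] = "pooled"

    used = _extract_at(land, used_pts["x"].to_numpy(), used_pts["y"].to_numpy())
    used["response"] = 1
    used["individual_id"] = used_pts["individual_id"].to_numpy()

    table = pd.concat([avail, used], ignore_index=True)
    table, dropped = _finalize(table, "landscape")
    info = {
        "level": "landscape",
        "n_available": int((table["response"] == 0).sum()),
        "n_used": int((table["response"] == 1).sum()),
        "n_dropped_nodata": int(dropped),
        "seed": seed,
    }
    return table, info


def _pooled_relocations(tracks: Sequence[Track]) -> pd.DataFrame:
    return pd.concat(
        [t.relocations.assign(individual_id=t.individual_id) for t in tracks],
        ignore_index=True,
    )


def _temporal_columns(df: pd.DataFrame, moon: MoonSeries) -> pd.DataFrame:
    ts = pd.DatetimeIndex(df["timestamp"])
    tloc = ts + pd.Timedelta(hours=LOCAL_UTC_OFFSET_HOURS)
    df = df.copy()
    df["hour"] = tloc.hour
    df["season"] = [season_of(t) for t in tloc]
    df["year"] = tloc.year
    df["moon_pct"] = np.asarray(moon.at(ts), dtype=float)
    return df


def _available_block(
    mcp_points: pd.DataFrame,
    tracks: Sequence[Track],
    land: Landscape,
    moon: MoonSeries,
    seed: int,
    ndvi_season: str = "timestamp",
) -> pd.DataFrame:
    """Available rows for home-range / hourly designs.

    Each random point inherits a timestamp drawn uniformly (seeded) from
    its individual's relocation timestamps, which supplies calibrated
    hour / season / year / moon values. By default NDVI is taken from
    the seasonal layer of that sampled timestamp, matching the seasonal
    NDVI distribution of the used rows; ``ndvi_season="midpoint"``
    instead uses the season containing the midpoint of the individual's
    tracking period for all of its available rows.
    """
    rng = np.random.default_rng(seed)
    frames = []
    by_track = {t.individual_id: t for t in tracks}
    for ind, grp in mcp_points.groupby("individual_id", sort=True):
        tr = by_track[ind]
        ts = pd.DatetimeIndex(tr.relocations["timestamp"])
        draw = ts[rng.integers(0, len(ts), size=len(grp))]
        if ndvi_season == "midpoint":
            mid = ts[0] + (ts[-1] - ts[0]) / 2 + pd.Timedelta(hours=LOCAL_UTC_OFFSET_HOURS)
            seas = season_of(mid)
        else:
            tloc = draw + pd.Timedelta(hours=LOCAL_UTC_OFFSET_HOURS)
            seas = np.array([season_of(t) for t in tloc], dtype=object)
        block = _extract_at(
            land, grp["x"].to_numpy(), grp["y"].to_numpy(), season=seas
        )
        block["timestamp"] = draw
        block = _temporal_columns(block, moon)
        block["individual_id"] = ind
        block["response"] = 0
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def _used_block(relocs: pd.DataFrame, land: Landscape, moon: MoonSeries) -> pd.DataFrame:
    df = _temporal_columns(relocs, moon)
    block = _extract_at(
        land, df["x"].to_numpy(), df["y"].to_numpy(), season=df["season"].to_numpy()
    )
    for col in ("timestamp", "hour", "season", "year", "moon_pct", "individual_id"):
        block[col] = df[col].to_numpy()
    block["response"] = 1
    return block


def build_homerange_table(
    mcp_points: pd.DataFrame,
    tracks: Sequence[Track],
    land: Landscape,
    moon: MoonSeries,
    seed: int,
    used_fraction: float = 1.0 / 24.0,
    ndvi_season: str = "timestamp",
) -> tuple[pd.DataFrame, dict]:
    """Home-range-level table: all MCP random points available, a seeded
    1/24 subsample of all relocations used."""
    rng = np.random.default_rng(seed)
    relocs = _pooled_relocations(tracks)
    n_used = int(round(used_fraction * len(relocs)))
    idx = np.sort(rng.choice(len(relocs), size=n_used, replace=False))
    used = _used_block(relocs.iloc[idx], land, moon)
    avail = _available_block(mcp_points, tracks, land, moon, seed + 1,
                             ndvi_season=ndvi_season)
    table = pd.concat([avail, used], ignore_index=True)
    table, dropped = _finalize(table, "homerange")
    info = {
        "level": "homerange",
        "n_available": int((table["response"] == 0).sum()),
        "n_used": int((table["response"] == 1).sum()),
        "n_relocations": int(len(relocs)),
        "n_dropped_nodata": int(dropped),
        "seed": seed,
    }
    return table, info


def build_hourly_tables(
    mcp_points: pd.DataFrame,
    tracks: Sequence[Track],
    land: Landscape,
    moon: MoonSeries,
    seed: int = 0,
    ndvi_season: str = "timestamp",
) -> dict[int, pd.DataFrame]:
    """24 split designs: per local hour h, available = all MCP random
    points, used = every relocation whose (floored) local hour is h.

    Raises if any hour has no relocations, naming the hour.
    """
    relocs = _pooled_relocations(tracks)
    hours = local_hour(relocs["timestamp"].to_numpy())
    avail = _available_block(mcp_points, tracks, land, moon, seed + 1,
                             ndvi_season=ndvi_season)
    avail, _ = _finalize(avail, "hourly")
    tables = {}
    for h in range(24):
        sel = hours == h
        if not sel.any():
            raise ValueError(f"no relocations at hour {h}")
        used = _used_block(relocs.loc[sel], land, moon)
        used, _ = _finalize(used, "hourly")
        tables[h] = pd.concat([avail, used], ignore_index=True)
    return tables
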