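"""Synthetic landscape and GPS-track generator with known selection truth.

The generator realizes the generative model the use-availability RSF
design estimates, so every downstream stage (sampling, GLMM fitting,
model selection, cross-validation, diel/lunar analysis) can be tested by
parameter recovery without any external data:

* home-range centres are placed over the landscape with probability
  proportional to ``exp(beta_landscape . zbar)`` of the local (disc-mean)
  standardized covariates — second-order selection;
* given a centre, hourly "used" locations are drawn within a truncated
  Gaussian home-range kernel with weight ``exp(b(t) . z)``, where
  ``b(t) = beta_within + delta_outside*[outside core] + diel + lunar``
  modulation at the fix's local hour and moon illumination — third-order
  selection. Draws are independent given the range (a point-process RSF,
  not a mechanistic step model), which makes likelihood-based recovery
  exact.

Selection coefficients are expressed per landscape standard deviation of
each covariate (the generator standardizes covariates over the full
landscape before weighting).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import signal
from shapely.geometry import MultiPoint, Polygon, box

from .covariates import (
    SEASONS,
    CovariateGrid,
    MoonSeries,
    proximity_to_water,
    season_of,
    shannon_focal,
    synthetic_moon_series,
    terrain_ruggedness,
)
from .temporal import double_raised_cosine, single_raised_cosine

__all__ = [
    "COVARIATES",
    "TruthConfig",
    "Track",
    "Landscape",
    "generate_landscape",
    "simulate_tracks",
    "mcp",
    "mcp_area_km2",
    "local_hour",
    "LOCAL_UTC_OFFSET_HOURS",
]

#: the five analysis covariates, in canonical order
COVARIATES = ("WC", "SVD", "NDVI", "ProxW", "TRI")

#: fixed local solar-time offset of the synthetic study region
LOCAL_UTC_OFFSET_HOURS = 3


def local_hour(timestamps) -> np.ndarray:
    """Integer local solar hour (floor of clock hour, UTC+3)."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    return ((ts.hour + LOCAL_UTC_OFFSET_HOURS) % 24).to_numpy()


# ---------------------------------------------------------------------
# Truth configuration
# ---------------------------------------------------------------------

def _cov_map(value) -> dict[str, float]:
    out = {c: 0.0 for c in COVARIATES}
    if value:
        for k, v in dict(value).items():
            if k not in out:
                raise KeyError(f"unknown covariate {k!r}")
            out[k] = float(v)
    return out


@dataclasses.dataclass
class TruthConfig:
    """Ground-truth simulation parameters.

    Coefficients are per landscape standard deviation of each covariate.
    ``diel_amplitude`` maps covariate -> (amplitude, template) where the
    template is ``"single"`` (raised cosine peaking at local noon) or
    ``"double"`` (peaks at 06:00/18:00); the within-range coefficient of
    that covariate is ``beta + amplitude * template(hour)``.
    ``lunar_amplitude`` maps covariate -> slope per unit moon fraction
    (moon illumination percent / 100).
    """

    beta_landscape: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"WC": 0.5, "NDVI": 0.4, "ProxW": -0.5, "TRI": -0.2}
    )
    beta_within: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "WC": -0.35, "SVD": 0.40, "NDVI": 0.30, "ProxW": 0.25, "TRI": 0.30,
        }
    )
    delta_outside: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"WC": 0.50, "SVD": 0.30, "ProxW": 0.45, "TRI": -0.45}
    )
    diel_amplitude: Mapping[str, tuple[float, str]] = dataclasses.field(default_factory=dict)
    lunar_amplitude: Mapping[str, float] = dataclasses.field(default_factory=dict)
    n_individuals: int = 36
    fixes_per_individual: int = 5000
    fix_interval_hours: float = 1.0
    home_range_scale: float = 4500.0
    truncation_sigmas: float = 0.5
    start_window: tuple[str, str] = ("2016-04-27", "2017-06-01")
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.fix_interval_hours <= 0:
            raise ValueError("fix_interval must be positive")
        self.beta_landscape = _cov_map(self.beta_landscape)
        self.beta_within = _cov_map(self.beta_within)
        self.delta_outside = _cov_map(self.delta_outside)
        self.diel_amplitude = {
            k: (float(a), t) for k, (a, t) in dict(self.diel_amplitude).items()
        }
        self.lunar_amplitude = {k: float(v) for k, v in dict(self.lunar_amplitude).items()}
        for m in (self.diel_amplitude, self.lunar_amplitude):
            for k in m:
                if k not in COVARIATES:
                    raise KeyError(f"unknown covariate {k!r}")
        vals = list(self.beta_landscape.values()) + list(self.beta_within.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("selection coefficients must be finite")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["start_window"] = list(self.start_window)
        d["diel_amplitude"] = {k: [a, t] for k, (a, t) in self.diel_amplitude.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TruthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "diel_amplitude" in d:
            d["diel_amplitude"] = {k: (v[0], v[1]) for k, v in d["diel_amplitude"].items()}
        if "start_window" in d:
            d["start_window"] = tuple(d["start_window"])
        return cls(**d)


@dataclasses.dataclass
class Track:
    """One individual's relocations plus its 100% MCP home range."""

    individual_id: str
    relocations: pd.DataFrame  # columns: timestamp, x, y
    mcp: Polygon
    area_id: str
    centre: tuple[float, float] | None = None

    @property
    def n_fixes(self) -> int:
        return len(self.relocations)

    @property
    def mcp_area_km2(self) -> float:
        return self.mcp.area / 1e6


# ---------------------------------------------------------------------
# Landscape bundle
# ---------------------------------------------------------------------

@dataclasses.dataclass
class Landscape:
    """Aligned covariate grids plus the protected-core / management polygons.

    ``standardization`` holds the landscape-wide (mean, sd) per analysis
    covariate (NDVI pooled over seasons); the simulator's selection
    coefficients act on these standardized values.
    """

    grids: dict[str, CovariateGrid]
    core: Polygon
    areas: dict[str, Polygon]
    standardization: dict[str, tuple[float, float]]

    @property
    def cell_size(self) -> float:
        return self.grids["WC"].cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.grids["WC"].extent

    def grid(self, cov: str, season: str | None = None) -> CovariateGrid:
        if cov == "NDVI":
            return self.grids[f"NDVI_{season}"]
        return self.grids[cov]

    def z_values(self, cov: str, season: str | None = None) -> np.ndarray:
        """Standardized covariate array."""
        m, s = self.standardization[cov]
        return (self.grid(cov, season).values - m) / s

    def in_core(self, x, y) -> np.ndarray:
        """True where points fall inside (or on the boundary of) the core."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.core, pts)

    def area_of(self, x, y) -> np.ndarray:
        """Management-area id containing each point."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        pts = shapely.points(x, y)
        out = np.array(["none"] * len(x), dtype=object)
        for name, poly in self.areas.items():
            hit = shapely.covers(poly, pts) & (out == "none")
            out[hit] = name
        return out

    def extract(self, x, y, season=None) -> pd.DataFrame:
        """Raw covariate values at points (nearest cell).

        ``season`` may be None (season-free NDVI: mean of the seasonal
        layers), a single label, or an array of per-point labels.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        out = {}
        for cov in COVARIATES:
            if cov != "NDVI":
                out[cov] = self.grids[cov].value_at(x, y)
        if season is None:
            nd = np.mean(
                [self.grids[f"NDVI_{s}"].value_at(x, y) for s in SEASONS], axis=0
            )
        elif np.isscalar(season) or isinstance(season, str):
            nd = self.grids[f"NDVI_{season}"].value_at(x, y)
        else:
            season = np.asarray(season, dtype=object)
            nd = np.full(len(x), np.nan)
            for s in SEASONS:
                sel = season == s
                if sel.any():
                    nd[sel] = self.grids[f"NDVI_{s}"].value_at(x[sel], y[sel])
        out["NDVI"] = np.atleast_1d(nd)
        return pd.DataFrame(out)[list(COVARIATES)]


def _smooth_field(rng, shape, corr_cells: float) -> np.ndarray:
    """Standardized Gaussian random field with ~corr_cells correlation length."""
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(
    extent: tuple[float, float, float, float],
    cell_size: float = 30.0,
    seed: int = 0,
    n_classes: int = 5,
    corr_cells: float = 3.0,
    shannon_radius: float = 1000.0,
) -> Landscape:
    """Generate an aligned covariate bundle with protected-core structure.

    The extent is split into a strictly protected western core (the
    park stand-in) and three eastern buffer management areas; rivers are
    meandering west-east polylines. TRI, SVD and ProxW are derived from
    the generated DEM, land cover and river mask through the covariate
    operations, exactly as for real inputs.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax - xmin < 10_000 or ymax - ymin < 10_000:
        raise ValueError("extent must be at least 10 x 10 km")
    nx = int(round((xmax - xmin) / cell_size))
    ny = int(round((ymax - ymin) / cell_size))
    rng = np.random.default_rng(seed)

    def make(name, values, **kw):
        return CovariateGrid(name=name, origin=(xmin, ymin), cell_size=cell_size,
                             values=values, **kw)

    # woody cover: smooth percent field in (0, 100)
    wc = make("WC", 100.0 / (1.0 + np.exp(-1.2 * _smooth_field(rng, (ny, nx), corr_cells))))
    # elevation
    dem = make("DEM", 1200.0 + 80.0 * _smooth_field(rng, (ny, nx), 2 * corr_cells))
    # land cover: quantile slices of a smooth field -> contiguous patches
    lcf = _smooth_field(rng, (ny, nx), corr_cells)
    edges = np.quantile(lcf, np.linspace(0, 1, n_classes + 1)[1:-1])
    landcover = make("LANDCOVER", np.digitize(lcf, edges).astype(float), categorical=True)
    # seasonal NDVI: shared base + seasonal offset + seasonal texture
    base = _smooth_field(rng, (ny, nx), corr_cells)
    offsets = {"short_dry": -0.03, "long_rain": 0.08, "long_dry": -0.08, "short_rain": 0.03}
    ndvi = {
        s: make(
            f"NDVI_{s}",
            np.clip(0.40 + 0.20 * base + offsets[s]
                    + 0.05 * _smooth_field(rng, (ny, nx), corr_cells), -1.0, 1.0),
            season_tag=s,
        )
        for s in SEASONS
    }
    # rivers and small drainages: meandering west-east polylines, dense
    # enough that every home range lies near some drainage (as in a
    # 1:50,000-scale hydrography layer)
    river = np.zeros((ny, nx))
    n_rivers = max(3, ny // 28)
    for k in range(n_rivers):
        row = (k + rng.uniform(0.2, 0.8)) / n_rivers * ny
        walk = np.cumsum(rng.normal(0, 0.6, nx))
        rows = np.clip(np.round(row + walk - walk.mean()).astype(int), 0, ny - 1)
        river[rows, np.arange(nx)] = 1.0
    river_grid = make("RIVER", river, categorical=True)

    tri = terrain_ruggedness(dem)
    svd = shannon_focal(landcover, radius=shannon_radius)
    proxw = proximity_to_water(river_grid)

    grids = {"WC": wc, "DEM": dem, "LANDCOVER": landcover, "RIVER": river_grid,
             "TRI": tri, "SVD": svd, "ProxW": proxw}
    grids.update({f"NDVI_{s}": g for s, g in ndvi.items()})

    # protected core = western 55 %, three buffer areas tile the east
    xsplit = xmin + 0.55 * (xmax - xmin)
    core = box(xmin, ymin, xsplit, ymax)
    h3 = (ymax - ymin) / 3.0
    areas = {
        "SNP": core,
        "buffer_S": box(xsplit, ymin, xmax, ymin + h3),
        "buffer_C": box(xsplit, ymin + h3, xmax, ymin + 2 * h3),
        "buffer_N": box(xsplit, ymin + 2 * h3, xmax, ymax),
    }

    standardization = {}
    for cov in COVARIATES:
        if cov == "NDVI":
            pooled = np.concatenate([ndvi[s].values.ravel() for s in SEASONS])
        else:
            pooled = grids[cov].values.ravel()
        pooled = pooled[np.isfinite(pooled)]
        standardization[cov] = (float(pooled.mean()), float(pooled.std()))

    return Landscape(grids=grids, core=core, areas=areas, standardization=standardization)


# ---------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------

def mcp(points) -> Polygon:
    """100% minimum convex polygon (convex hull) of the points.

    Requires at least three non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("MCP requires at least 3 points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("MCP requires at least 3 non-collinear points")
    return hull


def mcp_area_km2(points) -> float:
    return mcp(points).area / 1e6


# ---------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------

def _modulated_betas(truth: TruthConfig, hours: np.ndarray, moon_pct: np.ndarray) -> np.ndarray:
    """(n_fix, n_cov) within-range coefficients b(t) before the InOut shift."""
    b = np.tile([truth.beta_within[c] for c in COVARIATES], (len(hours), 1))
    for k, (amp, template) in truth.diel_amplitude.items():
        r = single_raised_cosine(hours) if template == "single" else double_raised_cosine(hours)
        b[:, COVARIATES.index(k)] += amp * r
    for k, slope in truth.lunar_amplitude.items():
        b[:, COVARIATES.index(k)] += slope * moon_pct / 100.0
    return b


def simulate_tracks(
    land: Landscape,
    truth: TruthConfig,
    moon: MoonSeries | None = None,
    max_rounds: int = 400,
) -> list[Track]:
    """Simulate GPS-like tracks under the ground-truth RSF.

    Used points are drawn by rejection sampling: proposals come from the
    truncated-Gaussian home-range kernel, and a proposal at covariates z
    is accepted with probability exp(b(t).z - s_max), where s_max is the
    exact maximum of the selection score over the kernel disc for that
    fix. Raises if acceptance collapses (selection coefficients too
    extreme), naming the offending coefficient.
    """
    rng = np.random.default_rng(truth.seed)
    xmin, ymin, xmax, ymax = land.extent
    cs = land.cell_size
    sigma = truth.home_range_scale
    radius = truth.truncation_sigmas * sigma

    t_lo = pd.Timestamp(truth.start_window[0])
    t_hi = pd.Timestamp(truth.start_window[1])
    if moon is None:
        moon = synthetic_moon_series(
            t_lo - pd.Timedelta(days=2),
            t_hi + pd.Timedelta(hours=truth.fix_interval_hours * truth.fixes_per_individual)
            + pd.Timedelta(days=2),
            new_moon_epoch=t_lo,
        )

    # -- second order: home-range centres ------------------------------
    ref = land.grids["WC"]
    xs, ys = ref.cell_centers()
    ny, nx = ref.shape
    disc = (lambda k: k / k.sum())(_disc(radius / cs))
    logit = np.zeros((ny, nx))
    for cov in COVARIATES:
        if truth.beta_landscape[cov] == 0.0:
            continue
        if cov == "NDVI":
            z = np.mean([land.z_values("NDVI", s) for s in SEASONS], axis=0)
        else:
            z = land.z_values(cov)
        zbar = signal.fftconvolve(z, disc, mode="same")
        logit += truth.beta_landscape[cov] * zbar
    # keep whole kernel disc inside the landscape
    margin = int(np.ceil(radius / cs)) + 1
    valid = np.zeros((ny, nx), dtype=bool)
    if ny <= 2 * margin or nx <= 2 * margin:
        raise ValueError("landscape too small for the home-range kernel radius")
    valid[margin:-margin, margin:-margin] = True
    w = np.where(valid, np.exp(logit - logit[valid].max()), 0.0).ravel()
    w /= w.sum()
    centre_cells = rng.choice(ny * nx, size=truth.n_individuals, p=w, replace=True)

    # precompute disc offsets (cell units)
    r_cells = int(np.ceil(radius / cs))
    dy, dx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    keep = np.hypot(dy, dx) * cs <= radius + cs  # cells the kernel can reach
    dy, dx = dy[keep], dx[keep]

    delta = np.array([truth.delta_outside[c] for c in COVARIATES])
    tracks = []
    for i, cell in enumerate(centre_cells):
        crow, ccol = divmod(cell, nx)
        cx, cy = xs[ccol], ys[crow]
        rows, cols = crow + dy, ccol + dx
        cell_x, cell_y = xs[cols], ys[rows]
        out_c = ~land.in_core(cell_x, cell_y)
        zc = {
            s: np.column_stack(
                [land.z_values(c, s)[rows, cols] for c in COVARIATES]
            )
            for s in SEASONS
        }

        start = t_lo + pd.Timedelta(seconds=float(rng.uniform(0, (t_hi - t_lo).total_seconds())))
        start = start.floor("h")
        times = start + pd.to_timedelta(
            np.arange(truth.fixes_per_individual) * truth.fix_interval_hours, unit="h"
        )
        hours = local_hour(times)
        moon_pct = np.asarray(moon.at(times), dtype=float)
        seasons = np.array([season_of(t) for t in times], dtype=object)
        b = _modulated_betas(truth, hours, moon_pct)

        # exact per-fix maximum of the score over the kernel disc
        smax = np.empty(len(times))
        for s in SEASONS:
            sel = seasons == s
            if sel.any():
                scores = zc[s] @ b[sel].T + ((zc[s] @ delta) * out_c)[:, None]
                smax[sel] = scores.max(axis=0)

        px = np.full(len(times), np.nan)
        py = np.full(len(times), np.nan)
        pending = np.arange(len(times))
        n_prop = 0
        n_acc = 0
        for _ in range(max_rounds):
            if pending.size == 0:
                break
            m = pending.size
            off = _truncated_gaussian_offsets(rng, m, sigma, radius)
            ok = np.ones(m, dtype=bool)
            qx, qy = cx + off[:, 0], cy + off[:, 1]
            col = np.floor((qx - xmin) / cs).astype(int)
            row = np.floor((qy - ymin) / cs).astype(int)
            zrow = np.zeros((m, len(COVARIATES)))
            outq = np.zeros(m, dtype=bool)
            inb = ok  # inside landscape guaranteed by the margin when ok
            if inb.any():
                outq[inb] = ~land.in_core(qx[inb], qy[inb])
                for s in SEASONS:
                    ssel = inb & (seasons[pending] == s)
                    if ssel.any():
                        zrow[ssel] = np.column_stack(
                            [land.z_values(c, s)[row[ssel], col[ssel]] for c in COVARIATES]
                        )
            score = np.einsum("ij,ij->i", b[pending], zrow) + (zrow @ delta) * outq
            accept = ok & (np.log(rng.uniform(size=m)) < score - smax[pending])
            n_prop += m
            n_acc += int(accept.sum())
            idx = pending[accept]
            px[idx], py[idx] = qx[accept], qy[accept]
            pending = pending[~accept]
        if pending.size:
            rate = n_acc / max(n_prop, 1)
            ranges = {
                c: max(
                    abs(b[:, j].max()), abs(b[:, j].min()), abs(delta[j])
                ) * (zc["long_rain"][:, j].max() - zc["long_rain"][:, j].min())
                for j, c in enumerate(COVARIATES)
            }
            worst = max(ranges, key=ranges.get)
            raise RuntimeError(
                f"rejection-sampling acceptance collapsed (rate {rate:.2e}); "
                f"coefficient on {worst} is too extreme"
            )

        rel = pd.DataFrame({"timestamp": times, "x": px, "y": py})
        hull = mcp(np.column_stack([px, py]))
        area_id = str(land.area_of(cx, cy)[0])
        tracks.append(Track(individual_id=f"ind{i + 1:02d}", relocations=rel,
                            mcp=hull, area_id=area_id, centre=(float(cx), float(cy))))
    return tracks


def _truncated_gaussian_offsets(rng, m: int, sigma: float, radius: float) -> np.ndarray:
    """m draws from an isotropic Gaussian truncated at ``radius``."""
    out = np.empty((0, 2))
    while len(out) < m:
        cand = rng.standard_normal((max(2 * m, 64), 2)) * sigma
        out = np.vstack([out, cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]])
    return out[:m]


def _disc(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(dy, dx) <= radius_cells).astype(float)


def tracks_to_csv(tracks: Sequence[Track], path) -> None:
    """Write relocations as CSV (id, timestamp, x, y)."""
    pd.concat(
        [t.relocations.assign(individual_id=t.individual_id) for t in tracks]
    )[["individual_id", "timestamp", "x", "y"]].to_csv(path, index=False)


def tracks_from_csv(path, land: Landscape | None = None) -> list[Track]:
    """Read tracks back from CSV (id, timestamp, x, y), recomputing MCPs.

    If a landscape is given, area ids are re-derived from each MCP's
    centroid; otherwise they are left as "unknown".
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for ind, grp in df.groupby("individual_id", sort=True):
        rel = grp[["timestamp", "x", "y"]].sort_values("timestamp").reset_index(drop=True)
        hull = mcp(rel[["x", "y"]].to_numpy())
        area = "unknown"
        if land is not None:
            area = str(land.area_of(hull.centroid.x, hull.centroid.y)[0])
        tracks.append(Track(individual_id=str(ind), relocations=rel, mcp=hull, area_id=area))
    return tracks


def mcps_to_geojson(tracks: Sequence[Track], path) -> None:
    import json

    features = [
        {
            "type": "Feature",
            "properties": {"individual_id": t.individual_id, "area_id": t.area_id,
                           "area_km2": t.mcp_area_km2},
            "geometry": shapely.geometry.mapping(t.mcp),
        }
        for t in tracks
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
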