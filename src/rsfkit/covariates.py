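"""Covariate grids and their derivation.

All spatial covariates live on regular grids in a projected metre
coordinate system. Internally ``values[0, 0]`` is the *south-west* cell
(row index increases northwards); ESRI ASCII-grid files store rows
north-to-south and are flipped on read/write. Missing data is ``NaN``.

The five analysis covariates are:

``WC``
    percent woody cover, in [0, 100];
``TRI``
    terrain ruggedness index: root of the summed squared elevation
    differences between a cell and its (available) 8 neighbours;
``SVD``
    Shannon diversity of land-cover classes within a circular buffer;
``ProxW``
    Euclidean distance (m) to the nearest river/drainage cell;
``NDVI``
    seasonal greenness in [-1, 1] (one layer per season).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "CovariateGrid",
    "MoonSeries",
    "SEASONS",
    "SEASON_OF_MONTH",
    "season_of",
    "shannon_focal",
    "terrain_ruggedness",
    "proximity_to_water",
    "resample_to_common_grid",
    "synthetic_moon_series",
    "moon_at",
    "rasterize_lines",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Season labels in calendar order; each spans three consecutive months.
SEASONS = ("short_dry", "long_rain", "long_dry", "short_rain")

#: month (1-12) -> season. Jan-Mar short dry, Apr-Jun long rain,
#: Jul-Sep long dry, Oct-Dec short rain.
SEASON_OF_MONTH = {m: SEASONS[(m - 1) // 3] for m in range(1, 13)}


def season_of(timestamp) -> str:
    """Season label for a timestamp (pandas/py datetime or ISO string)."""
    ts = pd.Timestamp(timestamp)
    return SEASON_OF_MONTH[ts.month]


@dataclasses.dataclass
class CovariateGrid:
    """One covariate on a regular metre grid.

    Parameters
    ----------
    name : covariate label (``WC``, ``TRI``, ``SVD``, ``ProxW``, ``NDVI``,
        ``DEM``, ``LANDCOVER``, ``RIVER`` ...).
    origin : (x0, y0) of the grid's south-west corner, metres.
    cell_size : cell edge length in metres.
    values : 2-D float array, row 0 southernmost; NaN marks nodata.
    season_tag : optional season label (seasonal NDVI layers only).
    categorical : True for class-coded layers (LANDCOVER, RIVER masks).
    """

    name: str
    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    season_tag: str | None = None
    categorical: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid must be 2-D with at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        ny, nx = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of column / row centres."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point (may be out of range)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell lookup; NaN outside the grid."""
        row, col = self.index_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        ny, nx = self.shape
        ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.full(row.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out if out.size > 1 else float(out[0])

    def copy_with(self, name: str, values: np.ndarray, **kw) -> "CovariateGrid":
        return CovariateGrid(
            name=name,
            origin=self.origin,
            cell_size=self.cell_size,
            values=values,
            season_tag=kw.get("season_tag", None),
            categorical=kw.get("categorical", False),
        )


# ---------------------------------------------------------------------
# Focal / neighbourhood operations
# ---------------------------------------------------------------------

def _disc_kernel(radius_cells: float) -> np.ndarray:
    """0/1 kernel; a cell belongs iff its centre lies within the radius."""
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(dy, dx) <= radius_cells + 1e-9).astype(float)


def shannon_focal(
    landcover: CovariateGrid, radius: float = 1000.0, fractional: bool = False
) -> CovariateGrid:
    """Shannon diversity H = -sum p_k ln p_k of land-cover classes in a
    circular buffer around each cell.

    Membership is by cell centre within ``radius`` of the focal cell
    centre (``fractional=True`` weights boundary cells by the disc area
    overlapping the cell). Nodata cells are excluded from the
    proportions; a window with no valid cell yields nodata.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    vals = landcover.values
    if fractional:
        kernel = _fractional_disc_kernel(radius / landcover.cell_size)
    else:
        kernel = _disc_kernel(radius / landcover.cell_size)
    valid = np.isfinite(vals)
    classes = np.unique(vals[valid])
    total = signal.fftconvolve(valid.astype(float), kernel, mode="same")
    h = np.zeros_like(vals, dtype=float)
    for c in classes:
        count = signal.fftconvolve((vals == c).astype(float), kernel, mode="same")
        if not fractional:
            count = np.round(count)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.clip(count / np.maximum(total, 1e-12), 0.0, 1.0)
        term = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        h += term
    if not fractional:
        total = np.round(total)
    h[total < 0.5] = np.nan
    h = np.maximum(h, 0.0)
    return landcover.copy_with("SVD", h)


def _fractional_disc_kernel(radius_cells: float, sub: int = 8) -> np.ndarray:
    """Disc kernel with fractional-area weights via subcell sampling."""
    r = int(np.ceil(radius_cells)) + 1
    n = 2 * r + 1
    off = (np.arange(sub) + 0.5) / sub - 0.5
    ky = np.zeros((n, n))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    for oy in off:
        for ox in off:
            ky += (np.hypot(dy + oy, dx + ox) <= radius_cells).astype(float)
    return ky / sub**2


def terrain_ruggedness(dem: CovariateGrid) -> CovariateGrid:
    """Terrain ruggedness index: sqrt of the summed squared elevation
    differences between each cell and its 8 neighbours.

    Edge cells use the available neighbour subset; nodata neighbours are
    skipped and a nodata focal cell stays nodata. Adding a constant to
    the DEM leaves the result unchanged.
    """
    z = dem.values
    if min(z.shape) < 3:
        raise ValueError("DEM must be at least 3x3 cells")
    ny, nx = z.shape
    ssq = np.zeros((ny, nx))
    pad = np.full((ny + 2, nx + 2), np.nan)
    pad[1:-1, 1:-1] = z
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            nb = pad[1 + dy : ny + 1 + dy, 1 + dx : nx + 1 + dx]
            d = z - nb
            ssq += np.where(np.isfinite(d), d**2, 0.0)
    tri = np.sqrt(ssq)
    tri[~np.isfinite(z)] = np.nan
    return dem.copy_with("TRI", tri)


def proximity_to_water(rivers: CovariateGrid) -> CovariateGrid:
    """Centre-to-centre Euclidean distance (m) to the nearest river cell.

    ``rivers`` is a binary mask (1 = river/drainage). Raises if the mask
    contains no river cell.
    """
    mask = rivers.values == 1
    if not mask.any():
        raise ValueError("no water features in the river mask")
    dist = ndimage.distance_transform_edt(~mask, sampling=rivers.cell_size)
    return rivers.copy_with("ProxW", dist.astype(float))


# ---------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------

def resample_to_common_grid(
    grids: Sequence[CovariateGrid], cell_size: float = 30.0
) -> list[CovariateGrid]:
    """Resample all grids onto the intersection extent at ``cell_size``.

    Continuous layers are interpolated bilinearly, categorical layers by
    nearest neighbour. Raises if the extents are disjoint.
    """
    xmin = max(g.extent[0] for g in grids)
    ymin = max(g.extent[1] for g in grids)
    xmax = min(g.extent[2] for g in grids)
    ymax = min(g.extent[3] for g in grids)
    if xmax - xmin < cell_size or ymax - ymin < cell_size:
        raise ValueError("grid extents are disjoint (no common area to resample)")
    nx = int(np.floor((xmax - xmin) / cell_size))
    ny = int(np.floor((ymax - ymin) / cell_size))
    xc = xmin + (np.arange(nx) + 0.5) * cell_size
    yc = ymin + (np.arange(ny) + 0.5) * cell_size
    out = []
    for g in grids:
        # fractional source indices of the target cell centres
        ix = (xc - g.origin[0]) / g.cell_size - 0.5
        iy = (yc - g.origin[1]) / g.cell_size - 0.5
        cols, rows = np.meshgrid(ix, iy)
        order = 0 if g.categorical else 1
        vals = ndimage.map_coordinates(
            g.values, [rows, cols], order=order, mode="nearest"
        )
        out.append(
            CovariateGrid(
                name=g.name,
                origin=(xmin, ymin),
                cell_size=cell_size,
                values=vals,
                season_tag=g.season_tag,
                categorical=g.categorical,
            )
        )
    return out


def rasterize_lines(lines, template: CovariateGrid, name: str = "RIVER") -> CovariateGrid:
    """Rasterize polylines (e.g. a river network) onto a template grid.

    ``lines`` is a sequence of coordinate sequences ``[(x, y), ...]`` or
    a GeoJSON-like dict with LineString / MultiLineString geometries.
    Every cell a segment passes through (sampled at half-cell spacing)
    is marked 1; the result is a binary mask aligned with the template.
    """
    if isinstance(lines, dict):
        lines = _geojson_lines(lines)
    mask = np.zeros(template.shape)
    ny, nx = template.shape
    for coords in lines:
        coords = np.asarray(coords, dtype=float)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            n = max(int(np.hypot(x1 - x0, y1 - y0) / (template.cell_size / 2)), 1)
            t = np.linspace(0.0, 1.0, n + 1)
            row, col = template.index_of(x0 + t * (x1 - x0), y0 + t * (y1 - y0))
            ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
            mask[row[ok], col[ok]] = 1.0
    return template.copy_with(name, mask, categorical=True)


def _geojson_lines(obj) -> list:
    out = []
    feats = obj.get("features", [obj])
    for f in feats:
        geom = f.get("geometry", f)
        if geom.get("type") == "LineString":
            out.append(geom["coordinates"])
        elif geom.get("type") == "MultiLineString":
            out.extend(geom["coordinates"])
    return out


# ---------------------------------------------------------------------
# Moon illumination
# ---------------------------------------------------------------------

class MoonSeries:
    """Daily percent moon illumination, step-constant within a date.

    Built from a date-indexed series (CSV columns ``date``,
    ``illumination_pct``); every relocation timestamp queried must fall
    within the series span.
    """

    def __init__(self, series: pd.Series):
        s = pd.Series(series).copy()
        s.index = pd.DatetimeIndex(s.index).normalize()
        if ((s < 0) | (s > 100)).any():
            raise ValueError("illumination must be within [0, 100]")
        self._series = s.sort_index()

    @classmethod
    def from_csv(cls, path) -> "MoonSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(pd.Series(df["illumination_pct"].values, index=df["date"]))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"date": self._series.index.date, "illumination_pct": self._series.values}
        ).to_csv(path, index=False)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self._series.index[0], self._series.index[-1]

    def at(self, timestamps) -> np.ndarray:
        """Percent illumination on the date(s) of the given timestamps."""
        ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
        dates = ts.normalize()
        lo, hi = self.span
        if (dates < lo).any() or (dates > hi).any():
            raise ValueError("timestamp outside the moon-series span")
        out = self._series.reindex(dates).to_numpy()
        if np.isnan(out).any():
            raise ValueError("moon series has gaps at queried dates")
        return out if out.size > 1 else float(out[0])


#: mean synodic month length in days
SYNODIC_DAYS = 29.53


def synthetic_moon_series(
    start, end, new_moon_epoch, synodic_days: float = SYNODIC_DAYS
) -> MoonSeries:
    """Cosine illumination model: pct(t) = 50 * (1 - cos(2 pi (t-t0)/P)).

    0% at the new-moon epoch, 100% half a synodic period later; sampled
    once per date (at midnight) and step-constant within the day.
    """
    dates = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize(), freq="D")
    t0 = pd.Timestamp(new_moon_epoch)
    days = (dates - t0) / pd.Timedelta(days=1)
    pct = 50.0 * (1.0 - np.cos(2.0 * np.pi * days / synodic_days))
    return MoonSeries(pd.Series(np.clip(pct, 0, 100), index=dates))


def moon_at(series: MoonSeries, timestamp):
    """Convenience wrapper around :meth:`MoonSeries.at`."""
    return series.at(timestamp)


# ---------------------------------------------------------------------
# ASCII-grid I/O (ESRI .asc)
# ---------------------------------------------------------------------

def read_ascii_grid(path, name: str | None = None, **kw) -> CovariateGrid:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(lines[i:])
    vals = np.atleast_2d(vals)[::-1]  # file rows run north->south
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return CovariateGrid(
        name=name or "grid",
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=vals,
        **kw,
    )


def write_ascii_grid(grid: CovariateGrid, path, nodata: float = -9999.0) -> None:
    ny, nx = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"nodata_value {nodata}\n")
        vals = np.where(np.isfinite(grid.values), grid.values, nodata)
        np.savetxt(fh, vals[::-1], fmt="%.6g")
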