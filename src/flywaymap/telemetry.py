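"""Telemetry tables, map projection and the shared analysis grid.

Tracks are tabular: one row per fix with animal id, UTC timestamp,
WGS84 longitude/latitude, sensor type (ARGOS or GPS) and Argos location
class.  All downstream density estimation happens on a planar grid in an
equal-area projection, so that cell values can be read as probability
mass per cell; this module owns the projection and the grid geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("flywaymap")

# Authalic (equal-area) Earth radius, metres.
EARTH_RADIUS_M = 6_371_007.181

#: Argos location classes ordered best to worst; G denotes a GPS fix.
LOCATION_CLASSES = ("G", "3", "2", "1", "0", "A", "B", "Z")
CLASS_RANK = {c: i for i, c in enumerate(LOCATION_CLASSES)}

REQUIRED_COLUMNS = ("animal_id", "timestamp", "lon", "lat", "sensor", "location_class")
OPTIONAL_COLUMNS = ("species_code", "marking_site")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """One or more input rows could not be parsed."""


@dataclass
class TelemetryFix:
    """A single observed location.

    ``x``/``y`` are planar metres, filled by :func:`project_fixes`;
    ``error_sd`` is one isotropic positional standard deviation in
    metres, filled by the preprocessing error model.
    """

    animal_id: str
    timestamp: pd.Timestamp
    lon: float
    lat: float
    sensor: str
    location_class: str
    x: float = math.nan
    y: float = math.nan
    error_sd: float = math.nan


@dataclass
class Track:
    """All fixes of one animal, time-ordered, held as a DataFrame.

    Columns: ``animal_id, timestamp, lon, lat, sensor, location_class``
    plus ``x, y, error_sd`` once filled.
    """

    animal_id: str
    fixes: pd.DataFrame
    species_code: str = ""
    marking_site: str = ""

    def __post_init__(self) -> None:
        if len(self.fixes) and (self.fixes["animal_id"] != self.animal_id).any():
            raise ValueError(f"track {self.animal_id!r} contains foreign animal ids")

    def __len__(self) -> int:
        return len(self.fixes)

    def with_fixes(self, fixes: pd.DataFrame) -> "Track":
        return replace(self, fixes=fixes.reset_index(drop=True))

    def to_fix_list(self) -> list[TelemetryFix]:
        cols = self.fixes.columns
        out = []
        for row in self.fixes.itertuples(index=False):
            d = dict(zip(cols, row))
            out.append(
                TelemetryFix(
                    animal_id=d["animal_id"],
                    timestamp=d["timestamp"],
                    lon=d["lon"],
                    lat=d["lat"],
                    sensor=d["sensor"],
                    location_class=str(d["location_class"]),
                    x=d.get("x", math.nan),
                    y=d.get("y", math.nan),
                    error_sd=d.get("error_sd", math.nan),
                )
            )
        return out


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis raster.

    ``origin_x``/``origin_y`` are the coordinates of the lower-left
    corner of cell (row 0, col 0); rows increase with ``y``.  The
    projection centre ``(lon0, lat0)`` ties planar coordinates back to
    WGS84.  One ``GridSpec`` is built per analysis and every
    utilization distribution in that analysis shares it, so grids can
    be summed and compared cell-by-cell.
    """

    origin_x: float
    origin_y: float
    cell_side: float
    n_cols: int
    n_rows: int
    lon0: float
    lat0: float

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError("cell_side must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def cell_area(self) -> float:
        return self.cell_side**2

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_side

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_side

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map planar points to (row, col).

        Half-open cells: a point exactly on a shared edge belongs to
        the cell with the larger index (plain floor division).
        """
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_side).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_side).astype(int)
        return row, col

    def shifted(self, dx: float, dy: float) -> "GridSpec":
        return replace(self, origin_x=self.origin_x + dx, origin_y=self.origin_y + dy)


# ---------------------------------------------------------------------------
# Reading and writing tracks
# ---------------------------------------------------------------------------


def _empty_fix_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=list(REQUIRED_COLUMNS) + ["x", "y", "error_sd"]
    )


def read_tracks(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    on_bad_rows: str = "error",
) -> list[Track]:
    """Read a Movebank-style CSV into one :class:`Track` per animal.

    Parameters
    ----------
    path:
        CSV file with columns ``animal_id, timestamp, lon, lat, sensor,
        location_class`` (``species_code`` and ``marking_site``
        optional).  ``column_map`` renames input columns to these
        canonical names first, e.g. ``{"individual-local-identifier":
        "animal_id"}``.
    on_bad_rows:
        ``"error"`` raises :class:`RowError` naming the offending line
        numbers; ``"drop"`` logs and skips them.

    Rows are grouped by animal and sorted by timestamp.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"location_class": str})
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")

    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = ts.isna() | lon.isna() | lat.isna()
    bad |= ~lat.between(-90.0, 90.0) | ~((lon > -180.0) & (lon <= 180.0))
    if bad.any():
        bad_lines = lines[bad.to_numpy()].tolist()
        msg = f"{int(bad.sum())} malformed row(s) at line(s) {bad_lines[:20]}"
        if on_bad_rows == "error":
            raise RowError(msg + " (unparseable timestamp/coordinate or out of range)")
        logger.warning("read_tracks: dropping %s", msg)
        df, ts, lon, lat = df[~bad], ts[~bad], lon[~bad], lat[~bad]

    df = df.assign(timestamp=ts, lon=lon, lat=lat)
    df["animal_id"] = df["animal_id"].astype(str)
    df["sensor"] = df["sensor"].astype(str).str.upper()
    df["location_class"] = df["location_class"].astype(str).str.upper()
    for col in ("x", "y", "error_sd"):
        if col not in df.columns:
            df[col] = np.nan

    tracks = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        species = str(grp["species_code"].iloc[0]) if "species_code" in grp else ""
        site = str(grp["marking_site"].iloc[0]) if "marking_site" in grp else ""
        keep = list(REQUIRED_COLUMNS) + ["x", "y", "error_sd"]
        tracks.append(
            Track(animal_id=str(animal), fixes=grp[keep], species_code=species, marking_site=site)
        )
    return tracks


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks to CSV; a later :func:`read_tracks` round-trips them."""
    frames = []
    for tr in tracks:
        df = tr.fixes.copy()
        df["species_code"] = tr.species_code
        df["marking_site"] = tr.marking_site
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else _empty_fix_frame()
    if len(out):
        out = out.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Projection: spherical Lambert azimuthal equal-area
# ---------------------------------------------------------------------------


def laea_project(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Lambert azimuthal equal-area projection (spherical).

    Equal-area is essential here: it keeps "probability mass per grid
    cell" comparable across the map, which is the whole reading of a
    utilization distribution raster.
    """
    lam = np.radians(np.asarray(lon, dtype=float)) - math.radians(lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = math.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    kp = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_M * kp * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_M * kp * (
        math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(lam)
    )
    return x, y


def laea_unproject(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`laea_project`."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
    rho = np.hypot(x, y)
    phi0 = math.radians(lat0)
    with np.errstate(invalid="ignore"):
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        sin_c, cos_c = np.sin(c), np.cos(c)
        safe_rho = np.where(rho == 0.0, 1.0, rho)
        phi = np.arcsin(
            np.clip(cos_c * math.sin(phi0) + y * sin_c * math.cos(phi0) / safe_rho, -1.0, 1.0)
        )
        lam = np.arctan2(
            x * sin_c, safe_rho * math.cos(phi0) * cos_c - y * math.sin(phi0) * sin_c
        )
    phi = np.where(rho == 0.0, phi0, phi)
    lam = np.where(rho == 0.0, 0.0, lam)
    lon = np.degrees(lam) + lon0
    lon = (lon + 180.0) % 360.0 - 180.0
    lon = np.where(lon == -180.0, 180.0, lon)
    return lon, np.degrees(phi)


def geodesic_distance_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (haversine) in metres on the authalic sphere."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dphi, dlam = phi2 - phi1, lam2 - lam1
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(a))


def data_centroid(tracks: Iterable[Track]) -> tuple[float, float]:
    lons = np.concatenate([t.fixes["lon"].to_numpy(float) for t in tracks])
    lats = np.concatenate([t.fixes["lat"].to_numpy(float) for t in tracks])
    if lons.size == 0:
        raise ValueError("no fixes to take a centroid over")
    if lons.max() - lons.min() > 170.0:
        raise ValueError(
            "fixes span more than 170 degrees of longitude; a single azimuthal "
            "projection is unreliable at that extent - split the data per flyway"
        )
    return float(lons.mean()), float(lats.mean())


def project_fixes(
    tracks: Sequence[Track], center: tuple[float, float] | None = None
) -> tuple[list[Track], tuple[float, float]]:
    """Fill planar ``x, y`` (metres) on every fix.

    The projection is Lambert azimuthal equal-area centred on the
    centroid of all fixes (or an explicit ``center``).  Returns the
    projected tracks and the centre used, which must be carried into
    :func:`make_grid` so rasters and contours can be georeferenced.
    """
    lon0, lat0 = center if center is not None else data_centroid(tracks)
    out = []
    for tr in tracks:
        df = tr.fixes.copy()
        x, y = laea_project(df["lon"].to_numpy(float), df["lat"].to_numpy(float), lon0, lat0)
        df["x"], df["y"] = x, y
        out.append(tr.with_fixes(df))
    return out, (lon0, lat0)


# ---------------------------------------------------------------------------
# The shared grid
# ---------------------------------------------------------------------------


def make_grid(
    tracks: Sequence[Track],
    cell_area_km2: float = 10.0,
    pad_m: float | None = None,
    cell_side_km: float | None = None,
    center: tuple[float, float] | None = None,
) -> GridSpec:
    """Build the shared analysis grid covering every projected fix.

    ``cell_area_km2`` sets the cell AREA (default 10 km^2, i.e. a side
    of sqrt(10) km ~ 3162.28 m).  If the alternative reading of grid
    resolution as a cell side length is wanted, pass ``cell_side_km``
    instead, which takes precedence.

    ``pad_m`` pads the bounding box of the fixes on every side so that
    bridge densities do not leak off the raster; the default is
    ``max(4 x max(error_sd), 20 km)`` (four positional standard
    deviations, with a floor that covers typical between-fix bridge
    spread at migration gaps).
    """
    tracks = list(tracks)
    if not tracks or all(len(t) == 0 for t in tracks):
        raise ValueError("make_grid needs at least one track with fixes")
    xs = np.concatenate([t.fixes["x"].to_numpy(float) for t in tracks])
    ys = np.concatenate([t.fixes["y"].to_numpy(float) for t in tracks])
    if np.isnan(xs).any():
        raise ValueError("fixes are not projected; call project_fixes first")
    if cell_side_km is not None:
        side = cell_side_km * 1000.0
    else:
        side = math.sqrt(cell_area_km2) * 1000.0
    if pad_m is None:
        errs = np.concatenate([t.fixes["error_sd"].to_numpy(float) for t in tracks])
        max_err = np.nanmax(errs) if np.isfinite(errs).any() else 0.0
        pad_m = max(4.0 * max_err, 20_000.0)
    x0, x1 = xs.min() - pad_m, xs.max() + pad_m
    y0, y1 = ys.min() - pad_m, ys.max() + pad_m
    n_cols = max(1, math.ceil((x1 - x0) / side))
    n_rows = max(1, math.ceil((y1 - y0) / side))
    if center is None:
        lon0, lat0 = data_centroid(tracks)
    else:
        lon0, lat0 = center
    return GridSpec(
        origin_x=float(x0),
        origin_y=float(y0),
        cell_side=float(side),
        n_cols=int(n_cols),
        n_rows=int(n_rows),
        lon0=float(lon0),
        lat0=float(lat0),
    )


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid — plain text)
# ---------------------------------------------------------------------------


def write_ascii_grid(mass: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a cell-mass raster as an ESRI ASCII grid (row 0 at the top)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x:.6f}\n"
        f"yllcorner {grid.origin_y:.6f}\n"
        f"cellsize {grid.cell_side:.6f}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, mass[::-1], fmt="%.10e")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid back into (mass array, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        mass = np.loadtxt(fh)
    mass = np.atleast_2d(mass)[::-1]
    return mass, header
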