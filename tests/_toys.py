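"""Small programmatic fixtures shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from flywaymap import GridSpec, Track, UtilizationDistribution
from flywaymap.preprocessing import MigrationEvent, Season

T0 = pd.Timestamp("2010-01-01", tz="UTC")


def fix_frame(times_s, lon=None, lat=None, x=None, y=None, err=None,
              sensor="GPS", classes=None, animal="toy"):
    n = len(times_s)
    df = pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": T0 + pd.to_timedelta(np.asarray(times_s, dtype=float), unit="s"),
            "lon": np.zeros(n) if lon is None else np.asarray(lon, dtype=float),
            "lat": np.zeros(n) if lat is None else np.asarray(lat, dtype=float),
            "sensor": sensor,
            "location_class": ["G"] * n if classes is None else list(classes),
            "x": np.full(n, np.nan) if x is None else np.asarray(x, dtype=float),
            "y": np.full(n, np.nan) if y is None else np.asarray(y, dtype=float),
            "error_sd": np.full(n, np.nan) if err is None else np.broadcast_to(
                np.asarray(err, dtype=float), (n,)
            ).copy(),
        }
    )
    return df


def planar_event(times_s, x, y, err, animal="toy") -> MigrationEvent:
    df = fix_frame(times_s, x=x, y=y, err=err, animal=animal)
    dur = max((times_s[-1] - times_s[0]) / 86400.0, 0.01)
    return MigrationEvent(
        animal_id=animal, season=Season.SPRING, fixes=df, duration_days=dur, complete=True
    )


def brownian_event(sig2s, n=201, dt=3600.0, err=1e-9, seed=0) -> MigrationEvent:
    """Planar track with known per-segment diffusion (m^2/s)."""
    rng = np.random.default_rng(seed)
    sig2s = np.asarray(sig2s, dtype=float)
    assert len(sig2s) == n - 1
    steps = rng.normal(0, 1, (n - 1, 2)) * np.sqrt(sig2s[:, None] * dt)
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if err > 1e-6:
        xy = xy + rng.normal(0, err, (n, 2))
    return planar_event(np.arange(n) * dt, xy[:, 0], xy[:, 1], max(err, 1e-9))


def square_grid(n=10, side=1000.0, origin=(0.0, 0.0)) -> GridSpec:
    return GridSpec(
        origin_x=origin[0], origin_y=origin[1], cell_side=side,
        n_cols=n, n_rows=n, lon0=90.0, lat0=30.0,
    )


def ud_from_array(arr, grid=None, **meta) -> UtilizationDistribution:
    arr = np.asarray(arr, dtype=float)
    if grid is None:
        grid = GridSpec(
            origin_x=0.0, origin_y=0.0, cell_side=1000.0,
            n_cols=arr.shape[1], n_rows=arr.shape[0], lon0=90.0, lat0=30.0,
        )
    return UtilizationDistribution(grid=grid, mass=arr / arr.sum(), metadata=meta)


def gaussian_ud(grid: GridSpec, cx, cy, sd, **meta) -> UtilizationDistribution:
    xs, ys = np.meshgrid(grid.x_centers, grid.y_centers)
    dens = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sd**2))
    return ud_from_array(dens, grid=grid, **meta)
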