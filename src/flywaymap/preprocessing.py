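"""Data retention, location-error assignment and migration-event segmentation.

The retention rule keeps the single best-quality fix per animal per
clock hour (Argos class ordering 3 > 2 > 1 > 0 > A > B > Z, GPS above
all).  Positional error is attached per location class: 23.5 m for GPS
and a per-class table for Argos spanning 0.45 km (class 3) to 7.92 km
(class B).  A sustained-speed plausibility filter removes physically
impossible fixes; it is a deliberately simple stand-in for heavier
operational Argos filters and makes no claim of matching them.
Finally each track is cut into full seasonal migration events running
between detected stationary winter and breeding ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .telemetry import CLASS_RANK, Track, geodesic_distance_m

logger = logging.getLogger("flywaymap")

#: Package-default Argos per-class positional SD in metres.  Only the
#: class-3 (450 m) and class-B (7920 m) endpoints are anchored to
#: published waterfowl error estimates; the intermediate values are
#: package defaults interpolated between them and should be overridden
#: when better per-study estimates exist.
DEFAULT_ARGOS_SD_M = {"3": 450.0, "2": 630.0, "1": 1190.0, "0": 2580.0, "A": 5070.0, "B": 7920.0}
DEFAULT_GPS_SD_M = 23.5


@dataclass(frozen=True)
class ErrorModel:
    """Isotropic positional SD per location class, in metres."""

    argos_sd_m: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ARGOS_SD_M))
    gps_sd_m: float = DEFAULT_GPS_SD_M

    def __post_init__(self) -> None:
        if self.gps_sd_m <= 0 or any(v <= 0 for v in self.argos_sd_m.values()):
            raise ValueError("all error SDs must be positive")
        if self.argos_sd_m.get("3", 0) > self.argos_sd_m.get("B", np.inf):
            raise ValueError("class-3 SD must not exceed class-B SD (quality ordering)")

    def sd_for(self, sensor: str, location_class: str) -> float:
        if sensor == "GPS" or location_class == "G":
            return self.gps_sd_m
        if location_class == "Z":
            raise ValueError(
                "class-Z fixes carry no usable error estimate; remove them with "
                "plausibility_filter before assigning errors"
            )
        try:
            return self.argos_sd_m[location_class]
        except KeyError:
            raise ValueError(f"unknown Argos location class {location_class!r}") from None


class Season(str, Enum):
    SPRING = "SPRING"
    FALL = "FALL"


@dataclass
class MigrationEvent:
    """One seasonal migration: the fixes between departure and arrival.

    ``complete`` is True only when the event runs between two distinct
    seasonal ranges (winter at one end, breeding at the other); only
    complete events enter utilization-distribution estimation.
    ``duration_days`` is fractional (events shorter than a day occur in
    real waterfowl data) with a floor of 0.01 d so durations can always
    serve as positive aggregation weights.
    """

    animal_id: str
    season: Season
    fixes: pd.DataFrame
    duration_days: float
    complete: bool

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")


# ---------------------------------------------------------------------------
# Hourly retention
# ---------------------------------------------------------------------------


def retain_hourly_best(track: Track) -> Track:
    """Keep the highest-quality fix in each clock hour.

    Quality order: G (GPS) > 3 > 2 > 1 > 0 > A > B > Z.  Ties within an
    hour keep the earlier fix.  Retained timestamps are truncated to
    the hour.  Idempotent.
    """
    df = track.fixes
    if len(df) == 0:
        return track
    df = df.copy()
    hour = df["timestamp"].dt.floor("h")
    rank = df["location_class"].map(CLASS_RANK)
    if rank.isna().any():
        bad = sorted(df.loc[rank.isna(), "location_class"].unique())
        raise ValueError(f"unknown location class(es) {bad}")
    order = np.lexsort((np.arange(len(df)), rank.to_numpy(), hour.to_numpy()))
    df = df.iloc[order]
    keep = ~df["timestamp"].dt.floor("h").duplicated(keep="first")
    df = df[keep].copy()
    df["timestamp"] = df["timestamp"].dt.floor("h")
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return track.with_fixes(df)


def assign_errors(track: Track, model: ErrorModel | None = None) -> Track:
    """Fill ``error_sd`` on every fix from the error model.

    Never touches coordinates or ordering.  Raises if class-Z fixes are
    still present (they must be removed by :func:`plausibility_filter`).
    """
    model = model or ErrorModel()
    df = track.fixes.copy()
    df["error_sd"] = [
        model.sd_for(s, c) for s, c in zip(df["sensor"], df["location_class"])
    ]
    return track.with_fixes(df)


# ---------------------------------------------------------------------------
# Speed plausibility filter
# ---------------------------------------------------------------------------


def _speeds_kmh(df: pd.DataFrame) -> np.ndarray:
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    d = geodesic_distance_m(
        df["lon"].to_numpy(float)[:-1],
        df["lat"].to_numpy(float)[:-1],
        df["lon"].to_numpy(float)[1:],
        df["lat"].to_numpy(float)[1:],
    )
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt > 0, d / dt * 3.6, np.inf)


def plausibility_filter(track: Track, vmax_kmh: float = 120.0) -> Track:
    """Remove class-Z fixes and speed-implausible outliers.

    While any inter-fix speed exceeds ``vmax_kmh``, the fix adjacent to
    the fastest segment whose removal most reduces the local maximum
    implied speed is dropped (ties: the fix with the larger positional
    error, then the later one).  This is a simple sustained-speed
    filter, not a reimplementation of operational Argos filtering.
    """
    df = track.fixes
    n0 = len(df)
    z = df["location_class"] == "Z"
    if z.any():
        logger.info("plausibility_filter[%s]: removing %d class-Z fixes", track.animal_id, z.sum())
        df = df[~z].reset_index(drop=True)

    removed = 0
    while len(df) >= 2:
        sp = _speeds_kmh(df)
        worst = int(np.argmax(sp))
        if sp[worst] <= vmax_kmh:
            break
        candidates = [worst, worst + 1]

        def local_max_without(i: int) -> float:
            sub = df.drop(df.index[i]).reset_index(drop=True)
            lo, hi = max(0, i - 2), min(len(sub) - 1, i + 2)
            if hi <= lo:
                return 0.0
            return float(np.max(_speeds_kmh(sub.iloc[lo : hi + 1])))

        scores = [local_max_without(i) for i in candidates]
        errs = df["error_sd"].to_numpy(float)
        best = min(
            range(len(candidates)),
            key=lambda k: (scores[k], -np.nan_to_num(errs[candidates[k]]), -candidates[k]),
        )
        df = df.drop(df.index[candidates[best]]).reset_index(drop=True)
        removed += 1

    if removed:
        logger.info(
            "plausibility_filter[%s]: removed %d speed-implausible fixes", track.animal_id, removed
        )
    if n0 and (n0 - len(df)) / n0 > 0.5:
        logger.warning(
            "plausibility_filter[%s]: removed >50%% of fixes (%d of %d) - review this track",
            track.animal_id,
            n0 - len(df),
            n0,
        )
    return track.with_fixes(df)


# ---------------------------------------------------------------------------
# Segmentation into migration events
# ---------------------------------------------------------------------------


@dataclass
class StationaryRange:
    start: int  # fix index, inclusive
    stop: int  # fix index, inclusive
    lon: float
    lat: float
    dwell_days: float
    label: str = ""  # WINTER / BREED / MOLT / OTHER


def _detect_stationary_ranges(
    df: pd.DataFrame, stationary_radius_km: float, dwell_days: float
) -> list[StationaryRange]:
    """Greedy maximal runs of fixes staying within a radius of their
    running centroid for at least ``dwell_days``."""
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    t = df["timestamp"].astype("int64").to_numpy() / 86400e9  # days
    n = len(df)
    out: list[StationaryRange] = []
    i = 0
    while i < n:
        cx, cy = lon[i], lat[i]
        j = i
        while j + 1 < n:
            nx = (cx * (j - i + 1) + lon[j + 1]) / (j - i + 2)
            ny = (cy * (j - i + 1) + lat[j + 1]) / (j - i + 2)
            if geodesic_distance_m(lon[j + 1], lat[j + 1], nx, ny) / 1000.0 > stationary_radius_km:
                break
            cx, cy = nx, ny
            j += 1
        if t[j] - t[i] >= dwell_days:
            out.append(
                StationaryRange(
                    start=i, stop=j, lon=float(cx), lat=float(cy), dwell_days=float(t[j] - t[i])
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def _label_ranges(
    ranges: list[StationaryRange], stationary_radius_km: float
) -> list[StationaryRange]:
    """Label stationary ranges WINTER / BREED / MOLT.

    Heuristic (the criteria are geographic and phenological, there is
    no single published algorithm): the southernmost and northernmost
    stationary ranges anchor the winter and breeding ranges; any range
    whose centroid sits within the stationary radius of an anchor
    shares its label.  An unlabelled range that directly follows a
    breeding range in time is a molting site; anything else is OTHER.
    Callers can override labels per range afterwards.
    """
    if not ranges:
        return ranges
    lats = [r.lat for r in ranges]
    south, north = ranges[int(np.argmin(lats))], ranges[int(np.argmax(lats))]
    for r in ranges:
        d_s = geodesic_distance_m(r.lon, r.lat, south.lon, south.lat) / 1000.0
        d_n = geodesic_distance_m(r.lon, r.lat, north.lon, north.lat) / 1000.0
        if d_s <= 2 * stationary_radius_km and south is not north:
            r.label = "WINTER"
        elif d_n <= 2 * stationary_radius_km:
            r.label = "BREED"
    prev = None
    for r in ranges:
        if not r.label:
            r.label = "MOLT" if prev is not None and prev.label == "BREED" else "OTHER"
        prev = r
    return ranges


def segment_migration_events(
    track: Track,
    stationary_radius_km: float = 50.0,
    dwell_days: float = 21.0,
    range_labels: dict[int, str] | None = None,
) -> list[MigrationEvent]:
    """Cut a track into seasonal migration events.

    Stationary seasonal ranges are maximal runs of fixes staying within
    ``stationary_radius_km`` of their running centroid for at least
    ``dwell_days``.  An event is the fix run from the departure fix of
    one range to the arrival fix of the next, inclusive; it is complete
    only when its endpoints are distinct winter/breeding ranges.  Fixes
    inside a molting range are excluded while travel to and from it is
    kept, so a breeding -> molt -> winter journey yields one fall event
    whose interior molt dwell is cut out.

    ``range_labels`` overrides the automatic WINTER/BREED/MOLT labels
    by stationary-range index (detection order along the track).
    """
    df = track.fixes.reset_index(drop=True)
    if len(df) < 2:
        return []
    ranges = _detect_stationary_ranges(df, stationary_radius_km, dwell_days)
    ranges = _label_ranges(ranges, stationary_radius_km)
    if range_labels:
        for idx, lab in range_labels.items():
            ranges[idx].label = lab
    seasonal = [r for r in ranges if r.label in ("WINTER", "BREED")]
    if len(seasonal) < 2:
        logger.info(
            "segment_migration_events[%s]: %d stationary range(s) found, "
            "no seasonal range pair - no events",
            track.animal_id,
            len(ranges),
        )
        return []

    molt_spans = [(r.start, r.stop) for r in ranges if r.label == "MOLT"]
    events: list[MigrationEvent] = []
    for a, b in zip(seasonal[:-1], seasonal[1:]):
        lo, hi = a.stop, b.start  # departure fix .. arrival fix, inclusive
        if hi <= lo:
            continue
        idx = np.arange(lo, hi + 1)
        for ms, me in molt_spans:
            if ms > lo and me < hi:  # interior molt dwell: drop inside, keep endpoints
                idx = idx[(idx <= ms) | (idx >= me)]
        ev = df.iloc[idx].reset_index(drop=True)
        t0, t1 = ev["timestamp"].iloc[0], ev["timestamp"].iloc[-1]
        duration = max((t1 - t0).total_seconds() / 86400.0, 0.01)
        season = Season.SPRING if b.lat > a.lat else Season.FALL
        complete = {a.label, b.label} == {"WINTER", "BREED"}
        events.append(
            MigrationEvent(
                animal_id=track.animal_id,
                season=season,
                fixes=ev,
                duration_days=float(duration),
                complete=bool(complete),
            )
        )
    return events


def preprocess_track(
    track: Track,
    model: ErrorModel | None = None,
    vmax_kmh: float = 120.0,
    stationary_radius_km: float = 50.0,
    dwell_days: float = 21.0,
) -> list[MigrationEvent]:
    """Full preprocessing chain: hourly retention -> plausibility filter
    -> error assignment -> event segmentation.  Returns complete events."""
    tr = retain_hourly_best(track)
    tr = plausibility_filter(tr, vmax_kmh=vmax_kmh)
    tr = assign_errors(tr, model)
    events = segment_migration_events(
        tr, stationary_radius_km=stationary_radius_km, dwell_days=dwell_days
    )
    return [e for e in events if e.complete]
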