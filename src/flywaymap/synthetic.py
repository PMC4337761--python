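"""Synthetic migratory telemetry with known ground truth.

The generator emulates the structure of multi-individual waterfowl
tracking data: each bird winters at the southern end of a population
corridor, migrates north along jittered corridor waypoints with
stopovers, breeds at the northern end (optionally molting at a
separate site), and returns in fall.  Movement is built as piecewise
processes — an Ornstein-Uhlenbeck jitter around stationary sites and a
drift-plus-diffusion along corridor legs — rather than one switching
SDE, so every fix carries an exact regime label and every segment an
exact Brownian motion variance for recovery tests.

Observation emulates the two transmitter types: GPS birds sample every
~4.5 h with 23.5 m error; Argos birds sample every ~22.4 h and draw a
location class per fix from a configurable (B-heavy) frequency table,
with class-specific isotropic error.  All randomness flows from one
seed through per-individual spawned substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import DEFAULT_ARGOS_SD_M, DEFAULT_GPS_SD_M
from .telemetry import Track, laea_project, laea_unproject

SECONDS_PER_DAY = 86_400.0

REGIMES = ("WINTER", "SPRING_MIG", "BREED", "MOLT", "FALL_MIG", "STOPOVER")


@dataclass(frozen=True)
class PopulationSpec:
    """One population: a corridor polyline and its members."""

    name: str
    species: str
    n_individuals: int
    waypoints: tuple[tuple[float, float], ...]  # (lon, lat), winter end first
    stopover_dwell_days: tuple[float, ...] = ()  # mean dwell at each interior waypoint

    def __post_init__(self) -> None:
        if len(self.waypoints) < 2:
            raise ValueError("a corridor needs at least 2 waypoints")
        n_interior = len(self.waypoints) - 2
        if self.stopover_dwell_days and len(self.stopover_dwell_days) != n_interior:
            raise ValueError("stopover_dwell_days must have one entry per interior waypoint")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror typical Asian waterfowl telemetry: mean inter-fix
    gaps of 4.5 h (GPS) and 22.4 h (Argos), GPS error 23.5 m, Argos
    class errors from 450 m (class 3) to 7.92 km (class B), flight
    speeds around 60 km/h, and a strong stopover-versus-flight contrast
    in the Brownian motion variance.
    """

    populations: tuple[PopulationSpec, ...]
    flight_speed_kmh: float = 60.0
    flight_sigma2: float = 200.0  # m^2/s during migratory flight
    stopover_sigma2: float = 10.0  # m^2/s at stopovers and seasonal sites
    winter_dwell_days: float = 100.0
    breeding_dwell_days: float = 60.0
    final_winter_dwell_days: float = 60.0
    molt_dwell_days: float = 0.0  # > 0 enables a molt cluster after breeding
    molt_offset_km: float = 150.0
    gps_fraction: float = 0.6
    gps_gap_hr: float = 4.5
    argos_gap_hr: float = 22.4
    gap_shape: float = 9.0  # gamma shape of inter-fix gaps
    dwell_shape: float = 16.0  # gamma shape of dwell durations (CV 0.25)
    argos_class_freqs: dict = field(
        default_factory=lambda: {
            "3": 0.05, "2": 0.08, "1": 0.12, "0": 0.15, "A": 0.23, "B": 0.35, "Z": 0.02
        }
    )
    z_error_m: float = 15_000.0
    corridor_jitter_km: float = 30.0  # per-individual waypoint jitter SD
    ou_tau_site_hr: float = 24.0  # OU relaxation time at stationary sites
    ou_tau_flight_hr: float = 96.0  # OU relaxation time of cross-corridor deviation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.flight_speed_kmh <= 0 or self.flight_sigma2 <= 0 or self.stopover_sigma2 <= 0:
            raise ValueError("speeds and variances must be positive")
        if min(self.winter_dwell_days, self.breeding_dwell_days, self.molt_dwell_days) < 0:
            raise ValueError("dwell days must be nonnegative")
        tot = sum(self.argos_class_freqs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"argos class frequencies must sum to 1, got {tot}")


@dataclass
class GroundTruth:
    """Exact simulation state behind one observed track."""

    animal_id: str
    regime: np.ndarray  # per-fix regime label
    true_lon: np.ndarray
    true_lat: np.ndarray
    true_x: np.ndarray  # planar metres in the simulation frame
    true_y: np.ndarray
    backbone_x: np.ndarray  # deterministic schedule position (no diffusion)
    backbone_y: np.ndarray
    sigma2_per_segment: np.ndarray  # true diffusion m^2/s between fixes i, i+1
    event_boundaries: pd.DataFrame  # columns: event, t_start_days, t_end_days
    projection_center: tuple[float, float]


def default_scenario(
    n_populations: int = 2,
    individuals_per_population: int = 4,
    n_species: int = 2,
    rng_seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """A plausible multi-population Central-Asian-style scenario.

    Corridors run south-to-north ~2,500 km apart-ish polylines with one
    or two interior stopover sites; populations are assigned to species
    round-robin.
    """
    base = [
        # (winter, stopovers..., breeding)
        ((85.0, 20.0), (87.0, 29.0), (89.0, 38.0), (92.0, 47.0)),
        ((75.0, 18.0), (76.5, 28.0), (78.0, 36.0), (80.0, 46.0)),
        ((95.0, 22.0), (97.0, 31.0), (99.0, 40.0), (101.0, 48.0)),
        ((68.0, 16.0), (69.0, 27.0), (70.5, 37.0), (72.0, 45.0)),
    ]
    pops = []
    for p in range(n_populations):
        wp = base[p % len(base)]
        pops.append(
            PopulationSpec(
                name=f"POP{p}",
                species=f"SP{p % max(n_species, 1)}",
                n_individuals=individuals_per_population,
                waypoints=wp,
                stopover_dwell_days=(4.0,) * (len(wp) - 2),
            )
        )
    return ScenarioConfig(populations=tuple(pops), rng_seed=rng_seed, **overrides)


def shelduck_like_scenario(rng_seed: int = 0, **overrides) -> ScenarioConfig:
    """Single population of 31 individuals, the size of a typical
    population-level shelduck analysis."""
    cfg = default_scenario(n_populations=1, individuals_per_population=31,
                           n_species=1, rng_seed=rng_seed, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Schedule: piecewise regimes with a deterministic backbone position
# ---------------------------------------------------------------------------


@dataclass
class _Phase:
    regime: str
    t0: float  # seconds
    t1: float
    x0: float  # backbone position, planar metres
    y0: float
    x1: float
    y1: float
    sigma2: float
    tau_s: float  # OU relaxation time of the deviation process

    def pos(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.t1 == self.t0:
            f = np.zeros_like(t)
        else:
            f = (t - self.t0) / (self.t1 - self.t0)
        return self.x0 + f * (self.x1 - self.x0), self.y0 + f * (self.y1 - self.y0)


def _build_schedule(
    pop: PopulationSpec, cfg: ScenarioConfig, wx: np.ndarray, wy: np.ndarray,
    rng: np.random.Generator,
) -> list[_Phase]:
    """Lay out the annual cycle as (regime, time span, backbone) phases."""
    v = cfg.flight_speed_kmh / 3.6  # m/s
    tau_site = cfg.ou_tau_site_hr * 3600.0
    tau_fly = cfg.ou_tau_flight_hr * 3600.0
    n_wp = len(wx)
    dwells = list(pop.stopover_dwell_days) or [0.0] * (n_wp - 2)

    phases: list[_Phase] = []
    t = 0.0

    def add(regime, dur_s, x0, y0, x1, y1, s2, tau):
        nonlocal t
        if dur_s <= 0:
            return
        phases.append(_Phase(regime, t, t + dur_s, x0, y0, x1, y1, s2, tau))
        t += dur_s

    def dwell_days(mean_days):
        if mean_days <= 0:
            return 0.0
        return float(rng.gamma(cfg.dwell_shape, mean_days / cfg.dwell_shape))

    # winter
    add("WINTER", dwell_days(cfg.winter_dwell_days) * SECONDS_PER_DAY,
        wx[0], wy[0], wx[0], wy[0], cfg.stopover_sigma2, tau_site)

    def traverse(regime, order):
        for a, b in zip(order[:-1], order[1:]):
            dist = math.hypot(wx[b] - wx[a], wy[b] - wy[a])
            add(regime, dist / v, wx[a], wy[a], wx[b], wy[b], cfg.flight_sigma2, tau_fly)
            if b != order[-1]:
                d = dwell_days(dwells[b - 1] if 0 < b < n_wp - 1 else 0.0)
                add("STOPOVER", d * SECONDS_PER_DAY,
                    wx[b], wy[b], wx[b], wy[b], cfg.stopover_sigma2, tau_site)

    # spring migration north
    traverse("SPRING_MIG", list(range(n_wp)))
    add("BREED", dwell_days(cfg.breeding_dwell_days) * SECONDS_PER_DAY,
        wx[-1], wy[-1], wx[-1], wy[-1], cfg.stopover_sigma2, tau_site)

    # optional molt cluster offset from the breeding site
    if cfg.molt_dwell_days > 0:
        ang = rng.uniform(0, 2 * math.pi)
        mx = wx[-1] + cfg.molt_offset_km * 1000.0 * math.cos(ang)
        my = wy[-1] + cfg.molt_offset_km * 1000.0 * math.sin(ang)
        dist = math.hypot(mx - wx[-1], my - wy[-1])
        add("FALL_MIG", dist / v, wx[-1], wy[-1], mx, my, cfg.flight_sigma2, tau_fly)
        add("MOLT", dwell_days(cfg.molt_dwell_days) * SECONDS_PER_DAY,
            mx, my, mx, my, cfg.stopover_sigma2, tau_site)
        dist = math.hypot(wx[-2] - mx, wy[-2] - my)
        add("FALL_MIG", dist / v, mx, my, wx[-2], wy[-2], cfg.flight_sigma2, tau_fly)
        rest = list(range(n_wp - 2, -1, -1))
    else:
        rest = list(range(n_wp - 1, -1, -1))

    # fall migration south (remaining legs), then final winter dwell
    traverse("FALL_MIG", rest)
    add("WINTER", dwell_days(cfg.final_winter_dwell_days) * SECONDS_PER_DAY,
        wx[0], wy[0], wx[0], wy[0], cfg.stopover_sigma2, tau_site)
    return phases


def _phase_at(phases: list[_Phase], t: float) -> _Phase:
    for ph in phases:
        if t < ph.t1:
            return ph
    return phases[-1]


# ---------------------------------------------------------------------------
# Individual simulation
# ---------------------------------------------------------------------------


def simulate_individual(
    cfg: ScenarioConfig,
    animal_index: int,
    population_index: int = 0,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] | None = None,
) -> tuple[Track, GroundTruth]:
    """Simulate one bird: true path, sampling times and observation error.

    The true position is the phase backbone (stationary site or
    constant-speed corridor leg) plus a per-axis Ornstein-Uhlenbeck
    deviation with diffusion equal to the phase's Brownian motion
    variance; over gaps short relative to the relaxation time the
    deviation increments are Brownian with that variance, which is what
    the dBBMM estimates.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.rng_seed).spawn(animal_index + 1)[-1]
        )
    pop = cfg.populations[population_index]
    lons = np.array([w[0] for w in pop.waypoints])
    lats = np.array([w[1] for w in pop.waypoints])
    if center is None:
        all_lons = [w[0] for p in cfg.populations for w in p.waypoints]
        all_lats = [w[1] for p in cfg.populations for w in p.waypoints]
        center = (float(np.mean(all_lons)), float(np.mean(all_lats)))
    wx, wy = laea_project(lons, lats, *center)
    jit = cfg.corridor_jitter_km * 1000.0
    wx = wx + rng.normal(0.0, jit, size=len(wx))
    wy = wy + rng.normal(0.0, jit, size=len(wy))

    phases = _build_schedule(pop, cfg, wx, wy, rng)
    total = phases[-1].t1

    is_gps = rng.random() < cfg.gps_fraction
    sensor = "GPS" if is_gps else "ARGOS"
    mean_gap = (cfg.gps_gap_hr if is_gps else cfg.argos_gap_hr) * 3600.0

    times = [0.0]
    while times[-1] < total:
        times.append(times[-1] + rng.gamma(cfg.gap_shape, mean_gap / cfg.gap_shape))
    t = np.array(times[:-1]) if times[-1] >= total else np.array(times)
    n = len(t)

    # OU deviation, exact discretization with phase-wise parameters
    dev = np.zeros((n, 2))
    regimes = np.empty(n, dtype=object)
    sig2 = np.empty(n)
    for i in range(n):
        ph = _phase_at(phases, t[i])
        regimes[i] = ph.regime
        sig2[i] = ph.sigma2
        if i > 0:
            dt = t[i] - t[i - 1]
            rho = math.exp(-dt / ph.tau_s)
            stat = ph.sigma2 * ph.tau_s / 2.0  # stationary variance of the OU deviation
            dev[i] = dev[i - 1] * rho + rng.normal(0.0, math.sqrt(stat * (1 - rho * rho)), 2)

    bx = np.empty(n)
    by = np.empty(n)
    for i in range(n):
        ph = _phase_at(phases, t[i])
        px, py = ph.pos(np.array([t[i]]))
        bx[i], by[i] = px[0], py[0]
    tx, ty = bx + dev[:, 0], by + dev[:, 1]

    # observation: sensor-specific error
    if is_gps:
        classes = np.array(["G"] * n)
        err = np.full(n, DEFAULT_GPS_SD_M)
    else:
        names = list(cfg.argos_class_freqs)
        probs = np.array([cfg.argos_class_freqs[c] for c in names])
        classes = rng.choice(names, size=n, p=probs)
        table = dict(DEFAULT_ARGOS_SD_M, Z=cfg.z_error_m)
        err = np.array([table[c] for c in classes])
    ox = tx + rng.normal(0.0, err)
    oy = ty + rng.normal(0.0, err)

    lon_obs, lat_obs = laea_unproject(ox, oy, *center)
    lon_true, lat_true = laea_unproject(tx, ty, *center)

    animal_id = f"{pop.name}_A{animal_index:03d}"
    t0 = pd.Timestamp("2010-01-01", tz="UTC")
    fixes = pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": t0 + pd.to_timedelta(np.round(t), unit="s"),
            "lon": lon_obs,
            "lat": lat_obs,
            "sensor": sensor,
            "location_class": classes,
            "x": np.nan,
            "y": np.nan,
            "error_sd": np.nan,
        }
    )
    track = Track(
        animal_id=animal_id, fixes=fixes, species_code=pop.species, marking_site=pop.name
    )

    mig = [ph for ph in phases if ph.regime in ("SPRING_MIG", "FALL_MIG", "STOPOVER", "MOLT")]
    bounds = []
    if mig:
        # event spans: contiguous runs of migratory phases
        run_start = mig[0].t0
        prev_end = mig[0].t1
        for ph in mig[1:]:
            if ph.t0 > prev_end + 1:  # gap: a seasonal dwell separates events
                bounds.append((run_start, prev_end))
                run_start = ph.t0
            prev_end = ph.t1
        bounds.append((run_start, prev_end))
    boundary_df = pd.DataFrame(
        [
            {"event": i, "t_start_days": a / SECONDS_PER_DAY, "t_end_days": b / SECONDS_PER_DAY}
            for i, (a, b) in enumerate(bounds)
        ]
    )

    truth = GroundTruth(
        animal_id=animal_id,
        regime=regimes,
        true_lon=lon_true,
        true_lat=lat_true,
        true_x=tx,
        true_y=ty,
        backbone_x=bx,
        backbone_y=by,
        sigma2_per_segment=sig2[:-1].astype(float),
        event_boundaries=boundary_df,
        projection_center=center,
    )
    return track, truth


def simulate_cohort(
    cfg: ScenarioConfig,
) -> tuple[list[Track], list[GroundTruth], pd.DataFrame]:
    """Simulate every individual of every population.

    Returns (tracks, ground truths, grouping table).  The grouping
    table (columns ``animal_id, population, species``) feeds the
    aggregation hierarchy directly.  Deterministic under
    ``cfg.rng_seed``: individuals draw from spawned substreams indexed
    by their global animal index.
    """
    all_lons = [w[0] for p in cfg.populations for w in p.waypoints]
    all_lats = [w[1] for p in cfg.populations for w in p.waypoints]
    center = (float(np.mean(all_lons)), float(np.mean(all_lats)))

    n_total = sum(p.n_individuals for p in cfg.populations)
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(n_total)
    tracks: list[Track] = []
    truths: list[GroundTruth] = []
    rows = []
    k = 0
    for pi, pop in enumerate(cfg.populations):
        for _ in range(pop.n_individuals):
            rng = np.random.default_rng(streams[k])
            tr, gt = simulate_individual(cfg, k, population_index=pi, rng=rng, center=center)
            tracks.append(tr)
            truths.append(gt)
            rows.append(
                {"animal_id": tr.animal_id, "population": pop.name, "species": pop.species}
            )
            k += 1
    return tracks, truths, pd.DataFrame(rows)
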