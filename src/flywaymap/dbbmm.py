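"""Dynamic Brownian bridge movement model: variance estimation and UDs.

The model treats the animal's path between two fixes as a Brownian
bridge pinned at the observed endpoints, with normally distributed
positional error at the fixes.  In any run of three fixes the middle
one is an independent observation of the bridge joining its
neighbours, so the Brownian motion variance sigma^2_m (m^2/s) can be
estimated by maximizing the likelihood of the middle fixes.  A sliding
window with margins compares, by BIC, one sigma^2_m for the whole
window against two variances split at a breakpoint, letting the
variance track behavioural switches (stopover vs directed flight)
along the path.  The utilization distribution (UD) is the
time-integrated bridge density rasterized on the shared grid.

For an intermediate fix z_j observed at time t_j between fixes
(z_a, t_a) and (z_b, t_b), with alpha = (t_j - t_a)/(t_b - t_a) and
T = t_b - t_a, the per-axis bridge variance is

    s(alpha) = T * alpha * (1 - alpha) * sigma2
               + (1 - alpha)^2 * delta_a^2 + alpha^2 * delta_b^2

and z_j ~ N(z_a + alpha * (z_b - z_a), s(alpha) * I).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .preprocessing import MigrationEvent
from .telemetry import GridSpec

logger = logging.getLogger("flywaymap")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class DbbmmConfig:
    """Tunable parameters of the estimator and rasterizer.

    ``window_size`` (w) and ``margin`` (m) are counts of locations; the
    defaults 31 and 11 follow established practice for migratory
    waterfowl at these sampling rates.  ``sigma2_bounds`` bound the
    Brownian motion variance search (m^2/s, log-scale Brent search).
    ``alpha_steps`` is the number of trapezoid nodes used to integrate
    the bridge density over the segment; ``truncation_radius`` cuts
    Gaussian evaluation beyond that many local SDs (the lost tail mass
    is restored by the final renormalization).
    """

    window_size: int = 31
    margin: int = 11
    alpha_steps: int = 25
    sigma2_bounds: tuple[float, float] = (1e-6, 1e7)
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        w, m = self.window_size, self.margin
        if m < 3:
            raise ValueError("margin must be at least 3 locations")
        if w < 2 * m + 1:
            raise ValueError("window_size must be at least 2*margin + 1")
        if self.sigma2_bounds[0] <= 0 or self.sigma2_bounds[0] >= self.sigma2_bounds[1]:
            raise ValueError("sigma2_bounds must be (min, max) with 0 < min < max")


@dataclass
class WindowRecord:
    """Diagnostics for one sliding-window fit."""

    start: int  # global index of first fix in window
    split: int | None  # window-local breakpoint fix index, None if single model
    bic_single: float
    bic_split: float
    sigma2: tuple[float, ...]  # (s2,) or (s2_left, s2_right)


@dataclass
class VarianceProfile:
    """Per-segment Brownian motion variance along one event.

    ``sigma2_m[i]`` applies to the segment between fixes i and i+1.
    """

    sigma2_m: np.ndarray
    windows: list[WindowRecord] = field(default_factory=list)
    window_size: int = 31
    margin: int = 11

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2_m, dtype=float)
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("sigma2_m must be finite and positive")
        self.sigma2_m = s


@dataclass
class UtilizationDistribution:
    """Nonnegative probability mass per grid cell, summing to 1."""

    grid: GridSpec
    mass: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mass shape does not match grid")
        if np.any(m < 0):
            raise ValueError("UD mass must be nonnegative")
        tot = m.sum()
        if not math.isclose(tot, 1.0, abs_tol=1e-6):
            raise ValueError(f"UD mass sums to {tot!r}, not 1")
        self.mass = m


class GridTooSmallError(ValueError):
    """Probability mass reached the raster boundary; enlarge the padding."""


# ---------------------------------------------------------------------------
# Bridge likelihood
# ---------------------------------------------------------------------------


def _fix_arrays(fixes) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    err = fixes["error_sd"].to_numpy(float)
    if np.isnan(x).any() or np.isnan(err).any():
        raise ValueError("fixes need projected x/y and error_sd before dBBMM fitting")
    return t, x, y, err


class _BridgeTerms:
    """Precomputed per-intermediate-fix quantities so the log-likelihood
    is a cheap closed form in sigma2 during the Brent search.

    Intermediate fixes are those at 1-based even positions in the run:
    each is evaluated under the bridge joining its two neighbours, which
    matches treating every second location as an independent observation
    of the bridge through the others.
    """

    __slots__ = ("a", "b", "r2", "n")

    def __init__(self, t: np.ndarray, x: np.ndarray, y: np.ndarray, err: np.ndarray):
        n = len(t)
        if n < 3:
            raise ValueError("bridge likelihood needs at least 3 fixes")
        j = np.arange(1, n - 1, 2)  # 0-based odd == 1-based even
        ia, ib = j - 1, j + 1
        T = t[ib] - t[ia]
        if np.any(np.diff(t) <= 0):
            raise ValueError("fixes must have strictly increasing timestamps")
        alpha = (t[j] - t[ia]) / T
        mx = x[ia] + alpha * (x[ib] - x[ia])
        my = y[ia] + alpha * (y[ib] - y[ia])
        self.r2 = (x[j] - mx) ** 2 + (y[j] - my) ** 2
        # s(alpha) = a * sigma2 + b
        self.a = T * alpha * (1.0 - alpha)
        self.b = (1.0 - alpha) ** 2 * err[ia] ** 2 + alpha**2 * err[ib] ** 2
        self.n = len(j)

    def loglik(self, sigma2: float) -> float:
        s = np.maximum(self.a * sigma2 + self.b, 1e-300)
        return float(np.sum(-_LOG2PI - np.log(s) - self.r2 / (2.0 * s)))

    def fit(self, bounds: tuple[float, float]) -> tuple[float, float]:
        """MLE of sigma2 by bounded search on log(sigma2).

        Returns (sigma2_hat, loglik at the optimum).
        """
        lo, hi = math.log(bounds[0]), math.log(bounds[1])
        res = minimize_scalar(
            lambda u: -self.loglik(math.exp(u)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        s2 = float(math.exp(res.x))
        return s2, float(-res.fun)


def bridge_likelihood(window_fixes, sigma2: float) -> float:
    """Log-likelihood of the intermediate fixes of a window under
    Brownian bridges with motion variance ``sigma2`` (m^2/s).

    ``window_fixes`` is a DataFrame slice with columns
    ``timestamp, x, y, error_sd``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return _BridgeTerms(*_fix_arrays(window_fixes)).loglik(sigma2)


# ---------------------------------------------------------------------------
# Sliding-window variance estimation
# ---------------------------------------------------------------------------


def _fit_terms(t, x, y, err, lo, hi, bounds):
    """Fit sigma2 on fixes [lo, hi] inclusive; returns (s2, ll, n_int)."""
    bt = _BridgeTerms(t[lo : hi + 1], x[lo : hi + 1], y[lo : hi + 1], err[lo : hi + 1])
    s2, ll = bt.fit(bounds)
    return s2, ll, bt.n


def estimate_variances(event: MigrationEvent, cfg: DbbmmConfig | None = None) -> VarianceProfile:
    """Sliding-window BIC estimation of the dynamic Brownian motion variance.

    A window of ``w`` fixes advances one fix at a time.  Per window a
    single-variance model (k = 1) is compared by BIC with the best
    two-variance model split at any breakpoint outside the two margins
    (k = 2; the breakpoint position is not counted as a parameter),
    with BIC = -2 lnL + k ln(n_intermediate).  Each non-margin segment
    collects the winning model's variance from every window covering
    it; the final per-segment value is the unweighted mean.

    Events with fewer than ``w`` fixes fall back to a single event-wide
    MLE (logged) rather than being dropped, preserving short
    coarse-duty-cycle events.
    """
    cfg = cfg or DbbmmConfig()
    t, x, y, err = _fix_arrays(event.fixes)
    n = len(t)
    if n < 3:
        raise ValueError("variance estimation needs at least 3 fixes")
    n_seg = n - 1
    w, m = cfg.window_size, cfg.margin

    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        logger.warning(
            "estimate_variances[%s]: all coordinates identical; sigma2 pinned to minimum",
            event.animal_id,
        )
        return VarianceProfile(
            sigma2_m=np.full(n_seg, cfg.sigma2_bounds[0]),
            windows=[],
            window_size=w,
            margin=m,
        )

    if n < w:
        s2, ll, _ = _fit_terms(t, x, y, err, 0, n - 1, cfg.sigma2_bounds)
        logger.info(
            "estimate_variances[%s]: %d fixes < window %d; single event-wide "
            "sigma2=%.4g m^2/s",
            event.animal_id,
            n,
            w,
            s2,
        )
        return VarianceProfile(
            sigma2_m=np.full(n_seg, s2), windows=[], window_size=w, margin=m
        )

    sums = np.zeros(n_seg)
    counts = np.zeros(n_seg, dtype=int)
    records: list[WindowRecord] = []

    for start in range(n - w + 1):
        end = start + w - 1
        s2_all, ll_all, n_int = _fit_terms(t, x, y, err, start, end, cfg.sigma2_bounds)
        bic1 = -2.0 * ll_all + 1.0 * math.log(n_int)

        best_bic2, best_split, best_pair = math.inf, None, None
        for p in range(m, w - m):  # window-local breakpoint fix index
            s2_l, ll_l, n_l = _fit_terms(t, x, y, err, start, start + p, cfg.sigma2_bounds)
            s2_r, ll_r, n_r = _fit_terms(t, x, y, err, start + p, end, cfg.sigma2_bounds)
            bic2 = -2.0 * (ll_l + ll_r) + 2.0 * math.log(n_l + n_r)
            if bic2 < best_bic2:
                best_bic2, best_split, best_pair = bic2, p, (s2_l, s2_r)

        if best_bic2 < bic1:
            split, sigmas = best_split, best_pair
        else:
            split, sigmas = None, (s2_all,)
        records.append(
            WindowRecord(
                start=start, split=split, bic_single=bic1, bic_split=best_bic2, sigma2=sigmas
            )
        )

        # assign to non-margin segments: window-local segment q joins fixes q,q+1
        for q in range(m, w - 1 - m):
            if split is None:
                val = sigmas[0]
            else:
                val = sigmas[0] if q < split else sigmas[1]
            sums[start + q] += val
            counts[start + q] += 1

    covered = counts > 0
    out = np.empty(n_seg)
    out[covered] = sums[covered] / counts[covered]
    if not covered.all():
        # segments inside the track-end margins inherit the nearest covered value
        idx = np.where(covered)[0]
        for i in np.where(~covered)[0]:
            out[i] = out[idx[np.argmin(np.abs(idx - i))]]
    out = np.clip(out, cfg.sigma2_bounds[0], cfg.sigma2_bounds[1])
    return VarianceProfile(sigma2_m=out, windows=records, window_size=w, margin=m)


# ---------------------------------------------------------------------------
# Rasterizing the UD
# ---------------------------------------------------------------------------


def compute_ud(
    event: MigrationEvent,
    profile: VarianceProfile,
    grid: GridSpec,
    cfg: DbbmmConfig | None = None,
) -> UtilizationDistribution:
    """Rasterize the time-integrated bridge density of one event.

    Per segment the bridge density is integrated over alpha with an
    ``alpha_steps``-node trapezoid rule; segment contributions are
    weighted by their elapsed time T.  Gaussian evaluation is truncated
    beyond ``truncation_radius`` local SDs.  Cell mass is density at
    the cell centre times cell area; the final grid is renormalized to
    exactly unit mass.

    Raises :class:`GridTooSmallError` if more than 1e-4 of the
    (pre-renormalization) mass sits in the boundary ring of cells.
    """
    cfg = cfg or DbbmmConfig()
    t, x, y, err = _fix_arrays(event.fixes)
    n = len(t)
    if len(profile.sigma2_m) != n - 1:
        raise ValueError("variance profile does not cover all segments")

    dens = np.zeros((grid.n_rows, grid.n_cols))
    xc, yc = grid.x_centers, grid.y_centers
    K = cfg.alpha_steps
    alphas = np.linspace(0.0, 1.0, K)
    wts = np.full(K, 1.0 / (K - 1))
    wts[[0, -1]] *= 0.5  # trapezoid weights summing to 1

    total_T = float(t[-1] - t[0])
    for i in range(n - 1):
        T = t[i + 1] - t[i]
        s2m = profile.sigma2_m[i]
        for al, wt in zip(alphas, wts):
            s = T * al * (1 - al) * s2m + (1 - al) ** 2 * err[i] ** 2 + al**2 * err[i + 1] ** 2
            s = max(s, 1e-6)
            sd = math.sqrt(s)
            mx = x[i] + al * (x[i + 1] - x[i])
            my = y[i] + al * (y[i + 1] - y[i])
            if sd < grid.cell_side / 2.0:
                # density at cell centres underflows for near-degenerate
                # bridges; deposit the mass quantum in the containing cell
                row, col = grid.cell_index(mx, my)
                if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
                    dens[row, col] += T * wt / grid.cell_area
                continue
            r = cfg.truncation_radius * sd
            c0 = max(0, int((mx - r - grid.origin_x) // grid.cell_side))
            c1 = min(grid.n_cols, int((mx + r - grid.origin_x) // grid.cell_side) + 1)
            r0 = max(0, int((my - r - grid.origin_y) // grid.cell_side))
            r1 = min(grid.n_rows, int((my + r - grid.origin_y) // grid.cell_side) + 1)
            if c1 <= c0 or r1 <= r0:
                continue
            gx = np.exp(-((xc[c0:c1] - mx) ** 2) / (2 * s))
            gy = np.exp(-((yc[r0:r1] - my) ** 2) / (2 * s))
            dens[r0:r1, c0:c1] += (T * wt / (2 * math.pi * s)) * np.outer(gy, gx)

    mass = dens * grid.cell_area / total_T
    boundary = (
        mass[0, :].sum() + mass[-1, :].sum() + mass[1:-1, 0].sum() + mass[1:-1, -1].sum()
    )
    if boundary > 1e-4:
        raise GridTooSmallError(
            f"{boundary:.3g} of the probability mass reached the raster boundary; "
            "rebuild the grid with larger padding"
        )
    tot = mass.sum()
    if tot <= 0:
        raise ValueError("no probability mass landed on the grid")
    mass /= tot
    meta = {
        "animal_id": event.animal_id,
        "level": "EVENT",
        "season": event.season.value,
        "duration_days": event.duration_days,
    }
    return UtilizationDistribution(grid=grid, mass=mass, metadata=meta)


def fit_event_ud(
    event: MigrationEvent, grid: GridSpec, cfg: DbbmmConfig | None = None
) -> tuple[UtilizationDistribution, VarianceProfile]:
    """Convenience: estimate the variance profile and rasterize in one call."""
    cfg = cfg or DbbmmConfig()
    profile = estimate_variances(event, cfg)
    return compute_ud(event, profile, grid, cfg), profile
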