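"""Bridge likelihood, dynamic variance estimation and UD rasterization."""

import math

import numpy as np
import pytest

import flywaymap as fm
from flywaymap.dbbmm import DbbmmConfig, GridTooSmallError, _BridgeTerms

from _toys import brownian_event, planar_event, square_grid


class TestBridgeLikelihood:
    def test_midpoint_bridge_variance_arithmetic(self):
        # alpha = 0.5, T = 7200 s, sigma2 = 1, delta = 0: s = 7200 * 0.25 = 1800
        ev = planar_event([0.0, 3600.0, 7200.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0], 1e-9)
        ll = fm.bridge_likelihood(ev.fixes, sigma2=1.0)
        s = 7200.0 * 0.25 * 1.0
        assert ll == pytest.approx(-math.log(2 * math.pi * s), rel=1e-6)

    def test_zero_residual_maximizes_likelihood(self):
        # collinear equally spaced fixes: midpoint exactly on the line
        ev = planar_event([0.0, 3600.0, 7200.0], [0.0, 500.0, 1000.0],
                          [0.0, 250.0, 500.0], 1.0)
        lls = [fm.bridge_likelihood(ev.fixes, s2) for s2 in (1e-6, 1e-3, 1.0, 100.0)]
        assert lls == sorted(lls, reverse=True)  # smaller sigma2 always better

    def test_duplicate_timestamps_rejected(self):
        ev = planar_event([0.0, 0.0, 3600.0], [0.0, 1.0, 2.0], [0.0, 1.0, 2.0], 1.0)
        with pytest.raises(ValueError):
            fm.bridge_likelihood(ev.fixes, 1.0)

    def test_density_matches_monte_carlo_cell_probability(self):
        """The bridge density formula equals the generative model: jittered
        endpoints + Brownian bridge deviation, checked by a 1e6-draw MC
        estimate of the probability of a small disc around the observation."""
        rng = np.random.default_rng(0)
        za, zb = np.array([0.0, 0.0]), np.array([4000.0, 1000.0])
        da, db, s2, T, alpha = 300.0, 500.0, 20.0, 7200.0, 1.0 / 3.0
        zj = np.array([1500.0, 600.0])
        ev = planar_event([0.0, alpha * T, T],
                          [za[0], zj[0], zb[0]], [za[1], zj[1], zb[1]],
                          [da, 1.0, db])
        ev.fixes.loc[0, "error_sd"], ev.fixes.loc[2, "error_sd"] = da, db
        ll = fm.bridge_likelihood(ev.fixes, s2)

        n = 1_000_000
        ta = za + rng.normal(0, da, (n, 2))
        tb = zb + rng.normal(0, db, (n, 2))
        mid = ta + alpha * (tb - ta) + rng.normal(
            0, math.sqrt(T * alpha * (1 - alpha) * s2), (n, 2)
        )
        r = 120.0  # small disc around the observed intermediate fix
        inside = np.hypot(mid[:, 0] - zj[0], mid[:, 1] - zj[1]) < r
        p_mc = inside.mean()
        p_model = math.exp(ll) * math.pi * r**2
        se = math.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(p_mc - p_model) < 3 * se + 0.02 * p_model  # MC noise + disc curvature


class TestEstimateVariances:
    def test_defaults_recorded_in_profile(self):
        ev = brownian_event(np.full(40, 20.0), n=41, seed=1)
        prof = fm.estimate_variances(ev)
        assert prof.window_size == 31 and prof.margin == 11

    def test_constant_sigma2_recovered(self):
        ests = [
            np.mean(fm.estimate_variances(brownian_event(np.full(200, 20.0), seed=s)).sigma2_m)
            for s in range(5)
        ]
        assert abs(np.mean(ests) - 20.0) / 20.0 < 0.15

    def test_two_regime_switch_detected(self):
        ev = brownian_event(np.concatenate([np.full(100, 5.0), np.full(100, 50.0)]), seed=3)
        prof = fm.estimate_variances(ev)
        w, m = prof.window_size, prof.margin
        # windows whose admissible breakpoint span contains the switch
        eligible = [r for r in prof.windows if r.start + m <= 100 <= r.start + w - 1 - m]
        hits = [
            r for r in eligible if r.split is not None and abs(r.start + r.split - 100) <= m
        ]
        assert len(hits) / len(eligible) >= 0.9
        assert np.mean(prof.sigma2_m[110:]) > 3 * np.mean(prof.sigma2_m[:90])

    def test_short_event_falls_back_to_single_variance(self):
        ev = brownian_event(np.full(10, 20.0), n=11, seed=2)
        prof = fm.estimate_variances(ev)
        assert len(set(np.round(prof.sigma2_m, 12))) == 1

    def test_identical_coordinates_pin_to_minimum(self):
        ev = planar_event(np.arange(12) * 3600.0, np.zeros(12), np.zeros(12), 10.0)
        prof = fm.estimate_variances(ev)
        assert np.all(prof.sigma2_m == DbbmmConfig().sigma2_bounds[0])

    def test_invalid_window_margin_combinations_rejected(self):
        with pytest.raises(ValueError):
            DbbmmConfig(margin=2)
        with pytest.raises(ValueError):
            DbbmmConfig(window_size=21, margin=11)


def _single_segment_ud(alpha_steps=25, trunc=4.0, cell=300.0, n=60, err=(300.0, 300.0),
                       s2=50.0, T=7200.0):
    """One bridge segment on a small local grid with a fixed variance."""
    grid = fm.GridSpec(
        origin_x=-n / 2 * cell, origin_y=-n / 2 * cell, cell_side=cell,
        n_cols=n, n_rows=n, lon0=90.0, lat0=30.0,
    )
    ev = planar_event([0.0, T], [-1500.0, 1500.0], [0.0, 0.0], err[0])
    ev.fixes.loc[1, "error_sd"] = err[1]
    prof = fm.VarianceProfile(sigma2_m=np.array([s2]))
    cfg = DbbmmConfig(alpha_steps=alpha_steps, truncation_radius=trunc)
    return fm.compute_ud(ev, prof, grid, cfg), grid, ev, prof


class TestComputeUd:
    def test_unit_mass(self, small_cohort):
        for ud in small_cohort["event_uds"]:
            assert ud.mass.sum() == pytest.approx(1.0, abs=1e-6)
            assert (ud.mass >= 0).all()

    def test_degenerate_bridge_hugs_the_line(self):
        cell = 1000.0
        grid = fm.GridSpec(origin_x=-5_000, origin_y=-5_000, cell_side=cell,
                           n_cols=30, n_rows=10, lon0=90.0, lat0=30.0)
        ev = planar_event([0.0, 7200.0], [0.0, 20_000.0], [500.0, 500.0], 1e-3)
        prof = fm.VarianceProfile(sigma2_m=np.array([1e-6]))
        ud = fm.compute_ud(ev, prof, grid, DbbmmConfig())
        on_line = ud.mass[grid.cell_index(np.zeros(1), np.array([500.0]))[0][()], :].sum()
        assert on_line >= 0.99

    def test_matches_monte_carlo_rasterization(self):
        """Cell masses match a 1e6-sample MC rasterization of the same
        alpha-discretized bridge: per-cell agreement within 3 binomial SE
        at the nominal exceedance rate (and never beyond 5 SE).  The
        endpoint errors are set well above the cell side so the
        rasterizer's density-at-centre approximation is negligible
        against the binomial noise."""
        err = 1000.0
        ud, grid, ev, prof = _single_segment_ud(trunc=8.0, err=(err, err))
        rng = np.random.default_rng(12345)
        K = 25
        alphas = np.linspace(0, 1, K)
        wts = np.full(K, 1 / (K - 1))
        wts[[0, -1]] *= 0.5
        n = 1_000_000
        ks = rng.choice(K, size=n, p=wts)
        al = alphas[ks]
        s = 7200.0 * al * (1 - al) * 50.0 + (1 - al) ** 2 * err**2 + al**2 * err**2
        mx = -1500.0 + al * 3000.0
        pts_x = mx + rng.normal(0, np.sqrt(s))
        pts_y = rng.normal(0, np.sqrt(s))
        row, col = grid.cell_index(pts_x, pts_y)
        ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        counts = np.zeros_like(ud.mass)
        np.add.at(counts, (row[ok], col[ok]), 1)
        p_mc = counts / n
        p_model = ud.mass
        sel = p_model > 1e-4
        se = np.sqrt(np.maximum(p_model, 1 / n) * (1 - p_model) / n)
        z = np.abs(p_mc - p_model) / se
        assert np.mean(z[sel] > 3.0) <= 0.01
        assert np.max(z[sel]) < 5.0

    def test_translation_equivariance(self):
        ud1, grid, ev, prof = _single_segment_ud()
        dx, dy = 5 * grid.cell_side, -3 * grid.cell_side
        ev2 = planar_event(
            ev.fixes["timestamp"].astype("int64").to_numpy() / 1e9 - 1262304000.0,
            ev.fixes["x"].to_numpy() + dx, ev.fixes["y"].to_numpy() + dy,
            300.0,
        )
        ud2 = fm.compute_ud(ev2, prof, grid.shifted(dx, dy), DbbmmConfig())
        np.testing.assert_array_equal(ud1.mass, ud2.mass)

    def test_alpha_integration_converged(self):
        ud25, *_ = _single_segment_ud(alpha_steps=25)
        ud50, *_ = _single_segment_ud(alpha_steps=50)
        assert np.max(np.abs(ud25.mass - ud50.mass)) < 1e-4

    def test_boundary_mass_raises(self):
        grid = square_grid(n=4, side=500.0, origin=(-1000.0, -1000.0))
        ev = planar_event([0.0, 7200.0], [-1500.0, 1500.0], [0.0, 0.0], 300.0)
        prof = fm.VarianceProfile(sigma2_m=np.array([50.0]))
        with pytest.raises(GridTooSmallError):
            fm.compute_ud(ev, prof, grid, DbbmmConfig())

    def test_stopover_flight_variance_contrast(self, small_cohort):
        """Transit legs get larger estimated sigma2_m than stopovers."""
        cfg, truths = small_cohort["cfg"], small_cohort["truths"]
        flights, stops = [], []
        for ev in small_cohort["events"]:
            prof = fm.estimate_variances(ev)
            sp = np.hypot(np.diff(ev.fixes["x"]), np.diff(ev.fixes["y"])) / np.diff(
                ev.fixes["timestamp"].astype("int64") / 1e9
            )
            fast = sp > np.median(sp)
            flights.append(np.mean(prof.sigma2_m[fast]))
            stops.append(np.mean(prof.sigma2_m[~fast]))
        assert np.mean(flights) > np.mean(stops)
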