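"""The synthetic cohort generator and its ground-truth guarantees."""

import numpy as np
import pandas as pd
import pytest

import flywaymap as fm


class TestSimulateIndividual:
    def test_single_site_scenario_stays_winter_bounded(self):
        pop = fm.PopulationSpec(
            name="P", species="S", n_individuals=1,
            waypoints=((85.0, 20.0), (85.0, 20.0001)),
        )
        cfg = fm.ScenarioConfig(
            populations=(pop,), winter_dwell_days=30.0, breeding_dwell_days=0.0,
            final_winter_dwell_days=0.0, gps_fraction=1.0, rng_seed=4,
        )
        track, truth = fm.simulate_individual(cfg, 0)
        # essentially no travel: displacement bounded by OU jitter + GPS error
        x, y = truth.true_x, truth.true_y
        assert np.hypot(x - x.mean(), y - y.mean()).max() < 10_000.0

    def test_short_corridor_rejected(self):
        with pytest.raises(ValueError, match="waypoints"):
            fm.PopulationSpec(name="P", species="S", n_individuals=1,
                              waypoints=((85.0, 20.0),))

    def test_gps_gap_mean_matches_configuration(self):
        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=40, rng_seed=9, gps_fraction=1.0
        )
        tracks, _, _ = fm.simulate_cohort(cfg)
        gaps = np.concatenate(
            [t.fixes["timestamp"].diff().dt.total_seconds().dropna() / 3600 for t in tracks]
        )
        assert abs(gaps.mean() - 4.5) / 4.5 < 0.10

    def test_argos_gap_mean_matches_configuration(self):
        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=25, rng_seed=9, gps_fraction=0.0
        )
        tracks, _, _ = fm.simulate_cohort(cfg)
        gaps = np.concatenate(
            [t.fixes["timestamp"].diff().dt.total_seconds().dropna() / 3600 for t in tracks]
        )
        assert abs(gaps.mean() - 22.4) / 22.4 < 0.10

    def test_displacement_variance_matches_configured_sigma2(self):
        """Error-free GPS fixes: per-regime displacement variance per unit
        time recovers the configured diffusion within 15%."""
        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=10, rng_seed=5, gps_fraction=1.0,
        )
        tracks, truths, _ = fm.simulate_cohort(cfg)
        for regime, target in [
            ("WINTER", cfg.stopover_sigma2),
            ("SPRING_MIG", cfg.flight_sigma2),
        ]:
            tot_sq, tot_t = 0.0, 0.0
            for tr, gt in zip(tracks, truths):
                t = tr.fixes["timestamp"].astype("int64").to_numpy() / 1e9
                seg_ok = (gt.regime[:-1] == regime) & (gt.regime[1:] == regime)
                # the diffusing part is the deviation from the schedule backbone
                dx = np.diff(gt.true_x - gt.backbone_x)[seg_ok]
                dy = np.diff(gt.true_y - gt.backbone_y)[seg_ok]
                dt = np.diff(t)[seg_ok]
                tot_sq += np.sum(dx**2 + dy**2)
                tot_t += 2 * np.sum(dt)  # two axes
            est = tot_sq / tot_t
            assert abs(est - target) / target < 0.15

    def test_argos_class_mix_and_errors(self):
        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=20, rng_seed=2, gps_fraction=0.0
        )
        tracks, _, _ = fm.simulate_cohort(cfg)
        classes = pd.concat([t.fixes["location_class"] for t in tracks])
        freq = classes.value_counts(normalize=True)
        assert freq.idxmax() == "B"  # B-heavy mix
        assert set(freq.index) <= {"3", "2", "1", "0", "A", "B", "Z"}


class TestSimulateCohort:
    def test_fixed_seed_is_bit_identical(self):
        cfg = fm.default_scenario(n_populations=2, individuals_per_population=2, rng_seed=21)
        t1, g1, m1 = fm.simulate_cohort(cfg)
        t2, g2, m2 = fm.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.fixes, b.fixes)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.true_x, b.true_x)

    def test_grouping_table_covers_every_animal(self):
        cfg = fm.default_scenario(n_populations=3, individuals_per_population=2, rng_seed=1)
        tracks, _, groups = fm.simulate_cohort(cfg)
        assert set(groups["animal_id"]) == {t.animal_id for t in tracks}
        assert groups["population"].nunique() == 3

    def test_regime_labels_partition_the_timeline(self):
        cfg = fm.default_scenario(n_populations=1, individuals_per_population=3, rng_seed=8,
                                  molt_dwell_days=20.0)
        tracks, truths, _ = fm.simulate_cohort(cfg)
        seen = set()
        for tr, gt in zip(tracks, truths):
            assert len(gt.regime) == len(tr.fixes)
            seen |= set(gt.regime)
        from flywaymap.synthetic import REGIMES

        assert seen <= set(REGIMES)
        assert {"WINTER", "SPRING_MIG", "BREED", "FALL_MIG", "MOLT"} <= seen

    def test_segmentation_recovers_event_boundaries(self):
        """On clean GPS tracks the detected events match the true
        migration spans within +/- 2 fixes."""
        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=5, rng_seed=13, gps_fraction=1.0
        )
        tracks, truths, _ = fm.simulate_cohort(cfg)
        recovered = 0
        for tr, gt in zip(tracks, truths):
            t = tr.fixes["timestamp"].astype("int64").to_numpy() / 1e9
            days = (t - t[0]) / 86400.0
            events = [e for e in fm.preprocess_track(tr) if e.complete]
            for _, row in gt.event_boundaries.iterrows():
                true_lo = np.searchsorted(days, row.t_start_days)
                true_hi = np.searchsorted(days, row.t_end_days)
                match = [
                    e
                    for e in events
                    if abs(np.searchsorted(days, (e.fixes["timestamp"].iloc[0] - tr.fixes["timestamp"].iloc[0]).total_seconds() / 86400.0) - true_lo) <= 2
                    and abs(np.searchsorted(days, (e.fixes["timestamp"].iloc[-1] - tr.fixes["timestamp"].iloc[0]).total_seconds() / 86400.0) - true_hi) <= 2
                ]
                if match:
                    recovered += 1
        total_true = sum(len(gt.event_boundaries) for gt in truths)
        assert recovered / total_true >= 0.8

    def test_distant_populations_yield_nearly_disjoint_flyways(self, small_cohort):
        """Corridors hundreds of km apart produce population UDs with
        low overlap."""
        pops = list(small_cohort["levels"]["POPULATION"].values())
        assert len(pops) == 2
        assert fm.percent_vi(pops[0], pops[1]) < 5.0


class TestEndToEndRecovery:
    def test_flyway_mass_concentrates_on_true_corridor(self):
        """Densely sampled, low-error GPS cohort: >= 95% of the flyway UD
        mass lies within 2 cell-widths of the true-path envelope."""
        from scipy.spatial import cKDTree

        from flywaymap.telemetry import Track

        cfg = fm.default_scenario(
            n_populations=1, individuals_per_population=4, rng_seed=23,
            gps_fraction=1.0, gps_gap_hr=1.0,
        )
        tracks, truths, groups = fm.simulate_cohort(cfg)
        events = [e for tr in tracks for e in fm.preprocess_track(tr)]
        ev_tracks = [Track(animal_id=e.animal_id, fixes=e.fixes) for e in events]
        ev_tracks, center = fm.project_fixes(ev_tracks)
        for e, t in zip(events, ev_tracks):
            e.fixes = t.fixes
        grid = fm.make_grid(ev_tracks, cell_area_km2=40.0, pad_m=300_000.0, center=center)
        uds = [fm.fit_event_ud(e, grid)[0] for e in events]
        fly = fm.build_flyway(uds, groups)["MULTISPECIES"]["ALL"]

        # densify every true path at sub-cell spacing; nearest-sample
        # distance then upper-bounds distance to the path, so the check
        # is conservative
        samples = []
        spacing = grid.cell_side / 3
        for gt in truths:
            x, y = fm.laea_project(gt.true_lon, gt.true_lat, grid.lon0, grid.lat0)
            seg = np.hypot(np.diff(x), np.diff(y))
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            t = np.arange(0.0, arc[-1], spacing)
            samples.append(np.c_[np.interp(t, arc, x), np.interp(t, arc, y)])
        tree = cKDTree(np.vstack(samples))

        rows, cols = np.nonzero(fly.mass > 0)
        mass = fly.mass[rows, cols]
        d, _ = tree.query(np.c_[grid.x_centers[cols], grid.y_centers[rows]])
        inside_mass = mass[d <= 2 * grid.cell_side].sum()
        assert inside_mass >= 0.95
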