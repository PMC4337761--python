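# flywaymap

Probabilistic mapping of migratory-bird flyways from satellite and GPS
telemetry, using dynamic Brownian bridge movement models (dBBMM).

Classical flyway maps are qualitative outlines drawn from band returns and
surveys. Given individual tracking data, a movement-model alternative is to
estimate, for every migration event, a **utilization distribution (UD)** — a
probability surface of where the animal was between its observed fixes — and
to aggregate those surfaces across events, individuals, populations and
species into quantitative flyway maps that distinguish stopover sites from
flight corridors. `flywaymap` implements that pipeline end to end, plus a
subsampling analysis that asks whether the number of tracked birds was
sufficient for the map to be representative.

## The model

Between two fixes $z_a$ (time $t_a$, positional error SD $\delta_a$) and
$z_b$ ($t_b$, $\delta_b$), the animal's position at intermediate time
fraction $\alpha = (t - t_a)/T$, $T = t_b - t_a$, is modelled as a Brownian
bridge with per-axis variance

$$s(\alpha) = T\,\alpha(1-\alpha)\,\sigma^2_m \;+\; (1-\alpha)^2\delta_a^2
\;+\; \alpha^2\delta_b^2 ,$$

where $\sigma^2_m$ (m²/s) is the Brownian motion variance — the animal's
mobility. The *dynamic* model lets $\sigma^2_m$ change along the track: a
sliding window of $w$ fixes (default 31) estimates $\sigma^2_m$ by maximum
likelihood, treating every second fix as an independent observation of the
bridge through its neighbours, and uses BIC to decide between one variance
for the window or two variances split at a behavioural breakpoint (breakpoints
are excluded from a margin of $m$ fixes, default 11, at each window end).
The UD of an event is the time-integrated bridge density rasterized on a
shared equal-area grid (default cell area 10 km²) and normalized to 1.

Flyway maps are weighted sums of UDs re-scaled to unit mass, weighting each
migration event by its duration in days, and each individual / population /
species by its mean event duration. Cumulative-probability contours classify
the map: the 50% highest-density region marks stopover sites, 50–75% core
movement areas, 75–99% flight corridors.

The sensitivity analysis computes, for k = 1, 4, 7, … up to n individuals,
the mean **percent volume of intersection**
$\%VI = 100\sum_{cells}\min(p, q)$ between UDs aggregated from up to 100
random k-subsets and the full-sample flyway UD, and smooths the curve with
LOESS. A curve still climbing at k = n means the sample under-represents the
flyway.

Because real multi-species telemetry compilations are rarely public, the
package ships a synthetic-track generator with exact ground truth (regime
labels, true coordinates, true $\sigma^2_m$): birds winter at a corridor's
southern end, migrate through stopovers to a breeding site (optionally a
separate molting site), and return, observed through GPS (~4.5 h gaps,
23.5 m error) or Argos sensors (~22.4 h gaps, class-dependent error from
0.45 km for class 3 to 7.92 km for class B).

## Worked example

```python
import flywaymap as fm
from flywaymap.telemetry import Track

# simulate two populations of three birds each
cfg = fm.default_scenario(n_populations=2, individuals_per_population=3,
                          rng_seed=11)
tracks, truths, groups = fm.simulate_cohort(cfg)

# preprocess: hourly best fix, speed filter, error model, event segmentation
events = [e for tr in tracks for e in fm.preprocess_track(tr)]

# shared equal-area grid and one UD per migration event
ev_tracks = [Track(animal_id=e.animal_id, fixes=e.fixes) for e in events]
ev_tracks, center = fm.project_fixes(ev_tracks)
for e, t in zip(events, ev_tracks):
    e.fixes = t.fixes
grid = fm.make_grid(ev_tracks, cell_area_km2=40.0, pad_m=500_000.0, center=center)
uds = [fm.fit_event_ud(e, grid)[0] for e in events]

# aggregate to the multi-species flyway and contour it
levels = fm.build_flyway(uds, groups)
flyway = levels["MULTISPECIES"]["ALL"]
for c in fm.contour_set(flyway).contours:
    print(f"{c.level}% {c.zone:9s} {c.cell_mask.sum():6d} cells "
          f"mass {c.enclosed_mass:.4f}")

pops = list(levels["POPULATION"].values())
print(f"population overlap: {fm.percent_vi(pops[0], pops[1]):.2f} %VI")
```

Output:

```
50% STOPOVER      40 cells mass 0.5007
75% CORE        1758 cells mass 0.7500
99% CORRIDOR   44707 cells mass 0.9900
population overlap: 0.00 %VI
```

Half the probability mass concentrates in ~40 stopover cells while the
corridors of the 99% contour cover two orders of magnitude more area — the
stopover/flight contrast the dynamic variance is designed to expose — and
the two simulated populations, whose corridors lie several hundred
kilometres apart, overlap by essentially zero.

There is also a small CLI: `flyway simulate`, `flyway preprocess`,
`flyway run` (full pipeline to rasters + GeoJSON contours) and
`flyway sensitivity`; see `flyway --help`.

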