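import numpy as np
import pandas as pd
import pytest

import flywaymap as fm
from flywaymap.telemetry import Track


@pytest.fixture(scope="session")
def small_cohort():
    """Two populations x three birds, run through the whole pipeline once.

    Shared across aggregation / sensitivity / acceptance tests; the grid
    is coarsened (40 km^2 cells) to keep the session fast while leaving
    hundreds of occupied cells.
    """
    cfg = fm.default_scenario(n_populations=2, individuals_per_population=3, rng_seed=11)
    tracks, truths, groups = fm.simulate_cohort(cfg)
    events = []
    for tr in tracks:
        events.extend(fm.preprocess_track(tr))
    ev_tracks = [Track(animal_id=e.animal_id, fixes=e.fixes) for e in events]
    ev_tracks, center = fm.project_fixes(ev_tracks)
    for e, t in zip(events, ev_tracks):
        e.fixes = t.fixes
    grid = fm.make_grid(ev_tracks, cell_area_km2=40.0, pad_m=500_000.0, center=center)
    uds = [fm.fit_event_ud(e, grid)[0] for e in events]
    levels = fm.build_flyway(uds, groups)
    return {
        "cfg": cfg,
        "tracks": tracks,
        "truths": truths,
        "groups": groups,
        "events": events,
        "grid": grid,
        "event_uds": uds,
        "levels": levels,
        "flyway": levels["MULTISPECIES"]["ALL"],
    }
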