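"""Duration-weighted aggregation of UDs and cumulative-probability contours.

A flyway map at any level (individual, population, species,
multi-species) is a weighted sum of child UDs re-scaled to unit mass.
Event UDs are weighted by their migration-event duration in days;
every level above that is weighted by the child's mean migration-event
duration, so long-duration routes contribute proportionally more dwell
time to the map.  Contours are highest-density cell sets: the 50%
contour marks stopover sites, 50-75% core movement areas and 75-99%
flight corridors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping

from .dbbmm import UtilizationDistribution
from .telemetry import GridSpec, laea_unproject

logger = logging.getLogger("flywaymap")

LEVELS = ("EVENT", "INDIVIDUAL", "POPULATION", "SPECIES", "MULTISPECIES")

#: Zone semantics of the standard contour levels.
ZONE_LABELS = {50: "STOPOVER", 75: "CORE", 99: "CORRIDOR"}


def aggregate_uds(
    children: Sequence[tuple[UtilizationDistribution, float]],
    metadata: dict | None = None,
) -> UtilizationDistribution:
    """Weighted sum of child UDs, re-scaled to unit mass.

    ``children`` is a sequence of (UD, weight_days) pairs sharing one
    :class:`GridSpec`.  Weights must be positive; a common rescaling of
    all weights leaves the result unchanged.
    """
    if not children:
        raise ValueError("aggregate_uds needs at least one child UD")
    grid = children[0][0].grid
    acc = np.zeros_like(children[0][0].mass)
    for ud, weight in children:
        if ud.grid != grid:
            raise ValueError("all child UDs must share one GridSpec")
        if not weight > 0:
            raise ValueError(f"aggregation weight must be positive, got {weight!r}")
        acc += weight * ud.mass
    acc /= acc.sum()
    return UtilizationDistribution(grid=grid, mass=acc, metadata=metadata or {})


def _mean_duration(ud: UtilizationDistribution) -> float:
    d = ud.metadata.get("duration_days")
    if d is None or not d > 0:
        raise ValueError("child UD lacks a positive duration_days in metadata")
    return float(d)


def build_flyway(
    event_uds: Sequence[UtilizationDistribution],
    groups: pd.DataFrame,
) -> dict[str, dict[str, UtilizationDistribution]]:
    """Aggregate event UDs up the full hierarchy.

    ``groups`` maps each animal to its population and species
    (columns ``animal_id, population, species``).  Returns
    ``{"INDIVIDUAL": {animal: UD}, "POPULATION": {pop: UD},
    "SPECIES": {species: UD}, "MULTISPECIES": {"ALL": UD}}``.
    Seasons are pooled: spring and fall events of an animal feed one
    individual route.

    Weights: event UDs by event duration; individuals, populations and
    species by their mean migration-event duration.
    """
    groups = groups.astype({"animal_id": str, "population": str, "species": str})
    lookup = groups.drop_duplicates("animal_id").set_index("animal_id")
    by_animal: dict[str, list[UtilizationDistribution]] = {}
    for ud in event_uds:
        animal = str(ud.metadata["animal_id"])
        if animal not in lookup.index:
            raise KeyError(f"animal {animal!r} missing from the grouping table")
        by_animal.setdefault(animal, []).append(ud)

    individual: dict[str, UtilizationDistribution] = {}
    mean_dur: dict[str, float] = {}
    for animal, uds in by_animal.items():
        durations = [_mean_duration(u) for u in uds]
        individual[animal] = aggregate_uds(
            list(zip(uds, durations)),
            metadata={
                "level": "INDIVIDUAL",
                "animal_id": animal,
                "duration_days": float(np.mean(durations)),
                "n_events": len(uds),
            },
        )
        mean_dur[animal] = float(np.mean(durations))

    def roll_up(members: dict[str, list[str]], child: dict, level: str) -> dict:
        out = {}
        for name, keys in members.items():
            pairs = [(child[k], _mean_duration(child[k])) for k in keys]
            mean_d = float(np.mean([w for _, w in pairs]))
            out[name] = aggregate_uds(
                pairs,
                metadata={"level": level, "name": name, "duration_days": mean_d,
                          "n_children": len(pairs)},
            )
        return out

    pops: dict[str, list[str]] = {}
    for animal in individual:
        pops.setdefault(str(lookup.loc[animal, "population"]), []).append(animal)
    population = roll_up(pops, individual, "POPULATION")

    spp: dict[str, list[str]] = {}
    for pop in population:
        sp = str(groups.loc[groups["population"] == pop, "species"].iloc[0])
        spp.setdefault(sp, []).append(pop)
    species = roll_up(spp, population, "SPECIES")

    multispecies = roll_up({"ALL": list(species)}, species, "MULTISPECIES")

    return {
        "INDIVIDUAL": individual,
        "POPULATION": population,
        "SPECIES": species,
        "MULTISPECIES": multispecies,
    }


# ---------------------------------------------------------------------------
# Cumulative probability contours
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    level: int  # percent
    zone: str
    enclosed_mass: float
    cell_mask: np.ndarray  # boolean grid mask of selected cells
    geometry: shapely.Geometry  # (multi)polygon in planar metres


@dataclass
class ContourSet:
    """Nested highest-density regions of a UD at the given percent levels."""

    grid: GridSpec
    contours: list[Contour] = field(default_factory=list)

    def __getitem__(self, level: int) -> Contour:
        for c in self.contours:
            if c.level == level:
                return c
        raise KeyError(level)


def contour_set(
    ud: UtilizationDistribution, levels: Sequence[int] = (50, 75, 99)
) -> ContourSet:
    """Highest-density cell sets reaching each cumulative mass level.

    Cells are ranked by mass descending (ties broken by row-major cell
    index) and the shortest prefix whose cumulative mass reaches
    q/100 is selected, so regions at increasing q are nested by
    construction.  The selected cell union is polygonized on the
    lattice (no smoothing), preserving interior holes.
    """
    for q in levels:
        if not 0 < q < 100:
            raise ValueError(f"contour level must be in (0, 100), got {q}")
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")  # stable: ties in row-major order
    csum = np.cumsum(flat[order])
    out = ContourSet(grid=ud.grid)
    for q in sorted(levels):
        k = int(np.searchsorted(csum, q / 100.0, side="left")) + 1
        k = min(k, len(flat))
        mask = np.zeros(flat.shape, dtype=bool)
        mask[order[:k]] = True
        mask = mask.reshape(ud.mass.shape)
        geom = _polygonize_mask(mask, ud.grid)
        out.contours.append(
            Contour(
                level=int(q),
                zone=ZONE_LABELS.get(int(q), f"P{q}"),
                enclosed_mass=float(csum[k - 1]),
                cell_mask=mask,
                geometry=geom,
            )
        )
    return out


def _polygonize_mask(mask: np.ndarray, grid: GridSpec) -> shapely.Geometry:
    rows, cols = np.nonzero(mask)
    boxes = [
        box(
            grid.origin_x + c * grid.cell_side,
            grid.origin_y + r * grid.cell_side,
            grid.origin_x + (c + 1) * grid.cell_side,
            grid.origin_y + (r + 1) * grid.cell_side,
        )
        for r, c in zip(rows, cols)
    ]
    return shapely.union_all(boxes, grid_size=grid.cell_side * 1e-9)


def contours_to_geojson(cs: ContourSet, path: str | Path | None = None) -> dict:
    """Export a contour set as a GeoJSON FeatureCollection in WGS84.

    Planar polygon vertices are inverse-projected through the grid's
    azimuthal equal-area centre.  Feature properties: ``level``,
    ``zone``, ``enclosed_mass``.
    """
    g = cs.grid

    def ring_to_lonlat(coords):
        xs, ys = np.array([c[0] for c in coords]), np.array([c[1] for c in coords])
        lon, lat = laea_unproject(xs, ys, g.lon0, g.lat0)
        return [[float(a), float(b)] for a, b in zip(lon, lat)]

    features = []
    for c in cs.contours:
        geom = mapping(c.geometry)
        if geom["type"] == "Polygon":
            polys = [geom["coordinates"]]
        elif geom["type"] == "MultiPolygon":
            polys = list(geom["coordinates"])
        else:  # pragma: no cover - union of boxes is always polygonal
            polys = []
        coords = [[ring_to_lonlat(ring) for ring in poly] for poly in polys]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "MultiPolygon", "coordinates": coords},
                "properties": {
                    "level": c.level,
                    "zone": c.zone,
                    "enclosed_mass": round(c.enclosed_mass, 6),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
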