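"""Observation containers and the count-redistribution step.

Structured abundance records are population-level totals surveyed inside
fixed polygons; the models work on grid cells, so each population total is
redistributed over the cells it intersects, proportionally to intersection
area (assuming individuals are homogeneously distributed within the
population), with the intersection area entering the count model as an
offset.  Opportunistic presences are point records assigned to cells and
replicated across all years (timeless replication).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["species", "population", "cell", "year", "count", "area",
                 "missing"]
PRESENCE_COLUMNS = ["species", "cell", "year", "presence", "log_road_dist",
                    "x", "y"]


@dataclass
class ObservationSet:
    """Count and presence records plus population geometry.

    ``counts``: one row per (species, population, cell, year); ``count`` is
    NaN exactly where ``missing`` is True (years without a census).
    ``presences``: one row per (species, cell, replicate year).
    ``populations``: DataFrame with columns population, species, geometry
    (shapely polygon), area.
    """

    counts: pd.DataFrame
    presences: pd.DataFrame = None
    populations: pd.DataFrame = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing_cols = [c for c in COUNT_COLUMNS if c not in self.counts]
        if missing_cols:
            raise ValueError(f"counts table lacks columns {missing_cols}")
        c = self.counts
        if (c["area"] <= 0).any():
            raise ValueError("offset areas must be positive")
        obs = c[~c["missing"]]
        if obs["count"].isna().any() or c.loc[c["missing"], "count"].notna().any():
            raise ValueError("count must be present iff the record is not "
                             "flagged missing")
        if (obs["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if self.presences is not None and len(self.presences):
            missing_cols = [col for col in PRESENCE_COLUMNS
                            if col not in self.presences]
            if missing_cols:
                raise ValueError(f"presence table lacks columns {missing_cols}")
            if not self.presences["presence"].isin([0, 1]).all():
                raise ValueError("presence indicator must be binary")

    @property
    def n_species(self) -> int:
        return int(self.counts["species"].max()) + 1

    def observed_counts(self) -> pd.DataFrame:
        return self.counts[~self.counts["missing"]]


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by weights, sum-preserving.

    Largest-remainder (Hamilton) rounding; ties broken by position for
    determinism.
    """
    w = np.asarray(weights, dtype=float)
    shares = total * w / w.sum()
    base = np.floor(shares).astype(int)
    rem = shares - base
    short = int(total - base.sum())
    if short > 0:
        order = np.lexsort((np.arange(len(w)), -rem))
        base[order[:short]] += 1
    return base


def presence_trials(presences: pd.DataFrame, domain, log_road_dist,
                    species=None, mode: str = "all_cells") -> pd.DataFrame:
    """Expand presence records into the Bernoulli support of the model.

    ``mode="all_cells"`` emits one trial per (species, cell, year): indicator
    1 where a retained record falls, 0 elsewhere — every cell is a Bernoulli
    trial of the thinned point process.  ``mode="presence_only"`` keeps just
    the positive records (the bookkeeping in which 47 locations over 10
    years contribute 470 observations).  ``log_road_dist`` is the per-cell
    observational bias covariate.
    """
    if mode == "presence_only":
        return presences.copy()
    if mode != "all_cells":
        raise ValueError(f"unknown presence-support mode {mode!r}")
    log_road_dist = np.asarray(log_road_dist, dtype=float)
    if species is None:
        species = sorted(presences["species"].unique())
    pos = {(int(r["species"]), int(r["cell"]), int(r["year"]))
           for _, r in presences.iterrows()}
    rows = []
    for j in species:
        for year in domain.years:
            for cid, (x, y) in zip(domain.cell_ids, domain.centroids):
                rows.append({
                    "species": int(j), "cell": int(cid), "year": int(year),
                    "presence": int((j, cid, int(year)) in pos),
                    "log_road_dist": float(log_road_dist[cid]),
                    "x": float(x), "y": float(y)})
    return pd.DataFrame(rows, columns=PRESENCE_COLUMNS)


def redistribute_counts(population_counts: pd.DataFrame,
                        population_polygons: dict, domain) -> pd.DataFrame:
    """Spread population totals over intersecting grid cells.

    ``population_counts`` has columns population, species, year, count
    (NaN for missing years).  Cell counts are integerized by largest-remainder
    rounding so they sum exactly to the population total; the offset is the
    population-cell intersection area in square meters.
    """
    rows = []
    for pop, geom in population_polygons.items():
        inter = []
        for cid, poly in zip(domain.cell_ids, domain.cell_polygons):
            a = geom.intersection(poly).area
            if a > 1e-9:
                inter.append((cid, a))
        if not inter:
            raise ValueError(f"population {pop!r} does not intersect the "
                             "domain grid")
        cells = np.array([c for c, _ in inter])
        areas = np.array([a for _, a in inter])
        recs = population_counts[population_counts["population"] == pop]
        for _, r in recs.iterrows():
            missing = bool(pd.isna(r["count"]))
            if missing:
                alloc = np.full(len(cells), np.nan)
            else:
                alloc = _largest_remainder(int(r["count"]), areas).astype(float)
            for cid, a, y in zip(cells, areas, alloc):
                rows.append({"species": int(r["species"]), "population": pop,
                             "cell": int(cid), "year": int(r["year"]),
                             "count": y, "area": float(a),
                             "missing": missing})
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
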