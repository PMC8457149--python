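"""Census-table processing into per-species growth series.

Raw forest-census records (tree, species, dbh, date, status) are converted
into the species-level growth signal the rooting-depth inversion regresses
on: per census interval, individual diameter growth (cm yr-1) is regressed
on ln(dbh at interval start) pooled across species to remove the size
effect, residuals are z-scored within the interval, and the species value is
the median residual of its trees.  Only canopy trees are used: dbh >= 30 cm,
species maximum height >= 30 m, complete alive records across every census,
and growth within configurable outlier bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GrowthFilter", "annual_growth", "filter_trees", "species_series"]

CENSUS_COLUMNS = ["tree_id", "species", "dbh_cm", "date", "status"]


@dataclass(frozen=True)
class GrowthFilter:
    """Selection rules for the growth population.

    min_dbh : cm — tree must be at least this large at its first census
    min_height : m — species maximum height threshold (canopy species)
    growth_bounds : cm yr-1 — per-interval growth outside these bounds marks
        the tree as an outlier record (ForestGEO-style bounds)
    min_trees : — species-intervals with fewer contributing trees are dropped
    """

    min_dbh: float = 30.0
    min_height: float = 30.0
    growth_bounds: tuple = (-0.5, 7.5)
    min_trees: int = 3


def annual_growth(census: pd.DataFrame) -> pd.DataFrame:
    """Per-tree per-interval diameter growth from consecutive census pairs.

    Returns a frame with one row per (tree, interval): species, interval
    index (0-based over the tree's consecutive census pairs aligned to the
    global census sequence), start/end dbh and dates, growth in cm yr-1, and
    whether both censuses recorded the tree alive.
    """
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    census = census.sort_values(["tree_id", "date"])
    all_dates = np.sort(census["date"].unique())
    date_index = {d: i for i, d in enumerate(all_dates)}

    rows = []
    for tree_id, g in census.groupby("tree_id", sort=False):
        dates = g["date"].to_numpy()
        if np.any(np.diff(dates) <= 0):
            raise ValueError(f"tree {tree_id!r}: census dates not strictly increasing")
        dbh = g["dbh_cm"].to_numpy(dtype=float)
        alive = (g["status"].to_numpy() == "alive")
        sp = g["species"].iloc[0]
        for j in range(len(dates) - 1):
            dt = dates[j + 1] - dates[j]
            rows.append(
                {
                    "tree_id": tree_id,
                    "species": sp,
                    "interval": date_index[dates[j]],
                    "date_start": dates[j],
                    "date_end": dates[j + 1],
                    "dbh_start": dbh[j],
                    "dbh_end": dbh[j + 1],
                    "growth_cm_yr": (dbh[j + 1] - dbh[j]) / dt,
                    "alive_both": bool(alive[j] and alive[j + 1]),
                }
            )
    return pd.DataFrame(rows)


def filter_trees(
    growth: pd.DataFrame,
    species_meta: pd.DataFrame,
    rules: GrowthFilter | None = None,
) -> pd.DataFrame:
    """Apply the canopy-tree selection rules to an :func:`annual_growth` table.

    ``species_meta`` must carry ``species`` and ``max_height_m``.  A tree is
    kept only if its species is canopy (max height >= min_height), it was at
    least ``min_dbh`` at its first census, it has an alive record for every
    census interval present in the table (complete records), and none of its
    interval growths falls outside ``growth_bounds``.
    """
    rules = rules or GrowthFilter()
    if growth.empty:
        return growth
    canopy = set(
        species_meta.loc[species_meta["max_height_m"] >= rules.min_height, "species"]
    )
    out = growth[growth["species"].isin(canopy)]

    n_intervals = growth["interval"].nunique()
    lo, hi = rules.growth_bounds

    def keep(tree: pd.DataFrame) -> bool:
        if tree["interval"].nunique() < n_intervals:
            return False  # incomplete record
        if not tree["alive_both"].all():
            return False
        first = tree.loc[tree["interval"].idxmin()]
        if first["dbh_start"] < rules.min_dbh:
            return False
        g = tree["growth_cm_yr"]
        return bool(((g >= lo) & (g <= hi)).all())

    kept = [tid for tid, tree in out.groupby("tree_id", sort=False) if keep(tree)]
    return out[out["tree_id"].isin(kept)].copy()


def species_series(
    filtered: pd.DataFrame,
    rules: GrowthFilter | None = None,
) -> pd.DataFrame:
    """Species-level growth series: median standardized size-model residuals.

    Per interval, growth is regressed on ln(dbh at interval start) pooled
    across species (ordinary least squares); residuals are z-scored within
    the interval; the species value is the median over its trees.  Only
    species-intervals with at least ``rules.min_trees`` contributing trees
    are retained.

    Returns a long frame (species, interval, growth_index, n_trees).
    """
    rules = rules or GrowthFilter()
    records = []
    for interval, block in filtered.groupby("interval", sort=True):
        x = np.log(block["dbh_start"].to_numpy(dtype=float))
        y = block["growth_cm_yr"].to_numpy(dtype=float)
        if np.unique(x).size >= 2:
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (intercept + slope * x)
        else:  # degenerate design: size carries no information
            resid = y - y.mean()
        sd = resid.std()
        z = resid / sd if sd > 0 else np.zeros_like(resid)
        block = block.assign(z=z)
        for sp, sub in block.groupby("species", sort=True):
            if len(sub) < rules.min_trees:
                continue
            records.append(
                {
                    "species": sp,
                    "interval": interval,
                    "growth_index": float(sub["z"].median()),
                    "n_trees": int(len(sub)),
                }
            )
    return pd.DataFrame(records)
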