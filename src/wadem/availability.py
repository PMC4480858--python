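"""Species-specific availability windows and daily landscape summaries.

Habitat "availability" is defined behaviorally: the 10-90% quantiles of water
depth at the species' observed foraging locations delimit the suitable depth
band. Each day, cells whose depth falls inside the closed band are available;
availability-side covariate means/SDs are computed over those cells and
use-side means over the occupied available cells. One row per species-day
(the :class:`DailyLandscapeRecord`) is the modeling unit of the temporal
foraging-conditions chain.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .covariates import CovariateStack, compute_reversal_series, season_windows
from .grid_io import DepthGrid

MIN_WINDOW_RECORDS = 10


@dataclasses.dataclass(frozen=True)
class AvailabilityWindow:
    """Suitable depth band for one species (cm, closed interval)."""

    species: str
    q_low_depth: float
    q_high_depth: float
    q_low: float = 0.10
    q_high: float = 0.90

    def __post_init__(self):
        if self.q_low_depth > self.q_high_depth:
            raise ValueError("window lower bound exceeds upper bound")


def estimate_window(
    survey: pd.DataFrame,
    grid: DepthGrid,
    species: str,
    q_low: float = 0.10,
    q_high: float = 0.90,
) -> AvailabilityWindow:
    """Depth-use quantile window for a species.

    Each survey record contributes one depth value (the depth at its cell-day),
    unweighted by flock size; quantiles use the linear-interpolation
    definition.
    """
    sub = survey[survey["species"] == species]
    if len(sub) < MIN_WINDOW_RECORDS:
        raise ValueError(
            f"need >= {MIN_WINDOW_RECORDS} records to estimate a window for {species!r}, "
            f"got {len(sub)}"
        )
    t = grid.dates.get_indexer(pd.to_datetime(sub["date"]))
    if (t < 0).any():
        raise ValueError("survey contains dates outside the depth record")
    depths = grid.depth[t, sub["row"].to_numpy(int), sub["col"].to_numpy(int)]
    lo, hi = np.quantile(depths, [q_low, q_high], method="linear")
    return AvailabilityWindow(species, float(lo), float(hi), q_low, q_high)


def available_mask(depth_slice: np.ndarray, window: AvailabilityWindow,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Boolean surface: cell available iff valid and depth within the closed band."""
    mask = (depth_slice >= window.q_low_depth) & (depth_slice <= window.q_high_depth)
    if valid is not None:
        mask = mask & valid
    return mask


# Field order matches the tidy CSV the TFC chain consumes.
RECORD_COLUMNS = [
    "species", "date", "month",
    "depth", "depth_sd", "recess", "recess_sd", "dsd", "dsd_sd",
    "reversal", "cells",
    "depth_use", "recess_use", "dsd_use",
    "flock_count", "individual_count",
]


def daily_record(
    species: str,
    date,
    cov: CovariateStack,
    survey: pd.DataFrame,
    window: AvailabilityWindow,
    reversal: pd.Series | None = None,
) -> dict:
    """One species-day landscape summary row.

    Availability statistics (mean/SD of depth, recession, DSD, plus the
    available-cell count) are taken over the day's available mask; use
    statistics over the occupied available cells, each occupied cell
    contributing once regardless of flock size. Use fields are NaN when no
    available cell is occupied.
    """
    t = cov.date_index(date)
    depth = cov.depth[t]
    mask = available_mask(depth, window, cov.valid)
    rec = {"species": species, "date": pd.Timestamp(date), "month": pd.Timestamp(date).month}
    layers = {"depth": depth, "recess": cov.recession[t], "dsd": cov.dsd[t]}
    n_avail = int(mask.sum())
    for name, layer in layers.items():
        vals = layer[mask]
        rec[name] = float(np.mean(vals)) if n_avail else np.nan
        rec[f"{name}_sd"] = float(np.std(vals, ddof=1)) if n_avail > 1 else np.nan
    rec["cells"] = n_avail
    rec["reversal"] = float(reversal.loc[pd.Timestamp(date)]) if reversal is not None else np.nan

    day = survey[(survey["species"] == species) & (survey["date"] == pd.Timestamp(date))]
    occupied = np.zeros_like(mask)
    counts = np.zeros(mask.shape, dtype=float)
    if len(day):
        r, c = day["row"].to_numpy(int), day["col"].to_numpy(int)
        np.add.at(counts, (r, c), day["count"].to_numpy(float))
        occupied[r, c] = True
    occ_avail = occupied & mask
    flocks = int(occ_avail.sum())
    rec["flock_count"] = flocks
    rec["individual_count"] = int(counts[occ_avail].sum())
    for name, layer in layers.items():
        rec[f"{name}_use"] = float(np.mean(layer[occ_avail])) if flocks else np.nan
    return rec


def build_daily_records(
    grid: DepthGrid,
    cov: CovariateStack,
    survey: pd.DataFrame,
    windows: dict[str, AvailabilityWindow],
    seasons: list | None = None,
    dates=None,
) -> pd.DataFrame:
    """Daily landscape records for every species over the requested dates.

    Defaults to the dry-season (Jan-Jun) days on which recession is defined.
    Reversal fractions are computed per species from its window.
    """
    if seasons is None:
        seasons = season_windows(grid.dates)
    if dates is None:
        in_season = np.zeros(len(grid.dates), dtype=bool)
        for s, e in seasons:
            in_season |= (grid.dates >= s) & (grid.dates <= e)
        defined = np.isfinite(cov.recession).any(axis=(1, 2))
        dates = grid.dates[in_season & defined]
    rows = []
    for species, window in windows.items():
        rev = compute_reversal_series(grid, window, seasons)
        sub = survey[survey["species"] == species]
        for date in dates:
            rows.append(daily_record(species, date, cov, sub, window, rev))
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df


def records_to_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def records_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
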