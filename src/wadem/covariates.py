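"""Hydrologic covariates derived from a daily depth stack.

Four cell-day covariates proxy the processes that control wading-bird prey
availability in a seasonally drying wetland:

* **DSD** (days since drydown): consecutive days, ending today, that a cell
  has been continuously inundated (depth > 0), capped at 1095 days (three
  years). A prey-production proxy — fish and crayfish biomass builds up over
  multi-annual inundation.
* **Recession rate**: ``(depth[t - lag] - depth[t]) / lag`` with a 14-day lag,
  cm/day, positive while the landscape dries. A prey-concentration proxy.
* **Hydroperiod**: mean days per year a cell is inundated over the record.
* **Reversal**: a within-season event where a cell dries below a species'
  lower depth-use quantile and subsequently rewets; such cells return to
  suitable depths with depleted prey.

Recession is undefined (NaN) for the first ``lag`` days of the record. DSD is
left-censored at the record start (days before the record contribute nothing).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xarray as xr

from .grid_io import DepthGrid

DSD_CAP_DAYS = 1095
RECESSION_LAG_DAYS = 14


def compute_dsd(depth: np.ndarray, cap_days: int = DSD_CAP_DAYS) -> np.ndarray:
    """Days since drydown along axis 0 of a daily depth array.

    ``dsd[t] = min(cap_days, number of consecutive days ending at t with
    depth > 0)``; zero whenever ``depth[t] <= 0``. Works on 1-D series or
    (time, ...) stacks.
    """
    depth = np.asarray(depth, dtype=float)
    wet = depth > 0
    dsd = np.zeros(depth.shape, dtype=float)
    run = np.zeros(depth.shape[1:] if depth.ndim > 1 else (), dtype=float)
    for t in range(depth.shape[0]):
        run = np.where(wet[t], np.minimum(run + 1, cap_days), 0.0)
        dsd[t] = run
    dsd[np.isnan(depth)] = np.nan
    return dsd


def compute_recession(depth: np.ndarray, lag_days: int = RECESSION_LAG_DAYS) -> np.ndarray:
    """Recession rate (cm/day) along axis 0; positive while drying.

    ``recession[t] = (depth[t - lag] - depth[t]) / lag``; NaN for ``t < lag``.
    Translation-invariant in depth.
    """
    depth = np.asarray(depth, dtype=float)
    rec = np.full(depth.shape, np.nan)
    if depth.shape[0] > lag_days:
        rec[lag_days:] = (depth[:-lag_days] - depth[lag_days:]) / float(lag_days)
    return rec


def compute_hydroperiod(depth: np.ndarray) -> np.ndarray:
    """Mean inundated days per year per cell: ``365 * (#days wet) / (#days)``."""
    depth = np.asarray(depth, dtype=float)
    wet = depth > 0
    return 365.0 * wet.sum(axis=0) / depth.shape[0]


def season_windows(dates: pd.DatetimeIndex, start=(1, 1), end=(6, 30)) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Dry-season windows (default Jan 1 - Jun 30) intersected with the record."""
    windows = []
    for year in sorted(set(dates.year)):
        s = pd.Timestamp(year=year, month=start[0], day=start[1])
        e = pd.Timestamp(year=year, month=end[0], day=end[1])
        s, e = max(s, dates[0]), min(e, dates[-1])
        if s <= e:
            windows.append((s, e))
    return windows


def compute_reversal_state(
    grid: DepthGrid,
    q_low: float,
    seasons: list[tuple[pd.Timestamp, pd.Timestamp]],
) -> np.ndarray:
    """Per cell-day boolean: has the cell dried below ``q_low`` and rewetted?

    Within each season window the state machine starts fresh. A cell is
    *reversed* on day t if on some earlier season day its depth fell strictly
    below ``q_low`` and on a later day (<= t) rose back to >= ``q_low``. Days
    outside every season window are NaN-flagged via a float array with values
    {0, 1, nan}.
    """
    state = np.full(grid.depth.shape, np.nan)
    for s, e in seasons:
        i0, i1 = grid.date_index(s), grid.date_index(e)
        below = np.zeros((grid.nrows, grid.ncols), dtype=bool)
        reversed_ = np.zeros_like(below)
        for t in range(i0, i1 + 1):
            d = grid.depth[t]
            reversed_ = reversed_ | (below & (d >= q_low))
            below = below | (d < q_low)
            state[t] = reversed_.astype(float)
    state[:, ~grid.valid] = np.nan
    return state


def compute_reversal_series(
    grid: DepthGrid,
    window,
    seasons: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> pd.Series:
    """Daily fraction of currently-available cells in a reversed state.

    ``window`` is an availability window with ``q_low_depth`` / ``q_high_depth``
    bounds; the reversal threshold is its lower bound. Days outside every
    season window are NaN; days with no available cell are 0.
    """
    if seasons is None:
        seasons = season_windows(grid.dates)
    state = compute_reversal_state(grid, window.q_low_depth, seasons)
    avail = (
        grid.valid[None, :, :]
        & (grid.depth >= window.q_low_depth)
        & (grid.depth <= window.q_high_depth)
    )
    n_avail = avail.sum(axis=(1, 2))
    n_rev = np.nansum(np.where(avail, state, 0.0), axis=(1, 2))
    frac = np.where(n_avail > 0, n_rev / np.maximum(n_avail, 1), 0.0)
    in_season = ~np.isnan(state).all(axis=(1, 2))
    frac = np.where(in_season, frac, np.nan)
    return pd.Series(frac, index=grid.dates, name="reversal")


@dataclasses.dataclass
class CovariateStack:
    """Cell-day covariates aligned with a DepthGrid.

    ``depth``, ``recession`` and ``dsd`` are (time, row, col); ``hydroperiod``
    is (row, col) and time-invariant over the record.
    """

    dates: pd.DatetimeIndex
    depth: np.ndarray
    recession: np.ndarray
    dsd: np.ndarray
    hydroperiod: np.ndarray
    valid: np.ndarray

    def date_index(self, date) -> int:
        loc = self.dates.get_indexer([pd.Timestamp(date)])[0]
        if loc < 0:
            raise KeyError(f"date {date} not in covariate stack")
        return int(loc)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "depth": (("time", "y", "x"), self.depth, {"units": "cm"}),
                "recession": (("time", "y", "x"), self.recession, {"units": "cm/day"}),
                "dsd": (("time", "y", "x"), self.dsd, {"units": "days"}),
                "hydroperiod": (("y", "x"), self.hydroperiod, {"units": "days/year"}),
                "valid": (("y", "x"), self.valid.astype(np.int8)),
            },
            coords={"time": self.dates},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CovariateStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(
                dates=pd.DatetimeIndex(pd.to_datetime(ds["time"].values)).normalize(),
                depth=ds["depth"].values.astype(float),
                recession=ds["recession"].values.astype(float),
                dsd=ds["dsd"].values.astype(float),
                hydroperiod=ds["hydroperiod"].values.astype(float),
                valid=ds["valid"].values.astype(bool),
            )


def compute_covariates(
    grid: DepthGrid,
    dsd_cap: int = DSD_CAP_DAYS,
    lag_days: int = RECESSION_LAG_DAYS,
) -> CovariateStack:
    """Compute the full covariate stack for a depth grid."""
    return CovariateStack(
        dates=grid.dates,
        depth=grid.depth,
        recession=compute_recession(grid.depth, lag_days),
        dsd=compute_dsd(grid.depth, dsd_cap),
        hydroperiod=compute_hydroperiod(grid.depth),
        valid=grid.valid,
    )
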