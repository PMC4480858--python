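"""Gridded daily water-depth stacks, survey tables, and region maps.

The spatial reference shared by every module is the integer cell lattice:
0-based, row-major ``(row, col)`` indices with row 0 at the north edge.
Projected cell-center coordinates (meters) are derived as
``x = (col + 0.5) * cell_size_m`` and ``y = (nrows - row - 0.5) * cell_size_m``.
Depths are centimeters relative to the ground surface; negative values mean
the water table is below ground and are retained ("wet" is strictly
``depth > 0``).

Supported on-disk formats: NetCDF ``(time, y, x)`` stacks with a ``depth_cm``
variable carrying a ``units`` attribute, long CSV (``date,row,col,depth_cm``),
single-band NetCDF or ESRI-ASCII surfaces, and plain CSV survey files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

SPECIES = ("egret", "ibis", "stork")

_UNIT_TO_CM = {"cm": 1.0, "centimeters": 1.0, "centimeter": 1.0, "m": 100.0, "meters": 100.0}


class GridIOError(ValueError):
    """Raised for malformed gridded or survey inputs."""


@dataclasses.dataclass
class DepthGrid:
    """Daily water-depth stack on a regular cell lattice.

    Attributes
    ----------
    dates : pd.DatetimeIndex
        Strictly increasing, gap-free daily calendar axis.
    depth : np.ndarray
        Float array shaped ``(n_days, nrows, ncols)``, cm. NaN only where
        ``valid`` is False.
    valid : np.ndarray
        Boolean ``(nrows, ncols)`` in-domain mask.
    cell_size_m : float
        Cell edge length in meters (default 400).
    """

    dates: pd.DatetimeIndex
    depth: np.ndarray
    valid: np.ndarray
    cell_size_m: float = 400.0

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.depth = np.asarray(self.depth, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth.ndim != 3:
            raise GridIOError(f"depth must be 3-D (time, row, col), got shape {self.depth.shape}")
        if self.valid.shape != self.depth.shape[1:]:
            raise GridIOError("valid mask shape does not match grid shape")
        if len(self.dates) != self.depth.shape[0]:
            raise GridIOError("date axis length does not match depth stack")
        if self.cell_size_m <= 0:
            raise GridIOError("cell_size_m must be positive")
        _check_daily_axis(self.dates)
        if not np.all(np.isfinite(self.depth[:, self.valid])):
            bad = np.argwhere(~np.isfinite(self.depth) & self.valid[None, :, :])
            t, r, c = bad[0]
            raise GridIOError(
                f"non-finite depth at valid cell (row={r}, col={c}) on {self.dates[t].date()}; "
                "missing single-cell values are not imputed"
            )

    @property
    def nrows(self) -> int:
        return self.depth.shape[1]

    @property
    def ncols(self) -> int:
        return self.depth.shape[2]

    @property
    def n_days(self) -> int:
        return self.depth.shape[0]

    def cell_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) cell-center coordinates in meters, shaped (nrows, ncols)."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        x = (cols + 0.5) * self.cell_size_m
        y = (self.nrows - rows - 0.5) * self.cell_size_m
        return x, y

    def date_index(self, date) -> int:
        ts = pd.Timestamp(date)
        loc = self.dates.get_indexer([ts])[0]
        if loc < 0:
            raise GridIOError(f"date {ts.date()} not in depth record")
        return int(loc)


@dataclasses.dataclass
class RegionMap:
    """Region label per cell (e.g. the WCA / BCNP / ENP hydrologic basins)."""

    labels: np.ndarray  # (nrows, ncols) of str; "" outside the domain

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def check_against(self, grid: DepthGrid) -> None:
        if self.labels.shape != (grid.nrows, grid.ncols):
            raise GridIOError("region map shape does not match grid")
        missing = grid.valid & (self.labels == "")
        if missing.any():
            r, c = np.argwhere(missing)[0]
            raise GridIOError(f"valid cell (row={r}, col={c}) has no region label")

    @property
    def levels(self) -> list[str]:
        return sorted({str(v) for v in self.labels.ravel() if v})


def _check_daily_axis(dates: pd.DatetimeIndex) -> None:
    if len(dates) == 0:
        raise GridIOError("empty date axis")
    if dates.has_duplicates or not dates.is_monotonic_increasing:
        raise GridIOError("dates must be strictly increasing")
    full = pd.date_range(dates[0], dates[-1], freq="D")
    if len(full) != len(dates):
        missing = full.difference(dates)
        shown = ", ".join(str(d.date()) for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise GridIOError(f"gap in daily date axis; missing: {shown}{more}")


# ---------------------------------------------------------------------------
# DepthGrid readers/writers


def read_depth_grid(path: str | Path) -> DepthGrid:
    """Read a daily depth stack from NetCDF (``depth_cm`` variable) or long CSV.

    CSV columns: ``date,row,col,depth_cm``. Cells absent from the CSV on every
    date are marked invalid; a cell present on some dates but not others is an
    error (no imputation). NetCDF variables must carry a ``units`` attribute.
    """
    path = Path(path)
    if path.suffix.lower() in {".nc", ".cdf", ".nc4"}:
        return _read_depth_netcdf(path)
    return _read_depth_csv(path)


def _read_depth_netcdf(path: Path) -> DepthGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = "depth_cm" if "depth_cm" in ds else "depth" if "depth" in ds else None
        if name is None:
            raise GridIOError(f"{path}: no depth variable (expected 'depth_cm')")
        da = ds[name]
        units = da.attrs.get("units")
        if not units:
            raise GridIOError(f"{path}: depth variable lacks a 'units' attribute")
        scale = _UNIT_TO_CM.get(str(units).lower())
        if scale is None:
            raise GridIOError(f"{path}: unsupported depth units {units!r}")
        depth = da.values.astype(float) * scale
        dates = pd.DatetimeIndex(pd.to_datetime(da["time"].values)).normalize()
        cell_size = float(ds.attrs.get("cell_size_m", 400.0))
    valid = np.isfinite(depth).all(axis=0)
    partial = np.isfinite(depth).any(axis=0) & ~valid
    if partial.any():
        r, c = np.argwhere(partial)[0]
        raise GridIOError(f"{path}: cell (row={r}, col={c}) has depth on some days only")
    return DepthGrid(dates=dates, depth=depth, valid=valid, cell_size_m=cell_size)


def _read_depth_csv(path: Path) -> DepthGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "row", "col", "depth_cm"}
    if not required.issubset(df.columns):
        raise GridIOError(f"{path}: CSV must have columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    _check_daily_axis(dates)
    nrows = int(df["row"].max()) + 1
    ncols = int(df["col"].max()) + 1
    depth = np.full((len(dates), nrows, ncols), np.nan)
    t = dates.get_indexer(df["date"])
    depth[t, df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["depth_cm"].to_numpy(float)
    valid = np.isfinite(depth).all(axis=0)
    partial = np.isfinite(depth).any(axis=0) & ~valid
    if partial.any():
        r, c = np.argwhere(partial)[0]
        raise GridIOError(f"{path}: cell (row={r}, col={c}) has depth on some days only")
    return DepthGrid(dates=dates, depth=depth, valid=valid)


def write_depth_grid(grid: DepthGrid, path: str | Path) -> Path:
    """Write a DepthGrid to NetCDF (.nc) or long CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in {".nc", ".cdf", ".nc4"}:
        da = xr.DataArray(
            grid.depth,
            dims=("time", "y", "x"),
            coords={"time": grid.dates},
            name="depth_cm",
            attrs={"units": "cm"},
        )
        ds = da.to_dataset()
        ds.attrs["cell_size_m"] = grid.cell_size_m
        ds.to_netcdf(path, engine="scipy")
        return path
    t, r, c = np.nonzero(np.broadcast_to(grid.valid, grid.depth.shape))
    df = pd.DataFrame(
        {
            "date": grid.dates[t].strftime("%Y-%m-%d"),
            "row": r,
            "col": c,
            "depth_cm": grid.depth[t, r, c],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Single-band surfaces


def write_surface(path: str | Path, values: np.ndarray, cell_size_m: float = 400.0) -> Path:
    """Write one grid-shaped band to NetCDF (.nc) or ESRI-ASCII (.asc).

    NaN encodes cells outside the valid domain and round-trips through the
    ASCII NODATA value.
    """
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise GridIOError(f"surface must be 2-D, got shape {values.shape}")
    if path.suffix.lower() in {".nc", ".cdf"}:
        da = xr.DataArray(values, dims=("y", "x"), name="value", attrs={"units": "1"})
        ds = da.to_dataset()
        ds.attrs["cell_size_m"] = cell_size_m
        ds.to_netcdf(path, engine="scipy")
        return path
    nrows, ncols = values.shape
    nodata = -9999
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0\n")
        fh.write("yllcorner 0\n")
        fh.write(f"cellsize {cell_size_m:.17g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values:
            fh.write(" ".join(f"{nodata}" if not np.isfinite(v) else f"{v:.17g}" for v in row))
            fh.write("\n")
    return path


def read_surface(path: str | Path) -> np.ndarray:
    """Read a single-band surface written by :func:`write_surface`."""
    path = Path(path)
    if path.suffix.lower() in {".nc", ".cdf"}:
        with xr.open_dataset(path, engine="scipy") as ds:
            return ds["value"].values.astype(float)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    if "nrows" in header and values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridIOError(f"{path}: data block does not match declared dimensions")
    return values


# ---------------------------------------------------------------------------
# Survey tables


def validate_survey(df: pd.DataFrame, grid: DepthGrid | None = None) -> pd.DataFrame:
    """Validate a survey DataFrame in place and return it normalized.

    Columns: date (datetime), row, col (int cell indices), species, count.
    """
    required = ["date", "row", "col", "species", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GridIOError(f"survey missing columns {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    df["count"] = df["count"].astype(int)
    df["species"] = df["species"].astype(str)
    unknown = ~df["species"].isin(SPECIES)
    if unknown.any():
        idx = int(np.flatnonzero(unknown.to_numpy())[0])
        raise GridIOError(f"record {idx}: unknown species {df['species'].iloc[idx]!r}")
    bad_count = df["count"] < 1
    if bad_count.any():
        idx = int(np.flatnonzero(bad_count.to_numpy())[0])
        raise GridIOError(f"record {idx}: count must be >= 1, got {df['count'].iloc[idx]}")
    if grid is not None:
        out = (
            (df["row"] < 0)
            | (df["row"] >= grid.nrows)
            | (df["col"] < 0)
            | (df["col"] >= grid.ncols)
        )
        if out.any():
            idx = int(np.flatnonzero(out.to_numpy())[0])
            raise GridIOError(
                f"record {idx}: cell (row={df['row'].iloc[idx]}, col={df['col'].iloc[idx]}) "
                "outside grid bounds"
            )
        invalid = ~grid.valid[df["row"].to_numpy(), df["col"].to_numpy()]
        if invalid.any():
            idx = int(np.flatnonzero(invalid)[0])
            raise GridIOError(
                f"record {idx}: cell (row={df['row'].iloc[idx]}, col={df['col'].iloc[idx]}) "
                "is outside the valid domain"
            )
        known = df["date"].isin(grid.dates)
        if not known.all():
            idx = int(np.flatnonzero(~known.to_numpy())[0])
            raise GridIOError(f"record {idx}: date {df['date'].iloc[idx].date()} not in depth record")
    return df.reset_index(drop=True)


def read_survey(path: str | Path, grid: DepthGrid | None = None) -> pd.DataFrame:
    """Read and validate a survey CSV (columns date,row,col,species,count)."""
    return validate_survey(pd.read_csv(Path(path)), grid=grid)


def write_survey(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def read_region_map(path: str | Path) -> RegionMap:
    """Read a region map CSV (columns row,col,region)."""
    df = pd.read_csv(Path(path))
    nrows = int(df["row"].max()) + 1
    ncols = int(df["col"].max()) + 1
    labels = np.full((nrows, ncols), "", dtype=object)
    labels[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["region"].astype(str).to_numpy()
    return RegionMap(labels=labels)


def write_region_map(region_map: RegionMap, path: str | Path) -> Path:
    r, c = np.nonzero(region_map.labels != "")
    pd.DataFrame({"row": r, "col": c, "region": region_map.labels[r, c]}).to_csv(
        Path(path), index=False
    )
    return Path(path)
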