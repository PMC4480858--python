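"""Spatial foraging conditions: the per-cell patch-abundance chain.

Each cell a species ever used gets one record: its frequency of use over the
record (count of survey dates with at least one bird) and the hydrologic
covariates averaged over exactly those instances of use — the expectation
being that covariates converge on the species' optima the more a cell is
frequented. Transformed frequency is modeled with hydrologic fixed terms, a
random region intercept, and a low-rank radial smoother fitted as a random
effect to absorb residual spatial correlation; candidates are ranked,
retained and averaged with the shared AICc machinery, and residual Moran's I
is reported with and without the smoother.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .covariates import CovariateStack, compute_reversal_state, season_windows
from .grid_io import DepthGrid, RegionMap, write_surface
from .mixed_models import (
    SmootherSpec,
    default_knot_count,
    moran_i,
    select_knots,
)
from .model_selection import AveragedModel, CandidateSet, fit_candidate_set
from .tfc import inverse_transform, transform

MIN_CELLS = 50

SFC_UNIVERSE = [
    "depth", "depth^2", "recess", "recess^2", "dsd", "dsd^2",
    "reversal", "hp", "hp^2", "depth*recess", "depth*dsd", "recess*dsd",
]

SFC_MODELS: list[tuple[str, ...]] = [
    (),
    ("depth",),
    ("depth", "depth^2"),
    ("depth", "depth^2", "recess"),
    ("depth", "depth^2", "recess", "recess^2"),
    ("depth", "depth^2", "dsd", "dsd^2"),
    ("depth", "depth^2", "dsd", "dsd^2", "hp"),
    ("depth", "depth^2", "dsd", "dsd^2", "hp", "depth*dsd"),
    ("depth", "depth^2", "recess", "dsd", "depth*dsd", "recess*dsd"),
    ("recess", "recess^2"),
    ("dsd", "dsd^2"),
    ("hp",),
    ("hp", "hp^2"),
    ("dsd", "dsd^2", "hp", "hp^2"),
    ("depth", "depth^2", "recess", "recess^2", "dsd", "dsd^2"),
    ("depth", "recess", "dsd", "depth*recess", "depth*dsd", "recess*dsd"),
    ("reversal",),
    ("depth", "depth^2", "reversal"),
    ("depth", "depth^2", "dsd", "dsd^2", "reversal", "hp"),
]


def sfc_transform(species: str) -> str:
    """Fourth root, except storks (inverse square root: many single uses)."""
    return "inv_square_root" if species == "stork" else "fourth_root"


def build_cell_records(
    survey: pd.DataFrame,
    cov: CovariateStack,
    region_map: RegionMap,
    species: str,
    grid: DepthGrid | None = None,
    window=None,
    cell_size_m: float = 400.0,
) -> pd.DataFrame:
    """One row per used cell: frequency of use and use-averaged covariates.

    Per-instance covariates are taken at the (date, cell) of each use and
    averaged over exactly ``frequency`` instances. The cell-level reversal
    covariate is the share of use instances on which the cell was in a
    reversed state (requires ``grid`` and the species' availability
    ``window``; NaN otherwise).
    """
    sub = survey[survey["species"] == species]
    state = None
    if grid is not None and window is not None:
        state = compute_reversal_state(grid, window.q_low_depth, season_windows(grid.dates))
    rows: dict[tuple[int, int], dict] = {}
    nrows = cov.depth.shape[1]
    for (date, r, c), _ in sub.groupby(["date", "row", "col"]):
        t = cov.date_index(date)
        key = (int(r), int(c))
        acc = rows.setdefault(
            key,
            {"row": key[0], "col": key[1], "frequency": 0,
             "depth": 0.0, "recess": 0.0, "dsd": 0.0, "reversal": 0.0, "n_rev": 0},
        )
        acc["frequency"] += 1
        acc["depth"] += float(cov.depth[t, key[0], key[1]])
        rec = cov.recession[t, key[0], key[1]]
        acc["recess"] += float(rec) if np.isfinite(rec) else 0.0
        acc["dsd"] += float(cov.dsd[t, key[0], key[1]])
        if state is not None and np.isfinite(state[t, key[0], key[1]]):
            acc["reversal"] += float(state[t, key[0], key[1]])
            acc["n_rev"] += 1
    out = []
    for (r, c), acc in sorted(rows.items()):
        f = acc["frequency"]
        out.append(
            {
                "row": r,
                "col": c,
                "region": str(region_map.labels[r, c]),
                "frequency": f,
                "depth": acc["depth"] / f,
                "recess": acc["recess"] / f,
                "dsd": acc["dsd"] / f,
                "reversal": acc["reversal"] / acc["n_rev"] if acc["n_rev"] else np.nan,
                "hp": float(cov.hydroperiod[r, c]),
                "x_m": (c + 0.5) * cell_size_m,
                "y_m": (nrows - r - 0.5) * cell_size_m,
            }
        )
    return pd.DataFrame(out)


@dataclasses.dataclass
class SfcModel:
    """Averaged semiparametric frequency-of-use model for one species."""

    species: str
    transform_tag: str
    averaged: AveragedModel
    smoother: SmootherSpec
    grid_shape: tuple[int, int]
    cell_size_m: float
    moran_with_smoother: tuple[float, float]
    moran_without_smoother: tuple[float, float]


def _residual_surface(records: pd.DataFrame, residuals: np.ndarray,
                      shape: tuple[int, int]) -> np.ndarray:
    surf = np.full(shape, np.nan)
    surf[records["row"].to_numpy(int), records["col"].to_numpy(int)] = residuals
    return surf


def fit_sfc(
    records: pd.DataFrame,
    species: str,
    models: list[tuple[str, ...]] | None = None,
    smoother: SmootherSpec | None = None,
    knots: int | None = None,
    grid_shape: tuple[int, int] | None = None,
    cell_size_m: float = 400.0,
    seed: int = 0,
    moran_permutations: int = 999,
) -> SfcModel:
    """Fit the semiparametric cell-frequency model and average it.

    Every candidate carries the region random intercept and the radial
    smoother. Residual Moran's I of the averaged model is computed with the
    smoother contribution included and excluded.
    """
    if len(records) < MIN_CELLS:
        raise ValueError(f"need >= {MIN_CELLS} used cells, got {len(records)}")
    if grid_shape is None:
        grid_shape = (int(records["row"].max()) + 1, int(records["col"].max()) + 1)
    work = records.copy()
    tag = sfc_transform(species)
    work["_response"] = transform(work["frequency"].to_numpy(float), tag)
    if smoother is None:
        coords = work[["x_m", "y_m"]].to_numpy(float)
        k = knots if knots is not None else default_knot_count(len(work))
        smoother = SmootherSpec(knots=select_knots(coords, k, seed=seed))
    model_list = models if models is not None else SFC_MODELS
    # drop reversal-bearing candidates when the covariate is unavailable
    if work["reversal"].isna().all():
        model_list = [m for m in model_list if not any("reversal" in t for t in m)]
    cset = CandidateSet(
        response="_response",
        models=model_list,
        random_intercept="region" if work["region"].nunique() > 1 else None,
        smoother=smoother,
    )
    averaged = fit_candidate_set(work, cset)
    used = work.loc[averaged.case_index]
    y = used["_response"].to_numpy(float)
    resid_full = y - averaged.predict(used, include_random=True)
    pred_nosmooth = np.zeros(len(used))
    for rm in averaged.retained:
        p = rm.fit.predict(used, include_random=True)
        coords = used[[*rm.fit.spec.smoother_coords]].to_numpy(float)
        from .mixed_models import radial_basis

        p -= radial_basis(coords, rm.fit.spec.smoother.knots) @ np.asarray(
            rm.fit.blups["smoother"]
        )
        pred_nosmooth += rm.weight * p
    resid_nosmooth = y - pred_nosmooth
    mi_with = moran_i(_residual_surface(used, resid_full, grid_shape),
                      n_perm=moran_permutations, seed=seed)
    mi_without = moran_i(_residual_surface(used, resid_nosmooth, grid_shape),
                         n_perm=moran_permutations, seed=seed)
    return SfcModel(
        species=species,
        transform_tag=tag,
        averaged=averaged,
        smoother=smoother,
        grid_shape=grid_shape,
        cell_size_m=cell_size_m,
        moran_with_smoother=mi_with,
        moran_without_smoother=mi_without,
    )


def predict_sfc_surface(
    model: SfcModel,
    cov: CovariateStack,
    region_map: RegionMap,
    dates,
    reversal_state: np.ndarray | None = None,
    surface_path=None,
    smoother_path=None,
) -> np.ndarray:
    """Averaged-model prediction per cell on the back-transformed frequency
    scale, averaged over the date range; optionally writes the surface and
    the smoother's spatial-effect map."""
    dates = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(dates)))
    nrows, ncols = model.grid_shape
    rr, cc = np.nonzero(cov.valid)
    acc = np.zeros(len(rr))
    for date in dates:
        t = cov.date_index(date)
        table = pd.DataFrame(
            {
                "depth": cov.depth[t, rr, cc],
                "recess": cov.recession[t, rr, cc],
                "dsd": cov.dsd[t, rr, cc],
                "hp": cov.hydroperiod[rr, cc],
                "reversal": (
                    reversal_state[t, rr, cc] if reversal_state is not None else 0.0
                ),
                "region": [str(region_map.labels[r, c]) for r, c in zip(rr, cc)],
                "x_m": (cc + 0.5) * model.cell_size_m,
                "y_m": (nrows - rr - 0.5) * model.cell_size_m,
            }
        )
        eta = model.averaged.predict(table, include_random=True)
        if model.transform_tag == "fourth_root":
            eta = np.maximum(eta, 0.0)
        else:
            eta = np.maximum(eta, 1e-6)
        acc += inverse_transform(eta, model.transform_tag)
    surface = np.full((nrows, ncols), np.nan)
    surface[rr, cc] = acc / len(dates)
    if surface_path is not None:
        write_surface(surface_path, surface, model.cell_size_m)
    if smoother_path is not None:
        smooth_field = smoother_effect_surface(model, cov)
        write_surface(smoother_path, smooth_field, model.cell_size_m)
    return surface


def smoother_effect_surface(model: SfcModel, cov: CovariateStack) -> np.ndarray:
    """Retained-weight-averaged smoother BLUP field (transformed scale)."""
    from .mixed_models import radial_basis

    nrows, ncols = model.grid_shape
    rr, cc = np.nonzero(cov.valid)
    coords = np.column_stack(
        [(cc + 0.5) * model.cell_size_m, (nrows - rr - 0.5) * model.cell_size_m]
    )
    field = np.zeros(len(rr))
    for rm in model.averaged.retained:
        Z = radial_basis(coords, rm.fit.spec.smoother.knots)
        field += rm.weight * (Z @ np.asarray(rm.fit.blups["smoother"]))
    out = np.full((nrows, ncols), np.nan)
    out[rr, cc] = field
    return out


def combine_indices(
    tfc_predictions: pd.DataFrame,
    sfc_surfaces: dict,
    availability_masks: dict,
) -> pd.DataFrame:
    """Daily combined habitat report for one species.

    Per day: the TFC flock/individual index (patch quality), the SFC surface
    mean over currently-available cells (patch abundance), and the product of
    the two after dividing each by its scenario maximum — one plausible
    combination; the raw columns are all preserved.
    """
    rows = []
    for _, rec in tfc_predictions.iterrows():
        date = pd.Timestamp(rec["date"])
        if date not in sfc_surfaces or date not in availability_masks:
            raise ValueError(f"no SFC surface/availability mask for {date.date()}")
        mask = availability_masks[date]
        surf = sfc_surfaces[date]
        n_avail = int(np.asarray(mask).sum())
        patch_abundance = float(np.nanmean(surf[mask])) if n_avail else 0.0
        rows.append(
            {
                "date": date,
                "species": rec["species"],
                "tfc_flock": rec["flock"],
                "tfc_individual": rec["individual"],
                "sfc_patch_abundance": patch_abundance,
                "available_cells": n_avail,
            }
        )
    out = pd.DataFrame(rows)
    tfc_max = out["tfc_individual"].max()
    sfc_max = out["sfc_patch_abundance"].max()
    out["combined_index"] = (
        (out["tfc_individual"] / tfc_max if tfc_max > 0 else 0.0)
        * (out["sfc_patch_abundance"] / sfc_max if sfc_max > 0 else 0.0)
    )
    # no suitable habitat means zero patch quality by definition
    out.loc[out["available_cells"] == 0, "combined_index"] = 0.0
    return out
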