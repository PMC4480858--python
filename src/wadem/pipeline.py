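"""End-to-end orchestration: simulate → covariates → availability → TFC →
SFC → combined indices, with a provenance manifest.

Every stage writes plain-text artifacts (CSV/JSON/ASCII grids, NetCDF for
the depth stack) into the output directory; the manifest records the seed,
configuration and SHA-256 of each artifact, and a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .availability import (
    available_mask,
    build_daily_records,
    estimate_window,
    records_to_csv,
)
from .covariates import compute_covariates, compute_reversal_state, season_windows
from .grid_io import write_depth_grid, write_region_map, write_survey
from .model_selection import render_table, save_averaged_model
from .sfc import build_cell_records, combine_indices, fit_sfc, predict_sfc_surface
from .synthetic import ScenarioConfig, simulate_scenario
from .tfc import RESOURCES, fit_abundance, fit_selection, predict_daily

log = logging.getLogger("wadem")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    scenario: ScenarioConfig = dataclasses.field(default_factory=ScenarioConfig)
    species: tuple[str, ...] = ("egret", "ibis", "stork")
    q_low: float = 0.10
    q_high: float = 0.90
    lag_days: int = 14
    dsd_cap: int = 1095
    smoother_knots: int | None = None
    moran_permutations: int = 999
    out_dir: str = "wadem_run"

    def __post_init__(self):
        if not (0 <= self.q_low < self.q_high <= 1):
            raise ValueError("quantile levels must satisfy 0 <= q_low < q_high <= 1")
        for sp in self.species:
            if sp not in self.scenario.preferences:
                raise ValueError(f"species {sp!r} has no preference parameters")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        scenario = ScenarioConfig(**raw.pop("scenario", {}))
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(scenario=scenario, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["preferences"] = {
            sp: dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
            for sp, p in self.scenario.preferences.items()
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the artifact directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def stage(name):
        log.info("[%7.1fs] %s", time.time() - t0, name)

    stage("simulate synthetic landscape and survey")
    grid, cov, regions, survey, truth = simulate_scenario(config.scenario)
    if config.lag_days != 14 or config.dsd_cap != 1095:
        cov = compute_covariates(grid, dsd_cap=config.dsd_cap, lag_days=config.lag_days)
    artifacts.append(write_depth_grid(grid, out / "depth.nc"))
    artifacts.append(write_survey(survey, out / "survey.csv"))
    artifacts.append(write_region_map(regions, out / "regions.csv"))
    truth.to_json(out / "ground_truth.json")
    artifacts.append(out / "ground_truth.json")

    stage("availability windows and daily landscape records")
    windows = {
        sp: estimate_window(survey, grid, sp, config.q_low, config.q_high)
        for sp in config.species
    }
    (out / "windows.json").write_text(
        json.dumps(
            {
                sp: {"q_low_depth": w.q_low_depth, "q_high_depth": w.q_high_depth}
                for sp, w in windows.items()
            },
            indent=1,
        )
    )
    artifacts.append(out / "windows.json")
    days = pd.DatetimeIndex(sorted(survey["date"].unique()))
    records = build_daily_records(grid, cov, survey, windows, dates=days)
    records_to_csv(records, out / "daily_records.csv")
    artifacts.append(out / "daily_records.csv")

    seasons = season_windows(grid.dates)
    results: dict = {"windows": {sp: [windows[sp].q_low_depth, windows[sp].q_high_depth]
                                 for sp in config.species}}
    combined_frames = []
    for sp in config.species:
        stage(f"TFC chain: {sp}")
        selection_sets = {}
        for resource in RESOURCES:
            sset = fit_selection(records, sp, resource)
            selection_sets[resource] = sset
            render_table(sset.averaged, out / f"tfc_selection_{sp}_{resource}.csv")
            save_averaged_model(sset.averaged, out / f"tfc_selection_{sp}_{resource}.json")
            artifacts += [out / f"tfc_selection_{sp}_{resource}.csv",
                          out / f"tfc_selection_{sp}_{resource}.json"]
        abundance_sets = {}
        for resp in ("flock", "individual"):
            aset = fit_abundance(records, sp, resp)
            abundance_sets[resp] = aset
            render_table(aset.averaged, out / f"tfc_abundance_{sp}_{resp}.csv")
            save_averaged_model(aset.averaged, out / f"tfc_abundance_{sp}_{resp}.json")
            artifacts += [out / f"tfc_abundance_{sp}_{resp}.csv",
                          out / f"tfc_abundance_{sp}_{resp}.json"]
        sub = records[records["species"] == sp]
        preds = predict_daily(selection_sets, abundance_sets, sub)
        preds_path = out / f"tfc_predictions_{sp}.csv"
        preds.assign(date=pd.to_datetime(preds["date"]).dt.strftime("%Y-%m-%d")).to_csv(
            preds_path, index=False, float_format="%.8g"
        )
        artifacts.append(preds_path)

        stage(f"SFC chain: {sp}")
        cells = build_cell_records(
            survey, cov, regions, sp, grid=grid, window=windows[sp],
            cell_size_m=grid.cell_size_m,
        )
        sfc_model = fit_sfc(
            cells, sp,
            knots=config.smoother_knots,
            grid_shape=(grid.nrows, grid.ncols),
            cell_size_m=grid.cell_size_m,
            seed=config.scenario.seed,
            moran_permutations=config.moran_permutations,
        )
        render_table(sfc_model.averaged, out / f"sfc_{sp}.csv")
        save_averaged_model(sfc_model.averaged, out / f"sfc_{sp}.json")
        artifacts += [out / f"sfc_{sp}.csv", out / f"sfc_{sp}.json"]
        rev_state = compute_reversal_state(grid, windows[sp].q_low_depth, seasons)
        mid = days[len(days) // 2]
        predict_sfc_surface(
            sfc_model, cov, regions, [mid], reversal_state=rev_state,
            surface_path=out / f"sfc_surface_{sp}.asc",
            smoother_path=out / f"sfc_smoother_{sp}.asc",
        )
        artifacts += [out / f"sfc_surface_{sp}.asc", out / f"sfc_smoother_{sp}.asc"]

        stage(f"combined indices: {sp}")
        masks = {}
        surfaces = {}
        for d in days:
            t = grid.date_index(d)
            masks[pd.Timestamp(d)] = available_mask(grid.depth[t], windows[sp], grid.valid)
            surfaces[pd.Timestamp(d)] = predict_sfc_surface(
                sfc_model, cov, regions, [d], reversal_state=rev_state
            )
        combined = combine_indices(preds, surfaces, masks)
        combined_frames.append(combined)
        results[f"moran_{sp}"] = {
            "with_smoother": sfc_model.moran_with_smoother,
            "without_smoother": sfc_model.moran_without_smoother,
        }
        results[f"tfc_r2_{sp}"] = {
            res: selection_sets[res].averaged.r2 for res in RESOURCES
        } | {f"abund_{r}": abundance_sets[r].averaged.r2 for r in ("flock", "individual")}

    combined_all = pd.concat(combined_frames, ignore_index=True)
    combined_all.assign(
        date=pd.to_datetime(combined_all["date"]).dt.strftime("%Y-%m-%d")
    ).to_csv(out / "combined_indices.csv", index=False, float_format="%.8g")
    artifacts.append(out / "combined_indices.csv")

    (out / "summary.json").write_text(json.dumps(results, indent=1, default=float))
    artifacts.append(out / "summary.json")

    manifest = {
        "version": __version__,
        "seed": config.scenario.seed,
        "config": config.to_dict(),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    stage("done")
    return out
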