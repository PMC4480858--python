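"""Synthetic Everglades-like landscape: seasonal drying with rainfall
reversals over a daily gridded depth record, plus wading-bird counts whose
occupancy follows known preference functions — the ground-truth testbed for
the whole pipeline.

The hydrology is deliberately simple: a landscape-wide stage trajectory
(linear dry-season decline at a configurable recession rate, Poisson rain
jumps, wet-season refill) minus a spatially correlated elevation surface,
plus optional spatially correlated daily noise. Birds are simulated as
cell-day occupancy, not individual movement: each wet cell gets a latent
intensity

    w = exp( -(depth - opt)^2 / (2 tol^2)
             + slope_r * recession
             + gain_d * dsd / (dsd + h) ),

cells are occupied independently with probability proportional to ``w``
(scaled to a day-level target count that rises with landscape-mean prey
production), and occupied-cell counts are 1 plus a negative-binomial draw,
so conspecific clustering enters as count overdispersion. Every parameter is
recorded in a :class:`GroundTruth` sidecar so downstream fits can be scored
against the generating truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .covariates import CovariateStack, compute_covariates, season_windows
from .grid_io import DepthGrid, RegionMap


@dataclasses.dataclass(frozen=True)
class SpeciesPreference:
    """Generating habitat-preference parameters for one species."""

    optimal_depth_cm: float
    depth_tolerance_cm: float
    recession_slope: float  # per cm/day; positive = drying preferred
    dsd_half_sat_days: float
    dsd_gain: float  # amplitude of the saturating prey-production term


# Preference defaults echo the species' published depth niches: the egret is
# the deep/broad generalist, ibis and stork are shallower tactile foragers.
DEFAULT_PREFERENCES: dict[str, SpeciesPreference] = {
    "egret": SpeciesPreference(20.0, 14.0, 0.8, 200.0, 1.5),
    "ibis": SpeciesPreference(13.0, 11.0, 1.0, 200.0, 1.5),
    "stork": SpeciesPreference(13.0, 13.0, 0.6, 200.0, 1.5),
}


@dataclasses.dataclass
class ScenarioConfig:
    """Knobs of the synthetic landscape and survey.

    All lengths in cm, rates in cm/day, ranges in cells.
    """

    seed: int = 0
    nrows: int = 40
    ncols: int = 40
    n_years: int = 4
    cell_size_m: float = 400.0
    start_year: int = 2001
    wet_season_peak_stage_cm: float = 50.0
    dry_season_recession_mean: float = 0.4
    rain_event_rate: float = 2.0  # events per dry season
    rain_magnitude_cm: float = 10.0
    spatial_corr_range_cells: float = 4.0
    topography_relief_cm: float = 30.0
    depth_noise_sd_cm: float = 1.0
    preferences: dict[str, SpeciesPreference] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PREFERENCES)
    )
    clustering_dispersion: float = 1.0  # negative-binomial overdispersion; 0 = Poisson
    flock_size_mean: float = 5.0  # mean birds per occupied cell
    detection_scale: float = 60.0  # target occupied cells per species-day
    abundance_dsd_gain: float = 0.6  # day-level abundance link to prey production
    n_survey_days: int = 200

    def __post_init__(self):
        for name, val in (
            ("nrows", self.nrows), ("ncols", self.ncols), ("n_years", self.n_years),
            ("cell_size_m", self.cell_size_m),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rain_event_rate", "rain_magnitude_cm", "topography_relief_cm",
                     "depth_noise_sd_cm", "detection_scale", "clustering_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.spatial_corr_range_cells <= 0:
            raise ValueError("spatial_corr_range_cells must be positive")

    @classmethod
    def from_toml(cls, path) -> "ScenarioConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        prefs = raw.pop("preferences", None)
        cfg = cls(**raw)
        if prefs:
            cfg.preferences = {
                sp: SpeciesPreference(**params) for sp, params in prefs.items()
            }
        return cfg


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters and per-day latent summaries of the survey draw."""

    preferences: dict[str, SpeciesPreference]
    clustering_dispersion: float
    flock_size_mean: float
    detection_scale: float
    abundance_dsd_gain: float
    daily: pd.DataFrame  # date, species, n_target, prey_index

    def to_json(self, path) -> None:
        payload = {
            "preferences": {
                sp: dataclasses.asdict(p) for sp, p in self.preferences.items()
            },
            "clustering_dispersion": self.clustering_dispersion,
            "flock_size_mean": self.flock_size_mean,
            "detection_scale": self.detection_scale,
            "abundance_dsd_gain": self.abundance_dsd_gain,
            "daily": self.daily.assign(
                date=self.daily["date"].dt.strftime("%Y-%m-%d")
            ).to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def correlated_field(rng: np.random.Generator, nrows: int, ncols: int,
                     corr_range_cells: float) -> np.ndarray:
    """Unit-variance spatially correlated field.

    White noise convolved with a Gaussian kernel of sigma = range / 2, which
    gives an autocorrelation ``exp(-d^2 / range^2)`` — the e-folding distance
    of the correlogram equals ``corr_range_cells``.
    """
    pad = int(np.ceil(4 * corr_range_cells)) + 1
    white = rng.standard_normal((nrows + 2 * pad, ncols + 2 * pad))
    smooth = ndimage.gaussian_filter(white, sigma=corr_range_cells / 2.0, mode="constant")
    field = smooth[pad : pad + nrows, pad : pad + ncols]
    sd = smooth[pad:-pad, pad:-pad].std()
    return (field - field.mean()) / (sd if sd > 0 else 1.0)


def simulate_topography(config: ScenarioConfig) -> np.ndarray:
    """Smooth elevation surface (cm), zero mean, max - min = relief."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.topography_relief_cm == 0:
        return np.zeros((config.nrows, config.ncols))
    field = correlated_field(rng, config.nrows, config.ncols, config.spatial_corr_range_cells)
    span = np.ptp(field)
    if span == 0:
        return np.zeros((config.nrows, config.ncols))
    field = field * (config.topography_relief_cm / span)
    return field - field.mean()


def _in_dry_season(dates: pd.DatetimeIndex) -> np.ndarray:
    return np.asarray(dates.month <= 6)


def simulate_depth_grid(config: ScenarioConfig, elevation: np.ndarray | None = None) -> DepthGrid:
    """Daily depth stack: seasonal stage trajectory minus elevation plus noise.

    The stage starts each calendar year at the wet-season peak, declines at
    ``dry_season_recession_mean`` cm/day through June 30 (with Poisson rain
    jumps of ``rain_magnitude_cm``), then refills at twice the recession rate
    until it regains the peak.
    """
    if elevation is None:
        elevation = simulate_topography(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    dates = pd.date_range(
        f"{config.start_year}-01-01", periods=config.n_years * 365, freq="D"
    )
    n = len(dates)
    dry = _in_dry_season(dates)
    season_len = 181.0
    p_rain = config.rain_event_rate / season_len
    rain = np.where(
        dry & (rng.random(n) < p_rain), config.rain_magnitude_cm, 0.0
    ) if config.rain_event_rate > 0 else np.zeros(n)

    peak = config.wet_season_peak_stage_cm
    stage = np.empty(n)
    stage[0] = peak
    r = config.dry_season_recession_mean
    for t in range(1, n):
        if dry[t]:
            stage[t] = stage[t - 1] - r + rain[t]
        else:
            stage[t] = min(peak, stage[t - 1] + 2.0 * r)

    depth = stage[:, None, None] - elevation[None, :, :]
    if config.depth_noise_sd_cm > 0:
        noise = np.empty((n, config.nrows, config.ncols))
        for t in range(n):
            noise[t] = correlated_field(
                rng, config.nrows, config.ncols, config.spatial_corr_range_cells
            )
        depth = depth + config.depth_noise_sd_cm * noise
    valid = np.ones((config.nrows, config.ncols), dtype=bool)
    return DepthGrid(dates=dates, depth=depth, valid=valid, cell_size_m=config.cell_size_m)


def default_region_map(config: ScenarioConfig) -> RegionMap:
    """Three latitudinal bands standing in for the WCA / BCNP / ENP basins."""
    labels = np.full((config.nrows, config.ncols), "", dtype=object)
    thirds = np.array_split(np.arange(config.nrows), 3)
    for band, name in zip(thirds, ("WCA", "BCNP", "ENP")):
        labels[band, :] = name
    return RegionMap(labels=labels)


def latent_weights(pref: SpeciesPreference, depth: np.ndarray, recession: np.ndarray,
                   dsd: np.ndarray) -> np.ndarray:
    """Unnormalized occupancy intensity of the generator, per cell."""
    z = (
        -((depth - pref.optimal_depth_cm) ** 2) / (2.0 * pref.depth_tolerance_cm**2)
        + pref.recession_slope * np.nan_to_num(recession)
        + pref.dsd_gain * dsd / (dsd + pref.dsd_half_sat_days)
    )
    z = z - np.nanmax(z)
    return np.exp(z)


def survey_days(config: ScenarioConfig, grid: DepthGrid, cov: CovariateStack) -> pd.DatetimeIndex:
    """Evenly subsample dry-season days with defined recession to the
    configured number of survey days."""
    eligible = []
    for s, e in season_windows(grid.dates):
        span = grid.dates[(grid.dates >= s) & (grid.dates <= e)]
        for d in span:
            t = grid.date_index(d)
            if np.isfinite(cov.recession[t][grid.valid]).all():
                eligible.append(d)
    eligible = pd.DatetimeIndex(eligible)
    if len(eligible) <= config.n_survey_days:
        return eligible
    pick = np.linspace(0, len(eligible) - 1, config.n_survey_days).round().astype(int)
    return eligible[np.unique(pick)]


def simulate_survey(
    config: ScenarioConfig,
    grid: DepthGrid,
    cov: CovariateStack | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a survey table from the latent preference model.

    Returns the validated survey DataFrame (date,row,col,species,count) and
    the :class:`GroundTruth` sidecar.
    """
    if cov is None:
        cov = compute_covariates(grid)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    days = survey_days(config, grid, cov)
    records = []
    daily_rows = []
    disp = config.clustering_dispersion
    mu_extra = max(config.flock_size_mean - 1.0, 0.0)
    for species, pref in config.preferences.items():
        for d in days:
            t = grid.date_index(d)
            wet = grid.valid & (grid.depth[t] > 0)
            n_wet = int(wet.sum())
            if n_wet == 0 or config.detection_scale == 0:
                daily_rows.append(
                    {"date": d, "species": species, "n_target": 0.0, "prey_index": np.nan}
                )
                continue
            w = latent_weights(pref, grid.depth[t], cov.recession[t], cov.dsd[t])
            w = np.where(wet, w, 0.0)
            sat = cov.dsd[t] / (cov.dsd[t] + pref.dsd_half_sat_days)
            prey = float(np.mean(sat[wet]))
            g = config.abundance_dsd_gain
            n_target = config.detection_scale * ((1.0 - g) + g * prey)
            p = np.minimum(1.0, n_target * w / w.sum())
            occ = rng.random(w.shape) < p
            occ &= wet
            rr, cc = np.nonzero(occ)
            if len(rr):
                if mu_extra == 0:
                    extra = np.zeros(len(rr), dtype=int)
                elif disp > 0:
                    r_nb = 1.0 / disp
                    extra = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_extra), len(rr))
                else:
                    extra = rng.poisson(mu_extra, len(rr))
                for i in range(len(rr)):
                    records.append(
                        {"date": d, "row": int(rr[i]), "col": int(cc[i]),
                         "species": species, "count": int(1 + extra[i])}
                    )
            daily_rows.append(
                {"date": d, "species": species, "n_target": n_target, "prey_index": prey}
            )
    survey = pd.DataFrame(records, columns=["date", "row", "col", "species", "count"])
    if len(survey):
        survey["date"] = pd.to_datetime(survey["date"])
    truth = GroundTruth(
        preferences=dict(config.preferences),
        clustering_dispersion=disp,
        flock_size_mean=config.flock_size_mean,
        detection_scale=config.detection_scale,
        abundance_dsd_gain=config.abundance_dsd_gain,
        daily=pd.DataFrame(daily_rows),
    )
    return survey, truth


def simulate_scenario(config: ScenarioConfig):
    """Full synthetic dataset: (grid, covariates, region map, survey, truth)."""
    elevation = simulate_topography(config)
    grid = simulate_depth_grid(config, elevation)
    cov = compute_covariates(grid)
    regions = default_region_map(config)
    survey, truth = simulate_survey(config, grid, cov)
    return grid, cov, regions, survey, truth
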