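import numpy as np
import pandas as pd
import pytest

from wadem.availability import build_daily_records, estimate_window
from wadem.covariates import compute_covariates
from wadem.grid_io import DepthGrid
from wadem.synthetic import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A modest seeded synthetic landscape shared across test modules."""
    cfg = ScenarioConfig(seed=11, nrows=25, ncols=25, n_years=2, n_survey_days=80)
    grid, cov, regions, survey, truth = simulate_scenario(cfg)
    return {"config": cfg, "grid": grid, "cov": cov, "regions": regions,
            "survey": survey, "truth": truth}


@pytest.fixture(scope="session")
def small_records(small_scenario):
    grid = small_scenario["grid"]
    survey = small_scenario["survey"]
    cov = small_scenario["cov"]
    windows = {sp: estimate_window(survey, grid, sp) for sp in ("egret", "ibis", "stork")}
    days = pd.DatetimeIndex(sorted(survey["date"].unique()))
    records = build_daily_records(grid, cov, survey, windows, dates=days)
    return {"windows": windows, "records": records, "days": days}


@pytest.fixture
def tiny_grid():
    """15-day 4x4 grid with deterministic depths for covariate plumbing."""
    dates = pd.date_range("2002-01-01", periods=15)
    depth = np.linspace(30, 16, 15)[:, None, None] + np.arange(16).reshape(4, 4) * 1.0
    valid = np.ones((4, 4), dtype=bool)
    return DepthGrid(dates=dates, depth=depth, valid=valid)


@pytest.fixture
def tiny_cov(tiny_grid):
    return compute_covariates(tiny_grid)
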