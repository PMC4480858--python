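"""Temporal foraging-conditions chain: transforms, stage-1 selection,
stage-2 abundance, and the chained daily prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wadem.tfc import (
    abundance_transform,
    decreasing_transform,
    fit_abundance,
    fit_selection,
    flock_individual_r2,
    inverse_transform,
    predict_daily,
    transform,
)


class TestTransforms:
    def test_fourth_root_values(self):
        assert transform(16.0, "fourth_root") == pytest.approx(2.0)
        assert transform(0.0, "fourth_root") == 0.0
        assert inverse_transform(2.0, "fourth_root") == pytest.approx(16.0)

    def test_inverse_fourth_root(self):
        assert transform(16.0, "inv_fourth_root") == pytest.approx(0.5)

    def test_inverse_square_root(self):
        assert transform(4.0, "inv_square_root") == pytest.approx(0.5)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            transform(-1.0, "fourth_root")
        with pytest.raises(ValueError):
            transform(0.0, "inv_fourth_root")

    @given(st.floats(1e-3, 1e6), st.sampled_from(
        ["fourth_root", "inv_fourth_root", "inv_square_root", "identity"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_identity(self, value, tag):
        back = inverse_transform(transform(value, tag), tag)
        assert back == pytest.approx(value, rel=1e-10)

    def test_species_rules(self):
        assert abundance_transform("stork", "flock") == "inv_fourth_root"
        assert abundance_transform("stork", "individual") == "fourth_root"
        assert abundance_transform("egret", "flock") == "fourth_root"
        assert decreasing_transform("inv_fourth_root")
        assert not decreasing_transform("fourth_root")


def constructed_records(n_days=90, seed=0, use_equals_avail=False):
    """Hand-built daily records with known structure (no simulation)."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2006-01-15", periods=n_days)
    depth = rng.uniform(10, 35, n_days)
    use = depth + (0.0 if use_equals_avail else rng.normal(0, 1.0, n_days))
    if use_equals_avail:
        use = depth + rng.normal(0, 0.01, n_days)
    rec = pd.DataFrame(
        {
            "species": "egret",
            "date": dates,
            "month": dates.month,
            "depth": depth,
            "depth_sd": rng.uniform(3, 6, n_days),
            "recess": rng.normal(0.3, 0.2, n_days),
            "recess_sd": rng.uniform(0.05, 0.2, n_days),
            "dsd": rng.uniform(50, 600, n_days),
            "dsd_sd": rng.uniform(20, 80, n_days),
            "reversal": rng.uniform(0, 0.4, n_days),
            "cells": rng.integers(200, 400, n_days),
            "depth_use": use,
            "recess_use": rng.normal(0.4, 0.2, n_days),
            "dsd_use": rng.uniform(100, 700, n_days),
            "flock_count": rng.integers(5, 60, n_days),
            "individual_count": rng.integers(60, 400, n_days),
        }
    )
    return rec


class TestFitSelection:
    def test_identity_case_recovers_unit_slope(self):
        rec = constructed_records(use_equals_avail=True)
        sset = fit_selection(rec, "egret", "depth", models=[("depth",)])
        assert sset.averaged.term_table.loc["depth", "avg_pe"] == pytest.approx(1.0, abs=0.05)
        assert sset.averaged.term_table.loc["intercept", "avg_pe"] == pytest.approx(0.0, abs=1.0)

    def test_single_candidate_equals_fit(self):
        rec = constructed_records(seed=1)
        sset = fit_selection(rec, "egret", "depth", models=[("depth",)])
        rm = sset.averaged.retained[0]
        assert rm.weight == 1.0
        assert sset.averaged.term_table.loc["depth", "avg_pe"] == rm.fit.coef["depth"]

    def test_too_few_days_rejected(self):
        rec = constructed_records(n_days=40)
        rec.loc[rec.index[10:], "flock_count"] = 0
        with pytest.raises(ValueError, match="usable days"):
            fit_selection(rec, "egret", "depth")

    def test_depth_preference_dominates_when_generated(self, depth_only_fit):
        """On a depth-only synthetic preference, depth availability carries
        the importance and recession terms stay minor (fixed seed)."""
        tt = depth_only_fit.averaged.term_table
        assert tt.loc["depth", "importance"] > 0.9
        recess_imp = [tt.loc[t, "importance"] for t in tt.index if t.startswith("recess")]
        assert max(recess_imp, default=0.0) < 0.5


@pytest.fixture(scope="module")
def depth_only_scenario():
    from wadem.availability import build_daily_records, estimate_window
    from wadem.synthetic import ScenarioConfig, SpeciesPreference, simulate_scenario

    prefs = {"egret": SpeciesPreference(20.0, 10.0, 0.0, 200.0, 0.0)}
    cfg = ScenarioConfig(seed=2000, preferences=prefs)
    grid, cov, regions, survey, truth = simulate_scenario(cfg)
    w = estimate_window(survey, grid, "egret")
    days = pd.DatetimeIndex(sorted(survey["date"].unique()))
    records = build_daily_records(grid, cov, survey, {"egret": w}, dates=days)
    return records


@pytest.fixture(scope="module")
def depth_only_fit(depth_only_scenario):
    return fit_selection(depth_only_scenario, "egret", "depth")


class TestFitAbundance:
    def test_constant_response_prefers_intercept_only(self):
        rec = constructed_records(seed=2)
        rec["individual_count"] = 81  # fourth root = 3 exactly
        aset = fit_abundance(rec, "egret", "individual",
                             models=[(), ("dsd_use",), ("depth_use", "depth_use^2")])
        assert aset.averaged.retained[0].terms == ()

    def test_transform_tag_applied(self):
        rec = constructed_records(seed=3)
        rec["species"] = "stork"
        aset = fit_abundance(rec, "stork", "flock", models=[("depth_use",)])
        assert aset.transform_tag == "inv_fourth_root"

    def test_dsd_link_sign_recovered_once(self, small_scenario, small_records):
        aset = fit_abundance(
            small_records["records"], "egret", "individual",
            models=[("dsd_use", "depth", "depth_sd"),
                    ("dsd_use", "depth", "depth^2", "depth_sd")],
        )
        assert aset.averaged.term_table.loc["dsd_use", "avg_pe"] > 0

    def test_permuted_response_is_null(self, small_records):
        rng = np.random.default_rng(0)
        rec = small_records["records"]
        rec = rec[rec["species"] == "egret"].copy()
        rec["individual_count"] = rng.permutation(rec["individual_count"].to_numpy())
        aset = fit_abundance(rec, "egret", "individual")
        assert aset.averaged.r2 < 0.2
        assert (aset.averaged.term_table.drop(index="intercept")["importance"] < 0.8).all()


@pytest.fixture(scope="module")
def fitted_sets():
    rec = constructed_records(n_days=120, seed=5)
    selection = {
        r: fit_selection(rec, "egret", r, models=[(r,), (r, f"{r}_sd")])
        for r in ("depth", "recess", "dsd")
    }
    abundance = {
        resp: fit_abundance(rec, "egret", resp,
                            models=[("depth_use",), ("depth_use", "reversal")])
        for resp in ("flock", "individual")
    }
    return rec, selection, abundance


class TestPredictDaily:
    def test_prediction_consistency_on_training_rows(self, fitted_sets):
        rec, selection, abundance = fitted_sets
        preds = predict_daily(selection, abundance, rec)
        # stage-1 prediction equals the averaged model's population-level fit
        expect = selection["depth"].averaged.predict(rec, include_random=False)
        np.testing.assert_allclose(preds["depth_use_pred"].to_numpy(), expect, atol=1e-10)
        assert (preds["flock"] >= 0).all()
        assert (preds["individual"] >= 0).all()

    def test_reversal_probe_is_model_consistent(self, fitted_sets):
        """Raising the reversal fraction moves predicted abundance in the
        direction of the fitted reversal coefficient (sign-consistency)."""
        rec, selection, abundance = fitted_sets
        base = rec.head(20).copy()
        high = base.copy()
        high["reversal"] = base["reversal"] + 0.3
        p0 = predict_daily(selection, abundance, base)
        p1 = predict_daily(selection, abundance, high)
        tt = abundance["individual"].averaged.term_table
        if "reversal" in tt.index:
            sign = np.sign(tt.loc["reversal", "avg_pe"])
            diff = p1["individual"].to_numpy() - p0["individual"].to_numpy()
            assert np.all(np.sign(diff[np.abs(diff) > 1e-12]) == sign)

    def test_extrapolation_flagged(self, fitted_sets):
        rec, selection, abundance = fitted_sets
        out = rec.head(3).copy()
        out["depth"] = 1e4
        preds = predict_daily(selection, abundance, out)
        assert preds["extrapolated"].all()

    def test_missing_fitted_set_rejected(self, fitted_sets):
        rec, selection, abundance = fitted_sets
        with pytest.raises(ValueError, match="missing fitted"):
            predict_daily({k: v for k, v in selection.items() if k != "dsd"},
                          abundance, rec)

    def test_flock_individual_predictions_correlated(self, small_records):
        """Predicted flock and individual indices move together across the
        synthetic season, mirroring the strong observed coupling."""
        rec = small_records["records"]
        rec = rec[rec["species"] == "egret"]
        selection = {r: fit_selection(rec, "egret", r) for r in ("depth", "recess", "dsd")}
        abundance = {resp: fit_abundance(rec, "egret", resp)
                     for resp in ("flock", "individual")}
        preds = predict_daily(selection, abundance, rec)
        ok = np.isfinite(preds["flock"]) & np.isfinite(preds["individual"])
        r = np.corrcoef(preds.loc[ok, "flock"], preds.loc[ok, "individual"])[0, 1]
        assert r > 0.7


class TestFlockIndividualR2:
    def test_proportional_series_is_one(self):
        rec = constructed_records(n_days=60, seed=6)
        rec["individual_count"] = 3 * rec["flock_count"]
        _, mean_r2 = flock_individual_r2(rec)
        assert mean_r2 == pytest.approx(1.0)

    def test_independent_noise_is_null(self):
        low = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rec = constructed_records(n_days=200, seed=seed)
            rec["flock_count"] = rng.integers(5, 50, len(rec))
            rec["individual_count"] = rng.integers(50, 500, len(rec))
            _, mean_r2 = flock_individual_r2(rec)
            low += mean_r2 < 0.05
        assert low >= 4

    def test_constant_series_flagged(self):
        rec = constructed_records(n_days=30, seed=7)
        rec["flock_count"] = 10
        per_year, _ = flock_individual_r2(rec)
        assert per_year.isna().all()
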