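"""Spatial foraging-conditions chain: cell records, the semiparametric
frequency model, surface prediction, and index combination."""

import numpy as np
import pandas as pd
import pytest

from wadem.covariates import compute_covariates
from wadem.grid_io import DepthGrid, RegionMap
from wadem.sfc import (
    build_cell_records,
    combine_indices,
    fit_sfc,
    predict_sfc_surface,
    sfc_transform,
    smoother_effect_surface,
)


def grid_with_regions(n=20, n_days=30, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2007-01-01", periods=n_days)
    depth = rng.uniform(5, 40, size=(n_days, n, n))
    grid = DepthGrid(dates=dates, depth=depth, valid=np.ones((n, n), bool))
    labels = np.full((n, n), "WCA", dtype=object)
    labels[n // 3 : 2 * n // 3] = "BCNP"
    labels[2 * n // 3 :] = "ENP"
    return grid, compute_covariates(grid), RegionMap(labels=labels)


class TestBuildCellRecords:
    def test_frequencies_count_distinct_dates(self):
        grid, cov, regions = grid_with_regions()
        survey = pd.DataFrame(
            {
                "date": pd.to_datetime(
                    ["2007-01-20", "2007-01-21", "2007-01-22", "2007-01-20"]
                ),
                "row": [2, 2, 2, 5],
                "col": [3, 3, 3, 5],
                "species": "egret",
                "count": [4, 1, 2, 9],
            }
        )
        recs = build_cell_records(survey, cov, regions, "egret")
        by_cell = recs.set_index(["row", "col"])["frequency"]
        assert by_cell.loc[(2, 3)] == 3
        assert by_cell.loc[(5, 5)] == 1

    def test_instance_average(self):
        grid, cov, regions = grid_with_regions(seed=1)
        dates = pd.to_datetime(["2007-01-20", "2007-01-21", "2007-01-22"])
        survey = pd.DataFrame(
            {"date": dates, "row": 4, "col": 7, "species": "ibis", "count": 1}
        )
        recs = build_cell_records(survey, cov, regions, "ibis")
        t = [grid.date_index(d) for d in dates]
        expect = np.mean([grid.depth[i, 4, 7] for i in t])
        assert recs.iloc[0]["depth"] == pytest.approx(expect)

    def test_groupby_oracle_and_conservation(self):
        grid, cov, regions = grid_with_regions(seed=2)
        rng = np.random.default_rng(3)
        k = 400
        survey = pd.DataFrame(
            {
                "date": grid.dates[rng.integers(15, 30, k)],
                "row": rng.integers(0, 20, k),
                "col": rng.integers(0, 20, k),
                "species": "egret",
                "count": rng.integers(1, 6, k),
            }
        )
        recs = build_cell_records(survey, cov, regions, "egret")
        occupied_pairs = survey.drop_duplicates(["date", "row", "col"])
        assert recs["frequency"].sum() == len(occupied_pairs)
        # oracle per cell via pandas group-by
        oracle = occupied_pairs.groupby(["row", "col"]).size()
        for (r, c), f in oracle.items():
            assert recs.set_index(["row", "col"]).loc[(r, c), "frequency"] == f

    def test_transform_rule(self):
        assert sfc_transform("stork") == "inv_square_root"
        assert sfc_transform("egret") == "fourth_root"


def synthetic_cells(n=22, seed=0, spatial=True, hp_effect=0.0, noise=0.1):
    """Cell records whose transformed frequency is driven by a smooth field
    and/or hydroperiod."""
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:n, 0:n]
    field = np.sin(rows / 4.0) + np.cos(cols / 5.0)
    hp = rng.uniform(100, 350, size=(n, n))
    eta = 1.6 + hp_effect * hp + (field if spatial else 0.0)
    eta = eta + noise * rng.standard_normal((n, n))
    freq = np.maximum(1, np.round(np.maximum(eta, 0.3) ** 4)).astype(int)
    recs = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "region": np.where(rows.ravel() < n // 2, "WCA", "ENP"),
            "frequency": freq.ravel(),
            "depth": rng.uniform(5, 30, n * n),
            "recess": rng.normal(0.3, 0.1, n * n),
            "dsd": rng.uniform(100, 700, n * n),
            "reversal": rng.uniform(0, 0.3, n * n),
            "hp": hp.ravel(),
            "x_m": ((cols.ravel() + 0.5) * 400.0),
            "y_m": ((n - rows.ravel() - 0.5) * 400.0),
        }
    )
    return recs, (n, n)


class TestFitSfc:
    def test_smoother_absorbs_spatial_trend(self):
        recs, shape = synthetic_cells(seed=4, spatial=True)
        model = fit_sfc(recs, "egret", models=[("hp",)], grid_shape=shape,
                        seed=0, moran_permutations=99)
        assert model.moran_without_smoother[0] > 0.3
        assert model.moran_with_smoother[0] < 0.05

    def test_null_smoother_variance_share(self):
        recs, shape = synthetic_cells(seed=5, spatial=False, hp_effect=0.004)
        model = fit_sfc(recs, "egret", models=[("hp",)], grid_shape=shape,
                        seed=0, moran_permutations=99)
        rm = model.averaged.retained[0]
        share = rm.fit.varcomp["smoother"] / rm.fit.varcomp["residual"]
        assert share < 0.01

    def test_hp_coefficient_recovered(self):
        recs, shape = synthetic_cells(seed=6, spatial=False, hp_effect=0.004, noise=0.05)
        model = fit_sfc(recs, "egret", models=[("hp",)], grid_shape=shape,
                        seed=0, moran_permutations=99)
        tt = model.averaged.term_table
        assert abs(tt.loc["hp", "avg_pe"] - 0.004) <= 2 * tt.loc["hp", "se"]
        assert tt.loc["hp", "avg_pe"] > 0

    def test_region_blups_sum_to_zero(self):
        recs, shape = synthetic_cells(seed=7, spatial=True)
        model = fit_sfc(recs, "egret", models=[("hp",)], grid_shape=shape,
                        seed=0, moran_permutations=99)
        rm = model.averaged.retained[0]
        assert abs(rm.fit.blups["region"].sum()) < 1e-6

    def test_too_few_cells_rejected(self):
        recs, shape = synthetic_cells()
        with pytest.raises(ValueError, match=">= 50"):
            fit_sfc(recs.head(20), "egret", grid_shape=shape)


@pytest.fixture(scope="module")
def fitted(small_scenario, small_records):
    grid = small_scenario["grid"]
    model_recs = build_cell_records(
        small_scenario["survey"], small_scenario["cov"], small_scenario["regions"],
        "egret", grid=grid, window=small_records["windows"]["egret"],
        cell_size_m=grid.cell_size_m,
    )
    return fit_sfc(model_recs, "egret", grid_shape=(grid.nrows, grid.ncols),
                   cell_size_m=grid.cell_size_m, seed=0, moran_permutations=99)


class TestPredictSurface:
    def test_single_date_equals_its_own_average(self, fitted, small_scenario):
        cov = small_scenario["cov"]
        regions = small_scenario["regions"]
        date = small_scenario["survey"]["date"].iloc[0]
        s1 = predict_sfc_surface(fitted, cov, regions, [date])
        s2 = predict_sfc_surface(fitted, cov, regions, [date, date])
        np.testing.assert_allclose(s1, s2, atol=1e-10, equal_nan=True)

    def test_hp_probe_is_model_consistent(self, fitted, small_scenario):
        """Raising hydroperiod uniformly moves the predicted frequency in
        the direction of the fitted coefficient."""
        import dataclasses

        cov = small_scenario["cov"]
        regions = small_scenario["regions"]
        tt = fitted.averaged.term_table
        hp_terms = [t for t in tt.index if t in ("hp", "hp^2")]
        if not hp_terms:
            pytest.skip("hydroperiod not retained in this fit")
        date = small_scenario["survey"]["date"].iloc[0]
        base = predict_sfc_surface(fitted, cov, regions, [date])
        cov_hi = dataclasses.replace(cov, hydroperiod=cov.hydroperiod + 20.0)
        high = predict_sfc_surface(fitted, cov_hi, regions, [date])
        # sign of the induced change in the linear predictor at the mean hp
        slope = 0.0
        if "hp" in tt.index:
            slope += tt.loc["hp", "avg_pe"]
        if "hp^2" in tt.index:
            slope += 2 * tt.loc["hp^2", "avg_pe"] * float(np.nanmean(cov.hydroperiod) + 10)
        diff = np.nanmean(high - base)
        assert np.sign(diff) == np.sign(slope)

    def test_smoother_surface_written(self, fitted, small_scenario, tmp_path):
        cov = small_scenario["cov"]
        regions = small_scenario["regions"]
        date = small_scenario["survey"]["date"].iloc[0]
        predict_sfc_surface(fitted, cov, regions, [date],
                            surface_path=tmp_path / "s.asc",
                            smoother_path=tmp_path / "sm.asc")
        from wadem.grid_io import read_surface

        sm = read_surface(tmp_path / "sm.asc")
        assert sm.shape == fitted.grid_shape
        np.testing.assert_allclose(sm[np.isfinite(sm)],
                                   smoother_effect_surface(fitted, cov)[np.isfinite(sm)])

    def test_unknown_date_rejected(self, fitted, small_scenario):
        with pytest.raises(KeyError):
            predict_sfc_surface(fitted, small_scenario["cov"],
                                small_scenario["regions"], ["1999-01-01"])


class TestCombineIndices:
    def make_inputs(self, n_days=5, surface_value=2.0, avail=True):
        dates = pd.date_range("2007-02-01", periods=n_days)
        preds = pd.DataFrame(
            {"date": dates, "species": "egret",
             "flock": np.linspace(1, 5, n_days),
             "individual": np.linspace(10, 50, n_days)}
        )
        surf = np.full((4, 4), surface_value)
        mask = np.ones((4, 4), bool) if avail else np.zeros((4, 4), bool)
        surfaces = {pd.Timestamp(d): surf for d in dates}
        masks = {pd.Timestamp(d): mask for d in dates}
        return preds, surfaces, masks

    def test_no_available_cells_zero(self):
        preds, surfaces, masks = self.make_inputs(avail=False)
        out = combine_indices(preds, surfaces, masks)
        assert (out["sfc_patch_abundance"] == 0).all()
        assert (out["combined_index"] == 0).all()

    def test_constant_surface_proportional_to_tfc(self):
        preds, surfaces, masks = self.make_inputs()
        out = combine_indices(preds, surfaces, masks)
        norm_tfc = out["tfc_individual"] / out["tfc_individual"].max()
        np.testing.assert_allclose(out["combined_index"], norm_tfc, atol=1e-12)

    def test_misaligned_dates_rejected(self):
        preds, surfaces, masks = self.make_inputs()
        del surfaces[pd.Timestamp("2007-02-03")]
        with pytest.raises(ValueError, match="2007-02-03"):
            combine_indices(preds, surfaces, masks)
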