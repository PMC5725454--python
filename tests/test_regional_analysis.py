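"""Regionalization, weighted means, export algorithms, and the MLR."""

import numpy as np
import pandas as pd
import pytest

from docpump import regional_analysis as ra
from docpump import synthetic_ocean as so


class TestDepthMeanNO3:
    def test_uniform_field_returns_constant(self, scenario):
        m = ra.depth_mean_no3(np.full(scenario.grid.n_box, 3.3), scenario.grid)
        np.testing.assert_allclose(m, 3.3)

    def test_hand_weighted_two_layer_case(self, scenario):
        grid = scenario.grid
        v = grid.to_column(np.zeros(grid.n_box))
        v[:, 1] = 1.0  # layer 2 only (38 m of the 74 m column)
        m = ra.depth_mean_no3(v.ravel(), grid)
        np.testing.assert_allclose(m, 38.0 / 74.0)

    def test_invariant_to_splitting_a_layer(self):
        coarse = so.build_grid(n_lat=4, n_lon=1, layer_bottoms=[36, 74, 200])
        fine = so.build_grid(n_lat=4, n_lon=1, layer_bottoms=[18, 36, 74, 200])
        rng = np.random.default_rng(0)
        per_layer = rng.uniform(1, 5, 3)
        v_coarse = np.tile(per_layer, coarse.n_col)
        v_fine = np.tile(per_layer[[0, 0, 1, 2]], fine.n_col)
        np.testing.assert_allclose(
            ra.depth_mean_no3(v_coarse, coarse), ra.depth_mean_no3(v_fine, fine)
        )

    def test_non_tiling_bounds_rejected(self, scenario):
        with pytest.raises(so.ConfigurationError):
            ra.depth_mean_no3(scenario.no3, scenario.grid, z_bottom=100.0)


class TestRegionalize:
    @pytest.fixture()
    def grid(self):
        return so.build_grid(n_lat=12, n_lon=3, lat_extent=80.0)

    def _labels(self, grid, values_by_condition):
        no3 = np.array(values_by_condition, dtype=float)
        return ra.regionalize(no3, grid)

    def test_oligotrophic_pacific_column_is_stp(self, grid):
        no3 = np.full(grid.n_col, 5.0)
        subtropical_pacific = (grid.col_lat > 20) & (grid.col_lat < 40) & (
            grid.col_basin == "Pacific")
        no3[subtropical_pacific] = 0.3
        rs = ra.regionalize(no3, grid)
        assert set(rs.labels[subtropical_pacific]) == {"STP"}

    def test_southern_thresholds(self, grid):
        no3 = np.full(grid.n_col, 5.0)
        south = grid.col_lat < -44
        no3[south] = 25.0
        rs = ra.regionalize(no3, grid)
        assert set(rs.labels[south]) == {"AAZ"}
        no3[south] = 15.0
        rs = ra.regionalize(no3, grid)
        assert set(rs.labels[south]) == {"SAZ"}

    def test_boundary_values_go_to_high_nutrient_side(self, grid):
        no3 = np.full(grid.n_col, 0.5)  # exactly at the gyre marker
        rs = ra.regionalize(no3, grid)
        assert not any(label.startswith("ST") for label in rs.labels)
        south = grid.col_lat < -44
        no3_s = np.full(grid.n_col, 5.0)
        no3_s[south] = 20.0  # exactly at the SAZ/AAZ split
        rs = ra.regionalize(no3_s, grid)
        assert set(rs.labels[south]) == {"AAZ"}

    def test_labels_partition_all_columns(self, scenario):
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        rs = ra.regionalize(m, scenario.grid)
        assert set(rs.labels) <= set(ra.REGION_NAMES)
        assert len(rs.labels) == scenario.grid.n_col

    def test_reference_world_has_all_ten_regions(self, scenario):
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        rs = ra.regionalize(m, scenario.grid)
        assert set(rs.labels) == set(ra.REGION_NAMES)

    def test_rerun_is_bit_identical(self, scenario):
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        a = ra.regionalize(m, scenario.grid)
        b = ra.regionalize(m, scenario.grid)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_unlabeled_column_rejected(self, grid):
        basins = grid.col_basin.astype(str)
        basins[0] = ""
        with pytest.raises(so.ConfigurationError, match="basin"):
            ra.regionalize(np.full(grid.n_col, 5.0), grid, basin_map=basins)


class TestMeans:
    def test_uniform_field_mean_independent_of_weights(self, scenario):
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        rs = ra.regionalize(m, scenario.grid)
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 5.0, scenario.grid.n_col)
        out = ra.regional_means({"f": np.full(scenario.grid.n_col, 2.5)}, w, rs)
        np.testing.assert_allclose(out["f"], 2.5)

    def test_export_weighted_hand_case(self):
        grid = so.build_grid(n_lat=4, n_lon=1)
        labels = np.array(["TP", "TP", "TA", "TA"])
        rs = ra.RegionSet(labels=labels, thresholds={}, basin_map=labels,
                          no3_mean=np.ones(4))
        out = ra.regional_means({"v": np.array([0.0, 4.0, 1.0, 1.0])},
                                np.array([1.0, 3.0, 1.0, 1.0]), rs)
        assert out.loc["TP", "v"] == pytest.approx(3.0)

    def test_area_weighting_with_equal_areas_is_arithmetic(self):
        grid = so.build_grid(n_lat=4, n_lon=1)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        z = ra.zonal_means({"v": v}, grid, weights=np.ones(4))
        np.testing.assert_allclose(z["v"].to_numpy(), v)

    def test_zonal_means_average_over_longitude(self, scenario):
        z = ra.zonal_means({"npp": scenario.ancillary.npp}, scenario.grid)
        assert len(z) == scenario.grid.n_lat
        ilat0 = scenario.grid.col_lat == scenario.grid.lat[0]
        np.testing.assert_allclose(
            z["npp"].iloc[0],
            np.average(scenario.ancillary.npp[ilat0],
                       weights=scenario.grid.box_area[ilat0]),
        )

    def test_all_zero_weights_in_region_rejected(self):
        grid = so.build_grid(n_lat=4, n_lon=1)
        labels = np.array(["TP", "TP", "TA", "TA"])
        rs = ra.RegionSet(labels=labels, thresholds={}, basin_map=labels,
                          no3_mean=np.ones(4))
        with pytest.raises(so.ConfigurationError):
            ra.regional_means({"v": np.ones(4)}, np.array([0.0, 0.0, 1.0, 1.0]), rs)


class TestSatelliteCExport:
    def test_single_algorithm_mean_is_that_map(self, scenario):
        anc = scenario.ancillary
        alg = so.default_export_algorithms(1)
        mean, stack = ra.satellite_cexport(anc.npp, anc.sst, alg)
        np.testing.assert_array_equal(mean, stack[0])

    def test_constant_ratio_scales_npp(self, scenario):
        anc = scenario.ancillary
        mean, _ = ra.satellite_cexport(anc.npp, anc.sst,
                                       [lambda npp, sst: 0.2 * npp])
        np.testing.assert_allclose(mean, 0.2 * anc.npp)

    def test_nine_variant_hand_average_on_three_columns(self):
        npp = np.array([100.0, 200.0, 50.0])
        sst = np.array([25.0, 5.0, 15.0])
        algs = so.default_export_algorithms(9)
        mean, stack = ra.satellite_cexport(npp, sst, algs)
        assert stack.shape == (9, 3)
        np.testing.assert_allclose(mean, np.mean([a(npp, sst) for a in algs], axis=0))

    def test_no_algorithm_rejected(self, scenario):
        with pytest.raises(so.ConfigurationError):
            ra.satellite_cexport(scenario.ancillary.npp, scenario.ancillary.sst, [])


class TestEfficiencyRatios:
    def _toy_regions(self):
        # symmetric latitude bands share areas: TP = bands 0 and 3, TA = 1 and 2
        grid = so.build_grid(n_lat=4, n_lon=1)
        labels = np.array(["TP", "TA", "TA", "TP"])
        return grid, ra.RegionSet(labels=labels, thresholds={}, basin_map=labels,
                                  no3_mean=np.ones(4))

    def test_identical_fields_give_unit_ratio(self, scenario):
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        rs = ra.regionalize(m, scenario.grid)
        v = scenario.ancillary.c_export
        out = ra.efficiency_ratios({"ndx": v, "cexport": v}, rs, scenario.grid,
                                   pairs=[("ndx", "cexport")])
        np.testing.assert_allclose(out["ndx:cexport"], 1.0)

    def test_two_box_hand_ratio(self):
        grid, rs = self._toy_regions()
        ndp = np.array([2.0, 0.0, 0.0, 4.0])
        cexp = np.array([10.0, 1.0, 1.0, 10.0])
        out = ra.efficiency_ratios({"ndp": ndp, "cexport": cexp}, rs, grid,
                                   pairs=[("ndp", "cexport")])
        # equal areas within the TP region: (2+4)/(10+10) = 0.3
        assert out.loc["TP", "ndp:cexport"] == pytest.approx(0.3)

    def test_zero_denominator_is_nan_not_inf(self):
        grid, rs = self._toy_regions()
        out = ra.efficiency_ratios({"ndp": np.ones(4), "cexport": np.zeros(4)},
                                   rs, grid, pairs=[("ndp", "cexport")])
        assert out["ndp:cexport"].isna().all()

    def test_subtropical_export_efficiency_exceeds_tropical(self, scenario):
        from docpump import surface_diagnostics as sd
        from docpump import export_flux as ef
        part = sd.partition_matrix(scenario.transport, "74m")
        sol = sd.solve_restoring(part, scenario.doc, scenario.doc, 0.5, "doc")
        export = ef.solve_export(scenario.transport, sol.j_full, 74.0)
        m = ra.depth_mean_no3(scenario.no3, scenario.grid)
        rs = ra.regionalize(m, scenario.grid)
        out = ra.efficiency_ratios({"ndx": export.areal,
                                    "cexport": scenario.ancillary.c_export},
                                   rs, scenario.grid, pairs=[("ndx", "cexport")])
        st = out.loc[["STP", "STA", "STI"], "ndx:cexport"].mean()
        tp = out.loc[["TP", "TA", "TI"], "ndx:cexport"].mean()
        assert st > tp


class TestMLR:
    def _regions_frame(self, rng, n=10):
        return pd.DataFrame({
            "f_pico": rng.uniform(0.1, 0.8, n),
            "log10_no3": rng.uniform(-2.0, 1.4, n),
        })

    def test_noiseless_recovery_to_six_digits(self):
        rng = np.random.default_rng(42)
        X = self._regions_frame(rng)
        y = 0.7 * X["f_pico"] - 0.1 * X["log10_no3"]
        fit = ra.fit_mlr(y, X)
        np.testing.assert_allclose(fit.params["f_pico"], 0.7, rtol=1e-6)
        np.testing.assert_allclose(fit.params["log10_no3"], -0.1, rtol=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_has_no_skill(self):
        rng = np.random.default_rng(1)
        X = self._regions_frame(rng, n=400)
        y = rng.standard_normal(400)
        fit = ra.fit_mlr(y, X)
        assert fit.r2 < 0.05

    def test_standardized_ratio_sign(self):
        rng = np.random.default_rng(3)
        X = self._regions_frame(rng)
        y = 0.7 * X["f_pico"] - 0.1 * X["log10_no3"]
        fit = ra.fit_mlr(y, X)
        assert fit.standardized_ratio < 0  # opposite-signed raw coefficients

    def test_standardized_coefficients_definition(self):
        rng = np.random.default_rng(4)
        X = self._regions_frame(rng)
        y = 0.7 * X["f_pico"] - 0.1 * X["log10_no3"] + 0.02 * rng.standard_normal(10)
        fit = ra.fit_mlr(y, X)
        for c in X.columns:
            expected = fit.params[c] * X[c].std(ddof=1) / y.std(ddof=1)
            assert fit.standardized[c] == pytest.approx(expected)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 10)
        X = pd.DataFrame({"a": x, "b": 2.0 * x})
        with pytest.raises(so.ConfigurationError, match="collinear"):
            ra.fit_mlr(x, X)

    def test_intercept_option(self):
        rng = np.random.default_rng(6)
        X = self._regions_frame(rng)
        y = 0.5 + 0.7 * X["f_pico"] - 0.1 * X["log10_no3"]
        fit = ra.fit_mlr(y, X, include_intercept=True)
        np.testing.assert_allclose(fit.params["f_pico"], 0.7, rtol=1e-6)

    def test_too_few_regions_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.4]})
        with pytest.raises(so.ConfigurationError):
            ra.fit_mlr(np.array([1.0, 2.0]), X)

    def test_prediction_ci_contains_fit(self):
        rng = np.random.default_rng(7)
        X = self._regions_frame(rng)
        y = 0.7 * X["f_pico"] - 0.1 * X["log10_no3"] + 0.05 * rng.standard_normal(10)
        fit = ra.fit_mlr(y, X)
        assert (fit.prediction["ci_low"] <= fit.prediction["fitted"]).all()
        assert (fit.prediction["fitted"] <= fit.prediction["ci_high"]).all()
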