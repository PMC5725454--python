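"""Gap-filling ensemble: predictor assembly, training, prediction, statistics."""

import numpy as np
import pandas as pd
import pytest

from docpump import ann_mapping as am
from docpump import synthetic_ocean as so


@pytest.fixture(scope="module")
def small_world():
    """A compact world with a linear-in-predictors target for fast training."""
    grid = so.build_grid(n_lat=24, n_lon=1, layer_bottoms=[36, 74, 200, 800, 3000])
    fields = {
        "x1": np.linspace(0.0, 1.0, grid.n_box),
        "x2": np.cos(np.linspace(0, 3, grid.n_box)),
        "depth": grid.box_depth,
    }
    predictors = am.assemble_predictors(grid, fields)
    target = 10.0 + 4.0 * fields["x1"]  # exactly representable
    return grid, predictors, target


def _obs(grid, values, **kw):
    kw.setdefault("fraction", 1.0)
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("seed", 0)
    return so.sample_observations(values, grid, **kw)


class TestAssemblePredictors:
    def test_row_count_equals_wet_boxes(self, scenario):
        table = am.assemble_predictors(scenario.grid, scenario.predictor_fields())
        assert len(table) == scenario.grid.n_box

    def test_constant_field_gives_constant_column(self, scenario):
        table = am.assemble_predictors(scenario.grid, {"c": np.full(scenario.grid.n_box, 7.0)})
        assert (table["c"] == 7.0).all()

    def test_depth_predictor_matches_layer_centers(self, scenario):
        table = am.assemble_predictors(scenario.grid, scenario.predictor_fields())
        grid = scenario.grid
        layer2 = grid.box_layer == 1
        assert (table["depth"].to_numpy()[layer2] == grid.z_center[1]).all()

    def test_column_fields_broadcast_down_the_water_column(self, scenario):
        grid = scenario.grid
        table = am.assemble_predictors(grid, {"sst": scenario.ancillary.sst})
        np.testing.assert_array_equal(table["sst"].to_numpy(),
                                      scenario.ancillary.sst[grid.box_col])

    def test_nan_predictor_rejected_with_box_listing(self, scenario):
        bad = scenario.doc.copy()
        bad[[3, 17]] = np.nan
        with pytest.raises(so.ConfigurationError, match=r"\[3, 17\]"):
            am.assemble_predictors(scenario.grid, {"doc": bad})

    def test_missing_predictor_rejected(self, scenario):
        with pytest.raises(so.ConfigurationError, match="missing"):
            am.assemble_predictors(scenario.grid, {}, predictor_names=("chlorophyll",))


class TestTrainMember:
    def test_linear_target_fits_to_high_r2(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        m = am.train_member(obs, predictors, am.ANNConfig(), member_seed=1)
        assert m.validation_r2 >= 0.999

    def test_members_differ_in_weights_but_agree_on_linear_target(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        m1 = am.train_member(obs, predictors, am.ANNConfig(), member_seed=1)
        m2 = am.train_member(obs, predictors, am.ANNConfig(), member_seed=2)
        assert not np.allclose(m1.model.coefs_[0], m2.model.coefs_[0])
        assert m1.validation_r2 >= 0.999 and m2.validation_r2 >= 0.999

    def test_constant_target_predicted_flat(self, small_world):
        grid, predictors, _ = small_world
        obs = _obs(grid, np.full(grid.n_box, 55.0))
        m = am.train_member(obs, predictors, am.ANNConfig(), member_seed=0)
        pred = m.predict(predictors.to_numpy())
        assert np.sqrt(np.mean((pred - 55.0) ** 2)) <= 0.1

    def test_member_reproducible_under_seed(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        m1 = am.train_member(obs, predictors, am.ANNConfig(), member_seed=9)
        m2 = am.train_member(obs, predictors, am.ANNConfig(), member_seed=9)
        np.testing.assert_array_equal(m1.train_rows, m2.train_rows)
        np.testing.assert_array_equal(m1.model.coefs_[0], m2.model.coefs_[0])

    def test_too_few_observations_rejected(self, small_world):
        grid, predictors, target = small_world
        obs = so.ObservationSet(
            box_index=np.arange(10), values=target[:10],
            fraction=1.0, noise_sd=0.0, withheld_basins=(), seed=0,
        )
        with pytest.raises(so.ConfigurationError, match="50"):
            am.train_member(obs, predictors, am.ANNConfig(), member_seed=0)


class TestEnsemble:
    def test_single_member_ensemble_equals_member(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        ens = am.train_ensemble(obs, predictors, am.ANNConfig(n_members=1, seed=3))
        field = am.predict_field(ens, predictors)
        member_pred = ens.members[0].predict(predictors.to_numpy())
        np.testing.assert_array_equal(field.values, member_pred)
        assert np.all(field.spread == 0.0)

    def test_prediction_invariant_to_member_order(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        ens = am.train_ensemble(obs, predictors, am.ANNConfig(n_members=3, seed=3))
        reversed_ens = am.ANNEnsemble(
            members=ens.members[::-1], config=ens.config,
            predictor_names=ens.predictor_names,
            train_min=ens.train_min, train_max=ens.train_max,
        )
        a = am.predict_field(ens, predictors).values
        b = am.predict_field(reversed_ens, predictors).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_extrapolation_mask_is_axis_aligned_range(self, small_world):
        grid, predictors, target = small_world
        half = predictors.iloc[: grid.n_box // 2]
        obs = so.ObservationSet(
            box_index=np.arange(len(half)), values=target[: len(half)],
            fraction=1.0, noise_sd=0.0, withheld_basins=(), seed=0,
        )
        ens = am.train_ensemble(obs, predictors, am.ANNConfig(n_members=1, seed=0))
        field = am.predict_field(ens, predictors)
        X = predictors.to_numpy()
        expected = np.any((X < ens.train_min) | (X > ens.train_max), axis=1)
        np.testing.assert_array_equal(field.extrapolation_mask, expected)

    def test_serialization_round_trip(self, small_world):
        grid, predictors, target = small_world
        obs = _obs(grid, target)
        ens = am.train_ensemble(obs, predictors, am.ANNConfig(n_members=2, seed=5))
        restored = am.ensemble_from_dict(am.ensemble_to_dict(ens))
        a = am.predict_field(ens, predictors).values
        b = am.predict_field(restored, predictors).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_retention_threshold_can_drop_members(self, small_world):
        grid, predictors, target = small_world
        noisy = target + np.random.default_rng(0).normal(0, 3.0, len(target))
        obs = _obs(grid, noisy)
        with pytest.raises(am.EnsembleError):
            am.train_ensemble(obs, predictors,
                              am.ANNConfig(n_members=2, seed=1, min_validation_r2=0.99999))


class TestFitStats:
    def test_perfect_prediction(self):
        s = am.holdout_stats(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert s.slope == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0)

    def test_constant_offset(self):
        s = am.holdout_stats(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert s.slope == pytest.approx(1.0)
        assert s.rmse == pytest.approx(1.0)

    def test_three_point_hand_case(self):
        # obs (1,2,3), pred (1,2,4): hand OLS of pred on obs gives slope 1.5;
        # R^2 = 1 - 1/2; RMSE = sqrt(1/3)
        s = am.holdout_stats(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert s.slope == pytest.approx(1.5)
        assert s.r2 == pytest.approx(0.5)
        assert s.rmse == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_zero_observed_variance_rejected(self):
        with pytest.raises(so.ConfigurationError):
            am.holdout_stats(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(so.ConfigurationError):
            am.holdout_stats(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestBasinExclusion:
    def test_empty_basin_rejected(self, scenario):
        obs = so.sample_observations(scenario.doc, scenario.grid, fraction=0.2,
                                     withheld_basins=["Indian"], seed=0)
        predictors = am.assemble_predictors(scenario.grid, scenario.predictor_fields())
        with pytest.raises(so.ConfigurationError, match="Indian"):
            am.basin_exclusion_validation(obs, predictors, scenario.grid,
                                          am.ANNConfig(n_members=1), "Indian")

    def test_training_excludes_the_held_basin(self, scenario, monkeypatch):
        obs = so.sample_observations(scenario.doc, scenario.grid, fraction=0.3, seed=0)
        predictors = am.assemble_predictors(scenario.grid, scenario.predictor_fields())
        captured = {}
        real_train = am.train_ensemble

        def spy(train_obs, preds, cfg):
            captured["basins"] = set(scenario.grid.box_basin[train_obs.box_index])
            captured["n"] = len(train_obs)
            return real_train(train_obs, preds, cfg)

        monkeypatch.setattr(am, "train_ensemble", spy)
        am.basin_exclusion_validation(obs, predictors, scenario.grid,
                                      am.ANNConfig(n_members=1, seed=2), "Pacific")
        held = (scenario.grid.box_basin[obs.box_index] == "Pacific").sum()
        assert "Pacific" not in captured["basins"]
        assert captured["n"] == len(obs) - held
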