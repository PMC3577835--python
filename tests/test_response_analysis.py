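"""Ensembles, response fields, fusion index, and sigmoid calibration."""

import numpy as np
import pytest

from phonotaxnet import network as nw
from phonotaxnet.preprocessing import classify_scores, stratified_split
from phonotaxnet.response_analysis import (
    CalibrationParams,
    FusionRegions,
    apply_calibration,
    build_ensemble,
    evaluate,
    fit_calibration,
    fusion_index_from_surface,
    member_predictions,
    predict,
    response_field,
)
from phonotaxnet.selection import ModelSpec
from phonotaxnet.song_features import FeatureSet, complete_pattern
from phonotaxnet.synthetic_data import BehavioralDataset

FOUR = FeatureSet(("pulse_duration", "pulse_pause", "chirp_duration", "chirp_period"))
FAST = nw.RPropConfig(cycles=300)


@pytest.fixture(scope="module")
def small_ensemble(default_dataset):
    return build_ensemble(default_dataset, ModelSpec(FOUR, 3), n_members=5,
                          rprop=FAST, rng=1)


class TestEnsemble:
    def test_single_member_equals_forward(self, default_dataset):
        ens = build_ensemble(default_dataset, ModelSpec(FOUR, 2), n_members=1,
                             rprop=FAST, rng=0)
        pats = default_dataset.patterns()[:5]
        mean, sd = predict(ens, pats)
        raw = member_predictions(ens, pats)[0]
        np.testing.assert_allclose(mean, raw, atol=1e-12)
        np.testing.assert_array_equal(sd, np.zeros(5))

    def test_same_master_seed_identical(self, default_dataset):
        a = build_ensemble(default_dataset, ModelSpec(FOUR, 2), n_members=3,
                           rprop=FAST, rng=11)
        b = build_ensemble(default_dataset, ModelSpec(FOUR, 2), n_members=3,
                           rprop=FAST, rng=11)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.flatten(), mb.flatten())

    def test_mean_matches_independent_average(self, small_ensemble, default_dataset):
        pats = default_dataset.patterns()[:7]
        mean, _ = predict(small_ensemble, pats)
        manual = member_predictions(small_ensemble, pats).mean(axis=0)
        np.testing.assert_allclose(mean, manual, atol=1e-12)

    def test_initialization_variability_gives_positive_sd(self, small_ensemble, default_dataset):
        _, sd = predict(small_ensemble, default_dataset.patterns()[:10])
        assert (sd > 0).all()

    def test_recovers_optimum_ordering(self, small_ensemble):
        good = complete_pattern(pulse_period=40, pulse_duty_cycle=0.5,
                                chirp_period=340, chirp_duty_cycle=0.5)
        bad = complete_pattern(pulse_period=150, pulse_duty_cycle=0.5,
                               chirp_period=2000, chirp_duty_cycle=0.5)
        mean, _ = predict(small_ensemble, [good, bad])
        assert mean[0] > mean[1]


class TestEvaluate:
    def test_end_to_end_test_correlation(self, default_dataset):
        """Reduced-budget pipeline still correlates strongly on held-out songs."""
        labels = classify_scores(default_dataset.scores)
        split = stratified_split(labels, 18, np.random.default_rng(2))
        train = default_dataset.subset(split.train_indices)
        test = default_dataset.subset(split.test_indices)
        report = evaluate(train, test, ModelSpec(FOUR, 4), n_members=10,
                          rprop=nw.RPropConfig(cycles=1500), rng=3)
        assert report.pearson_r > 0.8
        assert report.mse_test < 0.1
        assert report.pred_mean.shape == (18,)

    def test_shuffled_targets_destroy_correlation(self, default_dataset):
        """Negative control: shuffling test scores leaves nothing to predict."""
        labels = classify_scores(default_dataset.scores)
        split = stratified_split(labels, 18, np.random.default_rng(2))
        train = default_dataset.subset(split.train_indices)
        test_frame = default_dataset.subset(split.test_indices).frame.copy()
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            shuffled = test_frame.copy()
            shuffled["mean_score"] = rng.permutation(shuffled["mean_score"].to_numpy())
            report = evaluate(train, BehavioralDataset(shuffled), ModelSpec(FOUR, 2),
                              n_members=3, rprop=FAST, rng=seed)
            hits += abs(report.pearson_r) < 0.5
        assert hits >= 4


class TestResponseField:
    def test_1x1_grid_equals_predict(self, small_ensemble):
        fld = response_field(
            small_ensemble, ("pulse_duration", "pulse_pause"),
            (np.array([20.0]), np.array([20.0])),
            {"chirp_duration": 200.0, "chirp_period": 333.0},
        )
        p = complete_pattern(pulse_duration=20, pulse_pause=20,
                             chirp_duration=200, chirp_period=333)
        mean, sd = predict(small_ensemble, [p])
        assert fld.mean_scores[0, 0] == pytest.approx(mean[0])
        assert fld.sd_scores[0, 0] == pytest.approx(sd[0])

    def test_pulse_field_spec_shape(self, small_ensemble):
        fld = response_field(
            small_ensemble, ("pulse_duration", "pulse_pause"),
            (np.arange(5.0, 41.0, 5.0), np.arange(5.0, 41.0, 5.0)),
            {"chirp_duration": 200.0, "chirp_period": 333.0},
        )
        assert fld.mean_scores.shape == (8, 8)
        assert np.isfinite(fld.mean_scores).all()

    def test_invalid_grid_points_masked(self, small_ensemble):
        # duration exceeding the fixed period implies a negative pause
        fld = response_field(
            small_ensemble, ("chirp_duration", "pulse_duration"),
            (np.array([200.0, 400.0]), np.array([20.0])),
            {"chirp_period": 333.0, "pulse_pause": 20.0},
        )
        assert np.isfinite(fld.mean_scores[0, 0])
        assert np.isnan(fld.mean_scores[1, 0])

    def test_overdetermined_completion_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            response_field(
                small_ensemble, ("pulse_duration", "pulse_pause"),
                (np.array([20.0]), np.array([20.0])),
                {"pulse_period": 40.0, "chirp_duration": 200.0, "chirp_period": 333.0},
            )

    def test_duty_cycle_free_feature_set_gives_period_diagonals(self, default_dataset):
        """Models without duty-cycle information are constant along equal periods."""
        ens = build_ensemble(default_dataset,
                             ModelSpec(FeatureSet(("pulse_period", "chirp_pause")), 2),
                             n_members=3, rprop=nw.RPropConfig(cycles=800), rng=5)
        fld = response_field(
            ens, ("pulse_duration", "pulse_pause"),
            (np.arange(10.0, 31.0, 5.0), np.arange(10.0, 31.0, 5.0)),
            {"chirp_duration": 200.0, "chirp_pause": 133.0},
        )
        # points sharing pulse_duration + pulse_pause share the prediction
        g = fld.axis_grids[0]
        for i in range(len(g)):
            for j in range(len(g)):
                for i2 in range(len(g)):
                    j2 = i + j - i2
                    if 0 <= j2 < len(g):
                        assert fld.mean_scores[i, j] == pytest.approx(
                            fld.mean_scores[i2, j2], abs=1e-10
                        )


class TestFusionIndex:
    @staticmethod
    def surrogate(op):
        P = np.arange(10.0, 90.0, 2.5)
        C = np.arange(50.0, 910.0, 10.0)
        fp = ((P >= 35) & (P <= 45)).astype(float)
        fc = ((C >= 250) & (C <= 500)).astype(float)
        return P, C, op(fp[:, None], fc[None, :])

    def test_min_surface_is_and(self):
        P, C, S = self.surrogate(np.minimum)
        assert fusion_index_from_surface(P, C, S).value == pytest.approx(1.0)

    def test_max_surface_is_or(self):
        P, C, S = self.surrogate(np.maximum)
        assert fusion_index_from_surface(P, C, S).value == pytest.approx(0.0)

    def test_empty_region_rejected(self):
        P = np.array([40.0])
        C = np.array([300.0])
        with pytest.raises(ValueError, match="region"):
            fusion_index_from_surface(P, C, np.ones((1, 1)))

    def test_flat_surface_rejected(self):
        P, C, _ = self.surrogate(np.minimum)
        with pytest.raises(ValueError, match="degenerate"):
            fusion_index_from_surface(P, C, np.ones((len(P), len(C))))

    def test_regions_configurable(self):
        P, C, S = self.surrogate(np.minimum)
        regions = FusionRegions(unattractive_chirp_above=600.0)
        assert fusion_index_from_surface(P, C, S, regions).value == pytest.approx(1.0)


class TestCalibration:
    def test_midpoint_maps_to_zero_and_asymptotes(self):
        c = CalibrationParams(slope=3.0, midpoint=0.2)
        assert apply_calibration(c, np.array([0.2]))[0] == pytest.approx(0.0)
        assert apply_calibration(c, np.array([1e9]))[0] == pytest.approx(1.0)
        assert apply_calibration(c, np.array([-1e9]))[0] == pytest.approx(-1.0)

    def test_strictly_increasing(self, rng):
        c = CalibrationParams(slope=2.5, midpoint=-0.1)
        y = np.sort(rng.uniform(-2, 2, size=50))
        g = apply_calibration(c, y)
        assert (np.diff(g) > 0).all()

    def test_self_generated_parameters_recovered_within_1_percent(self, rng):
        pred = rng.uniform(-0.8, 1.2, size=120)
        obs = apply_calibration(CalibrationParams(3.0, 0.2), pred)
        fit = fit_calibration(pred, obs)
        assert fit.slope == pytest.approx(3.0, rel=0.01)
        assert fit.midpoint == pytest.approx(0.2, rel=0.01)
        assert not fit.identity_fallback

    def test_calibration_never_hurts_training_mse(self, rng):
        """Either the fitted sigmoid improves the fit or the fallback is flagged."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            pred = r.uniform(-1, 1, size=60)
            obs = np.clip(1.4 * pred + r.normal(0, 0.1, size=60), -1, 1)
            fit = fit_calibration(pred, obs)
            raw = float(np.mean((pred - obs) ** 2))
            cal = float(np.mean((apply_calibration(fit, pred) - obs) ** 2))
            assert cal <= raw + 1e-9 or fit.identity_fallback

    def test_compressive_observations_improved(self, rng):
        """A sigmoidal observation map is in the family, so calibration must win."""
        pred = rng.uniform(-1.5, 1.5, size=100)
        obs = apply_calibration(CalibrationParams(4.0, 0.0), pred)
        fit = fit_calibration(pred, obs)
        raw = float(np.mean((pred - obs) ** 2))
        cal = float(np.mean((apply_calibration(fit, pred) - obs) ** 2))
        assert cal < raw

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            fit_calibration(np.ones(10), np.linspace(-1, 1, 10))
        with pytest.raises(ValueError):
            CalibrationParams(slope=-1.0, midpoint=0.0)
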