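from datetime import date

import numpy as np
import pandas as pd
import pytest

from pengdisp.env import EnvLayer, standardize
from pengdisp.grid import make_grid
from pengdisp.synth import (
    EnvFieldSpec,
    SimConfig,
    TrueHabitatModel,
    apply_argos_observation,
    build_env_stack,
    generate_env_layers,
    sample_presence_cells,
    simulate_track,
)
from pengdisp.tracks import great_circle_km


def lag1_autocorr(field: np.ndarray) -> float:
    a = field[:, :-1].ravel()
    b = field[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestEnvGenerator:
    def test_values_respect_configured_range(self, small_grid):
        spec = EnvFieldSpec("BAT", (0.0, 7958.0), smoothness=4.0,
                            months=("static",))
        (layer,) = generate_env_layers(spec, small_grid, seed=1)
        assert layer.values.min() >= 0.0
        assert layer.values.max() <= 7958.0

    def test_zero_smoothness_is_white_noise(self):
        g = make_grid((0, 50, 0, 50), 0.5)  # 10^4 cells
        spec = EnvFieldSpec("SST", (0.0, 1.0), smoothness=0.0,
                            months=("static",))
        (layer,) = generate_env_layers(spec, g, seed=2)
        assert abs(lag1_autocorr(layer.values)) < 0.05

    def test_autocorrelation_increases_with_smoothness(self):
        g = make_grid((0, 50, 0, 50), 0.5)
        rs = []
        for sm in (0.0, 2.0, 6.0):
            spec = EnvFieldSpec("SST", (0.0, 1.0), smoothness=sm,
                                months=("static",))
            (layer,) = generate_env_layers(spec, g, seed=3)
            rs.append(lag1_autocorr(layer.values))
        assert rs[0] < rs[1] < rs[2]

    def test_bit_identical_under_repeated_seed(self, small_grid):
        spec = EnvFieldSpec("CHLa", (0.0, 24.91), smoothness=3.0)
        a = generate_env_layers(spec, small_grid, seed=4)
        b = generate_env_layers(spec, small_grid, seed=4)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.values, lb.values)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            EnvFieldSpec("BAT", (10.0, 0.0))

    def test_full_stack_has_eight_covariates(self, small_grid):
        stack = build_env_stack(small_grid, seed=5)
        assert stack.variable_names == [
            "BAT", "BAT.G3", "CHLA", "CHLA.G3", "SSH", "SSH.G3", "SST",
            "SST.G3",
        ]
        for name in ("BAT.G3", "CHLA.G3", "SSH.G3", "SST.G3"):
            vals = stack[name].values
            assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 100


def _uniform_suitability(grid, value=0.5):
    return EnvLayer("suitability", np.full(grid.shape, value))


class TestTrackSimulator:
    def test_unbiased_uncorrelated_mean_step_length(self, coarse_study_grid):
        config = SimConfig(habitat_bias=0.0, turn_concentration=0.0, seed=6)
        track = simulate_track(config, _uniform_suitability(coarse_study_grid),
                               coarse_study_grid, colony_index=0,
                               n_days=10_000, seed=6)
        lon = track["lon"].to_numpy()
        lat = track["lat"].to_numpy()
        steps = great_circle_km((lon[:-1], lat[:-1]), (lon[1:], lat[1:]))
        assert steps.mean() == pytest.approx(config.step_km_mean, rel=0.05)

    def test_strong_bias_confines_walk_to_plateau(self, coarse_study_grid):
        g = coarse_study_grid
        suit = np.zeros(g.shape)
        suit[:, : g.n_cols // 2] = 1.0  # high plateau on the western half
        config = SimConfig(habitat_bias=20.0, turn_concentration=0.0, seed=7)
        # colony 0 (FI) sits in the eastern low region; walk should find
        # and stay on the plateau
        track = simulate_track(config, EnvLayer("suitability", suit), g,
                               colony_index=0, n_days=400, seed=7)
        after = track.iloc[100:]
        r, c = g.point_to_cell(after["lon"].to_numpy(), after["lat"].to_numpy())
        on_plateau = suit[r, c] == 1.0
        assert on_plateau.mean() >= 0.8

    def test_single_day_track(self, coarse_study_grid):
        config = SimConfig(seed=8)
        track = simulate_track(config, _uniform_suitability(coarse_study_grid),
                               coarse_study_grid, colony_index=0, n_days=1,
                               seed=8)
        assert len(track) == 1
        name, lon0, lat0, dep, _ = config.colonies[0]
        d = great_circle_km((track.loc[0, "lon"], track.loc[0, "lat"]),
                            (lon0, lat0))
        assert 0 < d < config.step_km_mean * 10
        assert track.loc[0, "date"] == date(2007, 12, 12)

    def test_colony_outside_grid_rejected(self, small_grid):
        config = SimConfig(seed=9)
        with pytest.raises(ValueError, match="outside"):
            simulate_track(config, _uniform_suitability(small_grid),
                           small_grid, colony_index=0, n_days=5, seed=9)

    def test_undefined_suitability_everywhere_rejected(self, coarse_study_grid):
        config = SimConfig(seed=10)
        nan_layer = EnvLayer("suitability",
                             np.full(coarse_study_grid.shape, np.nan))
        with pytest.raises(ValueError, match="undefined"):
            simulate_track(config, nan_layer, coarse_study_grid, 0, 5, seed=10)

    def test_habitat_bias_raises_mean_visited_suitability(self, small_grid):
        rng = np.random.default_rng(11)
        suit = EnvLayer("suitability", rng.uniform(0, 1, small_grid.shape))
        config = SimConfig(
            colonies=(("T", -65.0, -55.0, "2008-01-01", 1),),
            habitat_bias=8.0, step_km_mean=30.0, step_km_sd=10.0, seed=12,
        )
        track = simulate_track(config, suit, small_grid, 0, 400, seed=12)
        r, c = small_grid.point_to_cell(track["lon"].to_numpy(),
                                        track["lat"].to_numpy())
        ok = r >= 0
        visited = suit.values[r[ok], c[ok]].mean()
        assert visited > suit.values.mean()


def _true_track(n_days=10, bird="b1"):
    from datetime import timedelta

    return pd.DataFrame({
        "bird_id": bird,
        "date": [date(2008, 1, 1) + timedelta(days=i) for i in range(n_days)],
        "lon": np.linspace(-60, -59, n_days),
        "lat": np.linspace(-52, -51, n_days),
    })


class TestArgosObservation:
    def test_zero_noise_reproduces_true_positions(self):
        config = SimConfig(class_error_km={0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0},
                           seed=13)
        fixes = apply_argos_observation(_true_track(), config, seed=13)
        merged = fixes.assign(date=fixes["timestamp"].dt.date).merge(
            _true_track(), on="date", suffixes=("", "_true")
        )
        np.testing.assert_allclose(merged["lon"], merged["lon_true"])
        np.testing.assert_allclose(merged["lat"], merged["lat_true"])

    def test_all_class3_rms_error_matches_scale(self):
        config = SimConfig(class_probabilities={0: 0.0, 1: 0.0, 2: 0.0, 3: 1.0},
                           fixes_per_window_mean=30.0, seed=14)
        truth = _true_track(n_days=60)
        fixes = apply_argos_observation(truth, config, seed=14)
        assert (fixes["location_class"] == 3).all()
        merged = fixes.assign(date=fixes["timestamp"].dt.date).merge(
            truth, on="date", suffixes=("", "_true")
        )
        disp = great_circle_km(
            (merged["lon"].to_numpy(), merged["lat"].to_numpy()),
            (merged["lon_true"].to_numpy(), merged["lat_true"].to_numpy()),
        )
        rms = float(np.sqrt(np.mean(disp**2)))
        assert rms == pytest.approx(0.15, rel=0.1)

    def test_fixes_confined_to_duty_on_windows(self):
        config = SimConfig(seed=15)
        fixes = apply_argos_observation(_true_track(), config, seed=15)
        hours = (fixes["timestamp"].dt.hour
                 + fixes["timestamp"].dt.minute / 60.0)
        assert ((hours >= 1.0) & (hours < 5.0)).all()

    def test_classes_follow_configured_distribution(self):
        config = SimConfig(seed=16, fixes_per_window_mean=50.0)
        fixes = apply_argos_observation(_true_track(60), config, seed=16)
        freq = fixes["location_class"].value_counts(normalize=True)
        for k, p in config.class_probabilities.items():
            assert freq.get(k, 0.0) == pytest.approx(p, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apply_argos_observation(pd.DataFrame(), SimConfig(seed=17), seed=17)

    def test_deterministic_under_seed(self):
        config = SimConfig(seed=18)
        a = apply_argos_observation(_true_track(), config, seed=18)
        b = apply_argos_observation(_true_track(), config, seed=18)
        pd.testing.assert_frame_equal(a, b)


class TestSimConfigInvariants:
    def test_class_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(class_probabilities={0: 0.5, 1: 0.1, 2: 0.1, 3: 0.1})

    def test_error_scales_must_be_ordered(self):
        with pytest.raises(ValueError, match="decrease"):
            SimConfig(class_error_km={0: 0.1, 1: 1.0, 2: 0.35, 3: 0.15})


class TestOccupancySampling:
    def test_presence_cells_prefer_suitable_habitat(self, small_grid):
        stack = standardize(build_env_stack(small_grid, seed=19))
        model = TrueHabitatModel({"BAT": 2.0, "intercept": -1.0})
        cells = sample_presence_cells(model, stack, n=60, seed=19)
        assert np.unique(cells).size == 60
        suit = model.suitability(stack).values.ravel()
        assert suit[cells].mean() > np.nanmean(suit)

    def test_suitability_is_probability(self, random_stack):
        model = TrueHabitatModel({"BAT": 1.0, "SST": -1.0})
        p = model.suitability(random_stack).values
        assert np.nanmin(p) > 0.0 and np.nanmax(p) < 1.0
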