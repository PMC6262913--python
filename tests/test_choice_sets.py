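"""Movement statistics, the availability radius, used/available sampling,
design extraction, and choice-set assembly."""

import numpy as np
import pytest

from choicersf import (
    ChoiceData,
    DesignCoding,
    MovementStats,
    TelemetryTrack,
    availability_radius,
    build_choice_sets,
    movement_stats,
    read_choice_csv,
    sample_available,
    write_choice_csv,
)
from choicersf.design import extract_design
from choicersf.errors import (
    DegenerateTrackError,
    InsufficientDataError,
    InvalidInputError,
    OutOfBoundsError,
)
from choicersf.landscape import CovariateGrids


def _track(xy, hours):
    times = np.datetime64("2012-01-01T00:00:00") + np.array(
        [np.timedelta64(int(h * 3600), "s") for h in hours]
    )
    return TelemetryTrack(individual_id="t", times=times, xy=np.asarray(xy, float))


class TestMovementStats:
    def test_constant_speed(self):
        t = _track([(0, 0), (500, 0), (1000, 0)], [0, 5, 10])
        s = movement_stats(t, nominal_interval=5.0)
        assert s.a == pytest.approx(100.0)
        assert s.b == pytest.approx(0.0)
        assert s.c == 5.0
        assert s.n_steps == 2

    def test_two_step_arithmetic(self):
        t = _track([(0, 0), (500, 0), (1500, 0)], [0, 5, 10])
        s = movement_stats(t, nominal_interval=5.0)
        assert s.a == pytest.approx(150.0)
        assert s.b == pytest.approx(70.7107, abs=1e-4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 200, size=(201, 2)), axis=0)
        t = _track(xy, np.arange(201) * 5.0)
        s = movement_stats(t, nominal_interval=5.0)
        # independent oracle: explicit python loop
        rates = []
        for i in range(200):
            d = float(np.hypot(*(xy[i + 1] - xy[i])))
            rates.append(d / 5.0)
        assert s.a == pytest.approx(np.mean(rates), abs=1e-9)
        assert s.b == pytest.approx(np.std(rates, ddof=1), abs=1e-9)

    def test_long_gaps_excluded_from_rates(self):
        # middle gap of 20 hr (> 2x nominal) must not enter a or b
        t = _track([(0, 0), (500, 0), (800, 0), (1300, 0)], [0, 5, 25, 30])
        s = movement_stats(t, nominal_interval=5.0)
        assert s.n_steps == 2
        assert s.a == pytest.approx(100.0)

    def test_too_few_steps_rejected(self):
        t = _track([(0, 0), (10, 0)], [0, 5])
        with pytest.raises(InsufficientDataError):
            movement_stats(t)

    def test_zero_elapsed_time_rejected(self):
        times = np.array(
            ["2012-01-01T00:00:00", "2012-01-01T00:00:00", "2012-01-01T05:00:00"],
            dtype="datetime64[s]",
        )
        with pytest.raises(InvalidInputError):
            TelemetryTrack("t", times, np.zeros((3, 2)))


class TestAvailabilityRadius:
    def test_formula(self):
        assert availability_radius(MovementStats(a=100, b=50, c=5, n_steps=10)) == 1000.0

    def test_zero_sd_limit(self):
        assert availability_radius(MovementStats(a=80, b=0, c=5, n_steps=10)) == 400.0

    def test_monotone_in_each_argument(self):
        base = availability_radius(MovementStats(a=100, b=50, c=5, n_steps=10))
        assert availability_radius(MovementStats(a=120, b=50, c=5, n_steps=10)) > base
        assert availability_radius(MovementStats(a=100, b=60, c=5, n_steps=10)) > base
        assert availability_radius(MovementStats(a=100, b=50, c=6, n_steps=10)) > base

    def test_stationary_track_degenerate(self):
        with pytest.raises(DegenerateTrackError):
            availability_radius(MovementStats(a=0, b=0, c=5, n_steps=10))


class TestSampleAvailable:
    def test_count_and_radius(self, small_grids):
        rng = np.random.default_rng(0)
        used = np.array([480.0, 480.0])
        pts = sample_available(used, 200.0, 5, small_grids, rng)
        assert pts.shape == (5, 2)
        assert np.all(np.hypot(*(pts - used).T) <= 200.0)

    def test_tiny_radius_still_returns_n(self, small_grids):
        rng = np.random.default_rng(1)
        used = np.array([480.0, 480.0])
        pts = sample_available(used, 1.0, 5, small_grids, rng)
        assert pts.shape == (5, 2)
        assert np.all(np.hypot(*(pts - used).T) <= 1.0)

    def test_mean_distance_matches_uniform_disc(self, small_grids):
        """Uniform on a disc of radius R has E[distance] = 2R/3."""
        rng = np.random.default_rng(2)
        used = np.array([480.0, 480.0])
        R = 100.0
        pts = sample_available(used, R, 10_000, small_grids, rng)
        mean_d = np.hypot(*(pts - used).T).mean()
        assert mean_d == pytest.approx(2.0 * R / 3.0, rel=0.01)


class TestExtractDesign:
    @pytest.fixture()
    def planted_grids(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        hab = np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1]])
        return CovariateGrids(
            layers={"v": vals},
            habitat=hab,
            habitat_labels=["ref", "b", "c"],
            cell_size=10.0,
        )

    def test_planted_values_recovered(self, planted_grids):
        coding = DesignCoding.from_grids(planted_grids)
        # cell (row 1, col 2) center: value 5, habitat code 0 (= reference)
        x = extract_design(np.array([25.0, 15.0]), planted_grids, coding)
        assert x[0] == 5.0
        assert np.all(x[1:] == 0.0)  # reference class -> all indicators zero

    def test_non_reference_class_sets_one_indicator(self, planted_grids):
        coding = DesignCoding.from_grids(planted_grids)
        # cell (0, 1): habitat code 1 -> label 'b'
        x = extract_design(np.array([15.0, 5.0]), planted_grids, coding)
        names = coding.column_names
        assert x[names.index("habitat:b")] == 1.0
        assert x[names.index("habitat:c")] == 0.0

    def test_same_cell_identical_vectors(self, planted_grids):
        coding = DesignCoding.from_grids(planted_grids)
        X = extract_design(np.array([[21.0, 11.0], [29.9, 19.9]]), planted_grids, coding)
        np.testing.assert_array_equal(X[0], X[1])

    def test_out_of_bounds_rejected(self, planted_grids):
        coding = DesignCoding.from_grids(planted_grids)
        with pytest.raises(OutOfBoundsError):
            extract_design(np.array([35.0, 5.0]), planted_grids, coding)


class TestBuildChoiceSets:
    def test_count_and_chosen_contract(self, small_grids, short_track):
        data = build_choice_sets(short_track, small_grids, seed=0)
        assert data.n_alternatives == 6  # used + 5 available
        assert data.n_sets <= short_track.n_fixes
        assert np.all(data.chosen == 0)
        # chosen coordinates equal the used fixes
        used_xy = data.coords[:, 0, :]
        kept = [int(s) for s in data.set_ids]
        np.testing.assert_allclose(used_xy, short_track.xy[kept])

    def test_available_points_within_radius(self, small_grids, short_track):
        stats = movement_stats(short_track)
        radius = availability_radius(stats)
        data = build_choice_sets(short_track, small_grids, seed=1, stats=stats)
        d = np.hypot(
            data.coords[:, 1:, 0] - data.coords[:, :1, 0],
            data.coords[:, 1:, 1] - data.coords[:, :1, 1],
        )
        assert np.all(d <= radius + 1e-9)

    def test_seeded_determinism(self, small_grids, short_track):
        a = build_choice_sets(short_track, small_grids, seed=5)
        b = build_choice_sets(short_track, small_grids, seed=5)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_long_csv_round_trip(self, tmp_path, small_grids, short_track):
        data = build_choice_sets(short_track, small_grids, seed=2)
        write_choice_csv(data, tmp_path / "c.csv", tmp_path / "coding.json")
        back = read_choice_csv(tmp_path / "c.csv", tmp_path / "coding.json")
        assert back.individual_id == data.individual_id
        assert back.column_names == data.column_names
        np.testing.assert_allclose(back.X, data.X, rtol=1e-12)
        np.testing.assert_array_equal(back.chosen, data.chosen)
        assert back.coding.reference == data.coding.reference
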