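"""Kinematic labelling: distances, window statistics, decision rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shearwater.labelling import (
    EARTH_RADIUS_M,
    ClassifierThresholds,
    arc_chord_tortuosity,
    attach_logger_values,
    classify_point,
    great_circle_distance,
    label_track,
    median_speed,
)
from shearwater.synthetic import SimConfig, simulate_track
from tests.conftest import equator_track


class TestGreatCircle:
    def test_zero_for_identical_points(self):
        assert great_circle_distance(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_one_degree_on_equator(self):
        d = great_circle_distance(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(EARTH_RADIUS_M * np.pi / 180.0, abs=1.0)

    def test_antipodal(self):
        assert great_circle_distance(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            np.pi * EARTH_RADIUS_M, rel=1e-9
        )

    @given(
        lat1=st.floats(-89, 89),
        lon1=st.floats(-180, 179),
        lat2=st.floats(-89, 89),
        lon2=st.floats(-180, 179),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d_ab = great_circle_distance(lat1, lon1, lat2, lon2)
        d_ba = great_circle_distance(lat2, lon2, lat1, lon1)
        assert d_ab >= 0
        assert d_ab == pytest.approx(d_ba, rel=1e-12, abs=1e-6)

    def test_nan_coordinate_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance(np.nan, 0, 0, 0)


class TestMedianSpeed:
    def test_constant_velocity(self):
        track = equator_track([10.0] * 7)
        assert median_speed(track, 3) == pytest.approx(10.0, rel=1e-6)

    def test_stationary(self):
        track = equator_track([0.0] * 7)
        assert median_speed(track, 3) == 0.0

    def test_median_of_segment_speeds(self):
        # 6-fix window with segment speeds 1,2,3,4,100 -> median 3
        track = equator_track([1.0, 2.0, 3.0, 4.0, 100.0])
        assert median_speed(track, 2) == pytest.approx(3.0, rel=1e-6)

    def test_undefined_near_ends(self):
        track = equator_track([10.0] * 7)
        assert np.isnan(median_speed(track, 0))
        assert np.isnan(median_speed(track, len(track) - 1))

    def test_non_increasing_timestamps_rejected(self):
        track = equator_track([10.0] * 6)
        track.loc[3, "time"] = track.loc[2, "time"]
        with pytest.raises(ValueError):
            median_speed(track, 2)


class TestTortuosity:
    def test_straight_line_is_one(self):
        track = equator_track([10.0] * 4)
        assert arc_chord_tortuosity(track, 2) == pytest.approx(1.0, abs=1e-9)

    def test_out_and_back_is_zero(self):
        # two fixes out, two back to the start: chord 0, arc > 0
        lons = [0.0, 0.01, 0.02, 0.01, 0.0]
        times = pd.Timestamp("2008-06-01T12:00Z") + pd.to_timedelta(
            np.arange(5) * 60, unit="s"
        )
        track = pd.DataFrame({"time": times, "lat": 0.0, "lon": lons})
        assert arc_chord_tortuosity(track, 2) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_two_legs(self):
        # two equal legs at 90 deg: arc 2L, chord L*sqrt(2)
        step = 0.001
        lats = [0.0, 0.0, 0.0, step, 2 * step]
        lons = [0.0, step, 2 * step, 2 * step, 2 * step]
        times = pd.Timestamp("2008-06-01T12:00Z") + pd.to_timedelta(
            np.arange(5) * 60, unit="s"
        )
        track = pd.DataFrame({"time": times, "lat": lats, "lon": lons})
        assert arc_chord_tortuosity(track, 2) == pytest.approx(np.sqrt(2) / 2, abs=1e-3)

    def test_zero_arc_flagged_not_crash(self):
        times = pd.Timestamp("2008-06-01T12:00Z") + pd.to_timedelta(
            np.arange(5) * 60, unit="s"
        )
        track = pd.DataFrame({"time": times, "lat": 10.0, "lon": 20.0})
        assert np.isnan(arc_chord_tortuosity(track, 2))

    @given(data=st.data())
    @settings(max_examples=30, derandomize=True)
    def test_bounded_in_unit_interval(self, data):
        n = 7
        lats = data.draw(
            st.lists(st.floats(-60, 60), min_size=n, max_size=n), label="lats"
        )
        lons = data.draw(
            st.lists(st.floats(-60, 60), min_size=n, max_size=n), label="lons"
        )
        times = pd.Timestamp("2008-06-01T12:00Z") + pd.to_timedelta(
            np.arange(n) * 60, unit="s"
        )
        track = pd.DataFrame({"time": times, "lat": lats, "lon": lons})
        t = arc_chord_tortuosity(track, 3)
        assert np.isnan(t) or 0.0 <= t <= 1.0


class TestClassifyPoint:
    @pytest.mark.parametrize(
        ("s", "t", "expected"),
        [
            (1.0, 0.99, "rest"),
            (8.0, 0.995, "flight"),
            (6.0, 0.50, "forage"),
            (2.5, 0.99, "rest"),  # boundary: speed exactly at the cut
            (2.6, 0.98, "flight"),  # boundary: tortuosity exactly at the cut
            (0.0, np.nan, "rest"),  # undefined tortuosity, slow -> rest
            (np.nan, 0.5, "undefined"),
        ],
    )
    def test_decision_rule(self, s, t, expected):
        assert classify_point(s, t) == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            classify_point(-1.0, 0.5)

    @given(s=st.floats(0, 30), t=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_partition_is_total_and_exclusive(self, s, t):
        assert classify_point(s, t) in {"rest", "flight", "forage"}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ClassifierThresholds(s_cut=-1.0)
        with pytest.raises(ValueError):
            ClassifierThresholds(t_cut=1.5)


class TestLabelTrack:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            label_track(equator_track([10.0] * 4))

    def test_all_flight_track(self, sim_config):
        cfg = SimConfig(turn_params={**sim_config.turn_params, "flight": 5000.0})
        states = np.array(["flight"] * 300, dtype=object)
        track = simulate_track(states, cfg, seed=3)
        lab = label_track(track)
        defined = lab[lab["label"] != "undefined"]
        assert (defined["label"] == "flight").mean() >= 0.95

    def test_stationary_track_is_rest(self, sim_config):
        states = np.array(["rest"] * 100, dtype=object)
        track = simulate_track(states, sim_config, seed=4)
        lab = label_track(track)
        defined = lab[lab["label"] != "undefined"]
        assert (defined["label"] == "rest").all()

    def test_boundary_fixes_undefined(self, trip):
        lab = label_track(trip.track)
        assert (lab["label"].iloc[:2] == "undefined").all()
        assert (lab["label"].iloc[-3:] == "undefined").all()

    def test_matches_bruteforce_oracle(self, trip):
        """Vectorised labelling agrees with a from-scratch window recomputation."""
        track = trip.track.iloc[:50].reset_index(drop=True)
        lab = label_track(track)
        for i in range(len(track)):
            s = median_speed(track, i)
            t = arc_chord_tortuosity(track, i)
            if i < 2 or i >= len(track) - 3:
                assert lab["label"].iloc[i] == "undefined"
            else:
                assert lab["s"].iloc[i] == pytest.approx(s, rel=1e-12)
                expected = classify_point(s, t)
                assert lab["label"].iloc[i] == expected


class TestAttachLoggerValues:
    @staticmethod
    def _logger():
        times = pd.to_datetime(
            ["2008-06-01T12:00Z", "2008-06-01T12:10Z", "2008-06-01T12:20Z"]
        )
        return pd.DataFrame({"time": times, "salt": [10, 20, 30], "light": [1, 2, 3]})

    def _fix_at(self, ts):
        return pd.DataFrame(
            {"time": [pd.Timestamp(ts)], "lat": [0.0], "lon": [0.0], "label": ["rest"]}
        )

    def test_exact_timestamp(self):
        out = attach_logger_values(self._fix_at("2008-06-01T12:10Z"), self._logger())
        assert out["salt"].iloc[0] == 20

    def test_equidistant_tie_goes_earlier(self):
        out = attach_logger_values(self._fix_at("2008-06-01T12:05Z"), self._logger())
        assert out["salt"].iloc[0] == 10

    def test_nearest_wins(self):
        # 4 min after the first sample, 6 min before the second
        out = attach_logger_values(self._fix_at("2008-06-01T12:04Z"), self._logger())
        assert out["salt"].iloc[0] == 10

    def test_empty_logger_rejected(self):
        with pytest.raises(ValueError):
            attach_logger_values(self._fix_at("2008-06-01T12:00Z"), self._logger().iloc[:0])
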