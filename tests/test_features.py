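import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homepatterns.events import EventStream, Location, SensorEvent, N_PHASES
from homepatterns.features import (
    DAY_FEATURE_NAMES,
    SUBSET_DAY_COLUMNS,
    aggregate_participants,
    day_feature_frame,
    day_features,
    feature_name,
    mean_busyness,
    split_days,
    time_between_events,
)

NIGHT_LEN = 7 * 3600.0


def te_closed_form(t):
    """Independent oracle: the telescoped form [(T_m - T_2) + (T_{m-1} - T_1)] / 2m."""
    m = len(t)
    return ((t[-1] - t[1]) + (t[-2] - t[0])) / (2 * m)


class TestTimeBetweenEvents:
    def test_equally_spaced_four_events(self):
        assert time_between_events([0, 10, 20, 30], NIGHT_LEN) == pytest.approx(5.0)

    def test_three_events(self):
        assert time_between_events([0, 10, 30], NIGHT_LEN) == pytest.approx(5.0)

    def test_sentinel_below_three_events(self):
        assert time_between_events([0, 100], 25200.0) == 25200.0
        assert time_between_events([], 25200.0) == 25200.0

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError):
            time_between_events([10, 0, 20], NIGHT_LEN)

    @given(st.lists(st.floats(min_value=0, max_value=25200,
                              allow_nan=False), min_size=3, max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_matches_telescoped_closed_form(self, times):
        t = sorted(times)
        assert time_between_events(t, NIGHT_LEN) == pytest.approx(
            te_closed_form(t), abs=1e-9)

    @given(st.lists(st.floats(min_value=0, max_value=3600, allow_nan=False),
                    min_size=3, max_size=30),
           st.floats(min_value=-1e5, max_value=1e5, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_shift_invariance(self, times, shift):
        t = np.sort(np.asarray(times))
        assert time_between_events(t + shift, NIGHT_LEN) == pytest.approx(
            time_between_events(t, NIGHT_LEN), abs=1e-6)


def _stream(events):
    return EventStream("U1", [SensorEvent("U1", ts, loc) for ts, loc in events])


class TestDayFeatures:
    DAY = dt.date(2024, 3, 1)

    def test_empty_day_sentinels(self):
        noon = dt.datetime(2024, 3, 5, 12, 0)
        stream = _stream([(noon, Location.LOUNGE)])
        vec = day_features(stream, self.DAY)
        for room in ("bedroom", "bathroom", "lounge"):
            for p in range(1, N_PHASES + 1):
                assert vec[feature_name(room, "busyness", p)] == 0
                te = vec[feature_name(room, "te", p)]
                assert te > 0  # phase length sentinel

    def test_single_event_at_1205_is_lounge_phase4(self):
        stream = _stream([(dt.datetime(2024, 3, 1, 12, 5), Location.LOUNGE)])
        vec = day_features(stream, self.DAY)
        assert vec[feature_name("lounge", "busyness", 4)] == 1
        assert vec[feature_name("lounge", "te", 4)] == 2 * 3600.0  # sentinel, m < 3
        assert vec.filter(like="_busyness_").sum() == 1

    def test_known_event_times_recounted(self):
        """Constructed day: counts and TE match a by-hand recount."""
        base = dt.datetime(2024, 3, 1, 23, 0)  # night phase of logical 1 Mar
        offsets = [0, 10, 20, 30]
        stream = _stream([(base + dt.timedelta(seconds=s), Location.BEDROOM)
                          for s in offsets])
        vec = day_features(stream, self.DAY)
        assert vec[feature_name("bedroom", "busyness", 1)] == 4
        assert vec[feature_name("bedroom", "te", 1)] == pytest.approx(5.0)

    def test_night_spans_midnight_in_one_logical_day(self):
        """23:30 and 05:30 next morning fall in the same (day, phase) cell."""
        stream = _stream([
            (dt.datetime(2024, 3, 1, 23, 30), Location.BATHROOM),
            (dt.datetime(2024, 3, 2, 1, 0), Location.BATHROOM),
            (dt.datetime(2024, 3, 2, 5, 30), Location.BATHROOM),
        ])
        vec = day_features(stream, self.DAY)
        assert vec[feature_name("bathroom", "busyness", 1)] == 3
        # times since 23:00: 1800, 7200, 23400 -> TE via the closed form
        assert vec[feature_name("bathroom", "te", 1)] == pytest.approx(
            ((23400 - 7200) + (7200 - 1800)) / 6.0)

    def test_busyness_conservation(self, default_cohort):
        """Summed busyness over all cells equals the stream's PIR count per day."""
        stream = default_cohort[0][0]
        frame = day_feature_frame(stream)
        busy_cols = [c for c in frame.columns if "_busyness_" in c]
        assert int(frame[busy_cols].to_numpy().sum()) == len(stream)

    def test_42_columns_in_schema_order(self):
        assert len(DAY_FEATURE_NAMES) == 42
        stream = _stream([(dt.datetime(2024, 3, 1, 12, 0), Location.LOUNGE)])
        assert list(day_feature_frame(stream).columns) == list(DAY_FEATURE_NAMES)


class TestSplitDays:
    @pytest.mark.parametrize("n, n_train", [(78, 55), (57, 40), (36, 25),
                                            (22, 15), (10, 7)])
    def test_published_split_arithmetic(self, n, n_train):
        days = [dt.date(2024, 1, 1) + dt.timedelta(days=i) for i in range(n)]
        split = split_days(days, 0.7, seed=0)
        assert len(split.train_days) == n_train
        assert len(split.test_days) == n - n_train

    def test_partition_is_disjoint_and_complete(self):
        days = [dt.date(2024, 1, 1) + dt.timedelta(days=i) for i in range(30)]
        split = split_days(days, 0.7, seed=3)
        assert set(split.train_days) | set(split.test_days) == set(days)
        assert not set(split.train_days) & set(split.test_days)

    def test_seed_reproducibility(self):
        days = [dt.date(2024, 1, 1) + dt.timedelta(days=i) for i in range(30)]
        assert split_days(days, seed=5) == split_days(days, seed=5)
        assert split_days(days, seed=5) != split_days(days, seed=6)

    def test_invalid_fraction_rejected(self):
        days = [dt.date(2024, 1, 1), dt.date(2024, 1, 2)]
        with pytest.raises(ValueError):
            split_days(days, fraction=1.5)


class TestAggregation:
    @pytest.mark.parametrize("subset, n_cols", [
        ("full84", 84), ("night12", 12), ("bedroom28", 28),
        ("bathroom28", 28), ("lounge28", 28),
    ])
    def test_subset_column_counts(self, default_day_frames, subset, n_cols):
        matrix = aggregate_participants(default_day_frames, subset)
        assert matrix.shape == (10, n_cols)

    def test_night12_column_structure(self, default_day_frames):
        cols = aggregate_participants(default_day_frames, "night12").columns
        expected = [f"{room}_{family}_tod1_{stat}"
                    for room in ("bedroom", "bathroom", "lounge")
                    for family in ("busyness", "te")
                    for stat in ("M", "SD")]
        assert list(cols) == expected

    def test_constant_days_give_zero_sd(self):
        frame = pd.DataFrame(
            [[1.0] * 42] * 3, columns=list(DAY_FEATURE_NAMES),
            index=[dt.date(2024, 1, 1 + i) for i in range(3)])
        matrix = aggregate_participants({"U1": frame}, "full84")
        sd_cols = [c for c in matrix.columns if c.endswith("_SD")]
        assert (matrix[sd_cols].to_numpy() == 0).all()

    def test_single_day_rejected(self):
        frame = pd.DataFrame([[1.0] * 42], columns=list(DAY_FEATURE_NAMES),
                             index=[dt.date(2024, 1, 1)])
        with pytest.raises(ValueError, match="SD"):
            aggregate_participants({"U1": frame}, "full84")

    def test_mean_sd_against_recount(self, default_day_frames):
        user, frame = next(iter(default_day_frames.items()))
        matrix = aggregate_participants({user: frame}, "night12")
        col = feature_name("bedroom", "busyness", 1)
        assert matrix.at[user, col + "_M"] == pytest.approx(frame[col].mean())
        assert matrix.at[user, col + "_SD"] == pytest.approx(
            frame[col].std(ddof=1))


class TestMeanBusyness:
    def test_uniform_days(self):
        frame = pd.DataFrame(0.0, columns=list(DAY_FEATURE_NAMES),
                             index=[dt.date(2024, 1, 1), dt.date(2024, 1, 2)])
        for room in ("bedroom", "bathroom", "lounge"):
            for p in range(1, N_PHASES + 1):
                frame[feature_name(room, "busyness", p)] = 70 / 21
        # 70 events per day over 7 phases -> 10 per ToD
        assert mean_busyness(frame) == pytest.approx(10.0)

    def test_empty_frame_is_zero(self):
        frame = pd.DataFrame(columns=list(DAY_FEATURE_NAMES))
        assert mean_busyness(frame) == 0.0

    def test_matches_event_recount(self, default_cohort, default_day_frames):
        stream = default_cohort[0][0]
        frame = default_day_frames[stream.user_id]
        n_days = len(frame)
        assert mean_busyness(frame) == pytest.approx(
            len(stream) / n_days / N_PHASES)
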