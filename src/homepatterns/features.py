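"""Busyness and time-between-events (TE) features per room and time of day.

Each logical day of a PIR-filtered stream is summarised by 42 features:
3 rooms x 7 ToD phases x 2 families,

* **busyness** — the event count *m* in the (room, phase, day) cell;
* **TE** — a summary of the spacing of consecutive events,

      TE = sum_{i=1}^{m-2} [ (T_{i+2} - T_{i+1}) + (T_{i+1} - T_i) ] / (2m)

  with times in seconds from the phase start.  The sum telescopes to
  [(T_m - T_2) + (T_{m-1} - T_1)] / (2m).  With fewer than three events
  there is no measurable rhythm and TE falls back to the phase length in
  seconds, so silent cells read as maximally slow rather than maximally
  fast.

Participant-level vectors are the per-day mean (M) and sample standard
deviation (SD) of each feature, restricted to one of the published feature
subsets (night-time only, full 24 h, or one room as an independent block).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    DEFAULT_SEGMENTATION,
    EventStream,
    N_PHASES,
    PIR_LOCATIONS,
    ToDWindow,
    filter_pir,
)

ROOMS = tuple(loc.value for loc in PIR_LOCATIONS)
FAMILIES = ("busyness", "te")


def feature_name(room: str, family: str, phase: int) -> str:
    return f"{room}_{family}_tod{phase}"


#: The 42 day-level feature names in schema order (room-major, then family,
#: then phase 1..7).
DAY_FEATURE_NAMES: tuple[str, ...] = tuple(
    feature_name(room, family, phase)
    for room in ROOMS
    for family in FAMILIES
    for phase in range(1, N_PHASES + 1)
)

#: Day-level column subsets behind each participant-level schema; the
#: participant matrix doubles each (mean + SD).
SUBSET_DAY_COLUMNS: dict[str, tuple[str, ...]] = {
    "night12": tuple(
        feature_name(room, family, 1) for room in ROOMS for family in FAMILIES
    ),
    "full84": DAY_FEATURE_NAMES,
    "bedroom28": tuple(
        feature_name("bedroom", family, p)
        for family in FAMILIES for p in range(1, N_PHASES + 1)
    ),
    "bathroom28": tuple(
        feature_name("bathroom", family, p)
        for family in FAMILIES for p in range(1, N_PHASES + 1)
    ),
    "lounge28": tuple(
        feature_name("lounge", family, p)
        for family in FAMILIES for p in range(1, N_PHASES + 1)
    ),
}


def time_between_events(seq: Sequence[float] | np.ndarray,
                        phase_length_s: float) -> float:
    """TE of one (room, phase, day) timestamp sequence (seconds).

    Implements the defining sum directly; returns the sentinel
    ``phase_length_s`` when fewer than three events occurred.
    """
    t = np.asarray(seq, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("timestamp sequence must be nondecreasing")
    m = t.size
    if m < 3:
        return float(phase_length_s)
    gaps = np.diff(t)  # gaps[i] = T_{i+1} - T_i
    total = float(gaps[:-1].sum() + gaps[1:].sum())
    return total / (2.0 * m)


def busyness(seq: Sequence[float] | np.ndarray) -> int:
    """Event count *m* of one (room, phase, day) cell."""
    return int(len(seq))


def _event_table(stream: EventStream,
                 segmentation: Sequence[ToDWindow]) -> pd.DataFrame:
    """Tabulate PIR events as (logical_day, room, phase, rel_s)."""
    stream = filter_pir(stream)
    if not stream.events:
        return pd.DataFrame(columns=["logical_day", "room", "phase", "rel_s"])
    ts = pd.DatetimeIndex([e.timestamp for e in stream.events])
    room = pd.Categorical([e.location.value for e in stream.events],
                          categories=list(ROOMS))
    sec_of_day = (ts.hour * 3600 + ts.minute * 60 + ts.second
                  + ts.microsecond / 1e6).to_numpy(dtype=float)
    minute_lookup = np.empty(24 * 60, dtype=np.int64)
    offset_lookup = np.empty(N_PHASES + 1, dtype=float)
    for w in segmentation:
        if w.start_minute <= w.end_minute:
            minute_lookup[w.start_minute:w.end_minute] = w.phase_id
        else:
            minute_lookup[w.start_minute:] = w.phase_id
            minute_lookup[:w.end_minute] = w.phase_id
        offset_lookup[w.phase_id] = w.start_minute * 60.0
    phase = minute_lookup[(sec_of_day // 60).astype(np.int64)]
    logical_day = (ts - pd.Timedelta(hours=6)).normalize()
    # seconds since the phase's wall-clock start; the night phase starts at
    # 23:00 of the logical day's own calendar date
    phase_clock_start = (
        logical_day.to_numpy().astype("datetime64[s]").astype(float)
        + offset_lookup[phase]
    )
    rel_s = ts.to_numpy().astype("datetime64[us]").astype(float) / 1e6 - phase_clock_start
    return pd.DataFrame({
        "logical_day": logical_day.date,
        "room": room,
        "phase": phase,
        "rel_s": rel_s,
    })


def day_feature_frame(stream: EventStream,
                      days: Iterable[dt.date] | None = None,
                      segmentation: Sequence[ToDWindow] = DEFAULT_SEGMENTATION,
                      ) -> pd.DataFrame:
    """All 42 features for every logical day of a stream.

    Rows are logical days (``days`` if given, else the observed contiguous
    span); columns are :data:`DAY_FEATURE_NAMES`.  Empty cells read
    busyness 0 and TE = phase length.
    """
    table = _event_table(stream, segmentation)
    phase_len = {w.phase_id: w.length_seconds for w in segmentation}
    if days is None:
        if table.empty:
            days = []
        else:
            lo, hi = min(table["logical_day"]), max(table["logical_day"])
            days = [lo + dt.timedelta(days=i) for i in range((hi - lo).days + 1)]
    days = list(days)

    frame = pd.DataFrame(index=pd.Index(days, name="logical_day"),
                         columns=list(DAY_FEATURE_NAMES), dtype=float)
    for room in ROOMS:
        for p in range(1, N_PHASES + 1):
            frame[feature_name(room, "busyness", p)] = 0.0
            frame[feature_name(room, "te", p)] = phase_len[p]
    if not table.empty:
        day_set = set(days)
        grouped = table.groupby(["logical_day", "room", "phase"],
                                observed=True, sort=True)["rel_s"]
        for (day, room, p), rel in grouped:
            if day not in day_set:
                continue
            t = np.sort(rel.to_numpy())
            frame.at[day, feature_name(room, "busyness", p)] = float(t.size)
            frame.at[day, feature_name(room, "te", p)] = time_between_events(
                t, phase_len[p])
    return frame


def day_features(stream: EventStream, logical_day: dt.date,
                 segmentation: Sequence[ToDWindow] = DEFAULT_SEGMENTATION,
                 ) -> pd.Series:
    """The 42-feature vector of a single logical day."""
    return day_feature_frame(stream, days=[logical_day],
                             segmentation=segmentation).iloc[0]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DaySplit:
    """A randomized train/test partition of logical days."""

    train_days: tuple[dt.date, ...]
    test_days: tuple[dt.date, ...]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.seed,
            "train_days": [d.isoformat() for d in self.train_days],
            "test_days": [d.isoformat() for d in self.test_days],
        }, indent=2))


def split_days(all_days: Sequence[dt.date], fraction: float = 0.7,
               seed: int = 0) -> DaySplit:
    """Shuffle days and split, round-half-up(fraction * n) to the train set.

    Reproduces the published learning-set sizes: 78 -> 55, 57 -> 40,
    36 -> 25, 22 -> 15 days at fraction 0.7.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    days = list(all_days)
    if len(days) < 2:
        raise ValueError("need at least 2 days to split")
    order = np.random.default_rng(seed).permutation(len(days))
    n_train = _round_half_up(fraction * len(days))
    shuffled = [days[i] for i in order]
    return DaySplit(tuple(shuffled[:n_train]), tuple(shuffled[n_train:]), seed)


def aggregate_participants(day_frames: Mapping[str, pd.DataFrame],
                           subset: str = "full84") -> pd.DataFrame:
    """Participant-level mean/SD matrix for one feature subset.

    ``day_frames`` maps user_id to that user's day-level feature frame
    (rows already restricted to the days of interest, e.g. a train split).
    Output columns interleave ``<name>_M`` and ``<name>_SD`` in schema
    order; the sample (n-1) standard deviation is used, so every user
    needs at least two days.
    """
    if subset not in SUBSET_DAY_COLUMNS:
        raise KeyError(f"unknown subset {subset!r}; one of {sorted(SUBSET_DAY_COLUMNS)}")
    day_cols = list(SUBSET_DAY_COLUMNS[subset])
    rows = {}
    for user_id, frame in day_frames.items():
        if len(frame) < 2:
            raise ValueError(
                f"user {user_id!r} has {len(frame)} day(s); SD needs >= 2")
        sub = frame[day_cols]
        mean, sd = sub.mean(axis=0), sub.std(axis=0, ddof=1)
        row = {}
        for col in day_cols:
            row[f"{col}_M"] = mean[col]
            row[f"{col}_SD"] = sd[col]
        rows[user_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "user_id"
    return out


def mean_busyness(day_frame: pd.DataFrame) -> float:
    """Mean per-ToD busyness: daily PIR event total / 7 phases, averaged over days.

    Used to place a participant on the published sedentary-to-active scale
    (roughly 50 to 400+ motion events per hour house-wide).
    """
    if len(day_frame) == 0:
        return 0.0
    busy_cols = [c for c in day_frame.columns if "_busyness_" in c]
    daily_total = day_frame[busy_cols].sum(axis=1)
    return float((daily_total / N_PHASES).mean())
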