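"""Sensor event data model, times-of-day segmentation and logical days.

A dwelling's raw record is a stream of timestamped sensor activations with
four attributes: participant id, timestamp, sensor location and sensor value.
Three passive-infrared (PIR) motion sensors (bedroom, bathroom, lounge) carry
the behavioural signal; two contact switches (front door, fridge) may be
present but are excluded from analysis.

The 24-hour clock is tiled by seven fixed *times of day* (ToD) windows,
phase 1 being the night window 23:00-05:59 which spans midnight.  To keep a
night block on a single analysis day, events are attributed to a *logical
day*: the calendar date of (timestamp - 6 h), so each logical day runs from
06:00 to 06:00 the next morning and owns the night that follows its daytime.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Location(str, Enum):
    """Sensor placements available in a dwelling."""

    BEDROOM = "bedroom"
    BATHROOM = "bathroom"
    LOUNGE = "lounge"
    FRONT_DOOR = "front_door"
    FRIDGE = "fridge"


#: The three motion sensors used for analysis, in canonical (schema) order.
PIR_LOCATIONS: tuple[Location, ...] = (
    Location.BEDROOM,
    Location.BATHROOM,
    Location.LOUNGE,
)


@dataclass(frozen=True, slots=True)
class SensorEvent:
    """One timestamped sensor activation."""

    user_id: str
    timestamp: dt.datetime
    location: Location
    value: int = 1


@dataclass(frozen=True)
class ToDWindow:
    """A half-open clock-time window [start, end) of the daily segmentation.

    ``start_minute``/``end_minute`` are minutes after midnight; a window with
    ``start_minute > end_minute`` wraps across midnight.
    """

    phase_id: int
    name: str
    start_minute: int
    end_minute: int

    def contains(self, minute_of_day: float) -> bool:
        if self.start_minute <= self.end_minute:
            return self.start_minute <= minute_of_day < self.end_minute
        return minute_of_day >= self.start_minute or minute_of_day < self.end_minute

    @property
    def length_seconds(self) -> float:
        span = (self.end_minute - self.start_minute) % (24 * 60)
        return span * 60.0


#: The seven fixed ToD windows tiling the 24-h clock.  "23:00-5:59" is read
#: as the half-open interval [23:00, 06:00); likewise for every window the
#: printed end label is the last whole minute of a half-open interval.
DEFAULT_SEGMENTATION: tuple[ToDWindow, ...] = (
    ToDWindow(1, "Night Time", 23 * 60, 6 * 60),
    ToDWindow(2, "Early Morning", 6 * 60, 10 * 60),
    ToDWindow(3, "Late Morning", 10 * 60, 12 * 60),
    ToDWindow(4, "Early Afternoon", 12 * 60, 14 * 60),
    ToDWindow(5, "Afternoon", 14 * 60, 17 * 60),
    ToDWindow(6, "Evening", 17 * 60, 20 * 60),
    ToDWindow(7, "Late Evening", 20 * 60, 23 * 60),
)

N_PHASES = len(DEFAULT_SEGMENTATION)

#: Offset of the logical-day boundary from midnight: a logical day runs
#: [06:00, 06:00 next day) so the night window is never split.
LOGICAL_DAY_OFFSET = dt.timedelta(hours=6)


def assign_tod(timestamp: dt.datetime | dt.time,
               segmentation: Sequence[ToDWindow] = DEFAULT_SEGMENTATION) -> int:
    """Return the phase id (1-7) of the window containing the clock time."""
    t = timestamp.time() if isinstance(timestamp, dt.datetime) else timestamp
    minute = t.hour * 60 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    for window in segmentation:
        if window.contains(minute):
            return window.phase_id
    raise ValueError(f"segmentation does not tile the clock at {t!r}")


def phase_length_seconds(phase_id: int,
                         segmentation: Sequence[ToDWindow] = DEFAULT_SEGMENTATION) -> float:
    """Clock length of a ToD window in seconds."""
    for window in segmentation:
        if window.phase_id == phase_id:
            return window.length_seconds
    raise KeyError(f"no phase {phase_id}")


def assign_logical_day(timestamp: dt.datetime) -> dt.date:
    """Calendar date of (timestamp - 6 h): the analysis day the event belongs to."""
    return (timestamp - LOGICAL_DAY_OFFSET).date()


def phase_start(logical_day: dt.date, phase_id: int,
                segmentation: Sequence[ToDWindow] = DEFAULT_SEGMENTATION) -> dt.datetime:
    """Wall-clock start of a phase within a logical day.

    The night phase (which wraps midnight) starts at 23:00 of the logical
    day's own date; daytime phases start on the logical day's date.
    """
    for window in segmentation:
        if window.phase_id == phase_id:
            start = dt.datetime.combine(
                logical_day, dt.time(window.start_minute // 60, window.start_minute % 60)
            )
            if start - dt.datetime.combine(logical_day, dt.time(0)) < LOGICAL_DAY_OFFSET:
                # clock start before 06:00 belongs to the *next* calendar date
                start += dt.timedelta(days=1)
            return start
    raise KeyError(f"no phase {phase_id}")


@dataclass
class EventStream:
    """All events of one participant, sorted ascending by timestamp."""

    user_id: str
    events: list[SensorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def filter_pir(stream: EventStream) -> EventStream:
    """Keep only the three PIR motion-sensor locations; order preserved."""
    keep = set(PIR_LOCATIONS)
    return EventStream(stream.user_id,
                       [e for e in stream.events if e.location in keep])


HEADER = ["user_id", "timestamp", "location", "value"]


@dataclass
class LoadReport:
    """Accepted/rejected row counts from reading an event log."""

    accepted: int = 0
    rejected: list[dict] = field(default_factory=list)

    def reject(self, line: int, reason: str) -> None:
        self.rejected.append({"line": line, "reason": reason})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"accepted": self.accepted, "n_rejected": len(self.rejected),
             "rejected": self.rejected}, indent=2))


def read_events(path: str | Path,
                report: LoadReport | None = None) -> list[EventStream]:
    """Read an event-log CSV into one sorted stream per participant.

    The file must carry the header ``user_id,timestamp,location,value`` with
    ISO-8601 timestamps.  Malformed rows are rejected record-by-record and
    recorded (with their line number) in *report*; they never abort the load.
    """
    path = Path(path)
    if report is None:
        report = LoadReport()
    by_user: dict[str, list[SensorEvent]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != HEADER:
            raise ValueError(f"{path}: expected header {','.join(HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                report.reject(lineno, f"expected 4 fields, got {len(row)}")
                continue
            user_id, ts_raw, loc_raw, val_raw = (c.strip() for c in row)
            try:
                ts = dt.datetime.fromisoformat(ts_raw)
            except ValueError:
                report.reject(lineno, f"malformed timestamp {ts_raw!r}")
                continue
            try:
                loc = Location(loc_raw)
            except ValueError:
                report.reject(lineno, f"unknown location {loc_raw!r}")
                continue
            try:
                value = int(val_raw)
            except ValueError:
                value = 1
            by_user.setdefault(user_id, []).append(
                SensorEvent(user_id, ts, loc, value))
            report.accepted += 1
    return [EventStream(uid, evs) for uid, evs in sorted(by_user.items())]


def write_events(streams: Iterable[EventStream], path: str | Path) -> None:
    """Write streams to a single event-log CSV (inverse of :func:`read_events`)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for stream in streams:
            for e in stream.events:
                writer.writerow([e.user_id, e.timestamp.isoformat(),
                                 e.location.value, e.value])
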