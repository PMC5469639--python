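"""Synthetic smart-home event simulator for two cohorts.

Generates PIR motion-event streams with the statistical structure the
analysis pipeline assumes: per-room, per-time-of-day Poisson event rates,
an 8-second sensor blind time, fragmented (bursty) night-time activity for
the cognitively-impaired cohort, and daytime carer-visit bursts in the
lounge.  The two default cohort profiles — OP (older persons) and CI
(persons with cognitive impairments) — overlap during the day but differ
strongly at night, where sleep fragmentation raises CI bedroom and bathroom
activity; night-time is therefore the most discriminative period, which is
the separation the downstream clustering must recover.

Event-rate magnitudes are anchored to the published span for home PIR
sensing (a sedentary resident around 50 motion events per hour house-wide,
an active one above 400).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import (
    DEFAULT_SEGMENTATION,
    EventStream,
    Location,
    N_PHASES,
    PIR_LOCATIONS,
    SensorEvent,
)

ROOMS = tuple(loc.value for loc in PIR_LOCATIONS)


@dataclass(frozen=True)
class VisitWindow:
    """A planned daytime visit: a burst of lounge events once per day.

    ``rate_per_hour`` is the event rate *during* the visit;
    ``duration_s`` its length.  The visit start is uniform within the phase.
    """

    phase_id: int
    rate_per_hour: float
    duration_s: float


@dataclass(frozen=True)
class CohortProfile:
    """Expected PIR event rates (events/hour) per room and ToD phase.

    ``rates[room]`` is a length-7 tuple indexed by phase 1..7.
    ``night_fragmentation`` >= 1 turns night activity into bursts of that
    mean size (total expected count unchanged), emulating fragmented sleep.
    """

    cohort: str
    rates: dict[str, tuple[float, ...]]
    night_fragmentation: float = 1.0
    visit_windows: tuple[VisitWindow, ...] = ()
    blind_time_s: float = 8.0
    #: lognormal sigma of the per-participant rate multiplier (mean 1) drawn
    #: once per (room, phase); individual homes differ in overall tempo, so
    #: within-cohort variance is real, not just Poisson noise
    rate_heterogeneity: float = 0.35

    def __post_init__(self) -> None:
        for room, phase_rates in self.rates.items():
            if room not in ROOMS:
                raise ValueError(f"unknown room {room!r}")
            if len(phase_rates) != N_PHASES:
                raise ValueError(f"{room}: need {N_PHASES} phase rates")
            if any(r < 0 for r in phase_rates):
                raise ValueError(f"{room}: negative rate")
        if self.blind_time_s < 0:
            raise ValueError("blind_time_s must be >= 0")
        if self.night_fragmentation < 1:
            raise ValueError("night_fragmentation must be >= 1")
        if self.rate_heterogeneity < 0:
            raise ValueError("rate_heterogeneity must be >= 0")


#: Default profiles.  Phases: 1 Night, 2 Early Morning, 3 Late Morning,
#: 4 Early Afternoon, 5 Afternoon, 6 Evening, 7 Late Evening.
DEFAULT_OP_PROFILE = CohortProfile(
    cohort="OP",
    rates={
        "bedroom":  (6.0, 20.0, 6.0, 5.0, 5.0, 8.0, 25.0),
        "bathroom": (1.5, 12.0, 6.0, 5.0, 5.0, 8.0, 10.0),
        "lounge":   (0.5, 12.0, 25.0, 25.0, 25.0, 30.0, 18.0),
    },
    night_fragmentation=1.0,
    visit_windows=(
        VisitWindow(3, 180.0, 20 * 60.0),
        VisitWindow(5, 180.0, 20 * 60.0),
    ),
)

DEFAULT_CI_PROFILE = CohortProfile(
    cohort="CI",
    rates={
        "bedroom":  (20.0, 22.0, 8.0, 6.0, 6.0, 9.0, 30.0),
        "bathroom": (6.0, 12.0, 7.0, 6.0, 6.0, 9.0, 14.0),
        "lounge":   (2.0, 11.0, 23.0, 23.0, 23.0, 28.0, 20.0),
    },
    night_fragmentation=2.5,
    visit_windows=(
        VisitWindow(3, 180.0, 30 * 60.0),
        VisitWindow(5, 180.0, 30 * 60.0),
    ),
)


def blend_profiles(base: CohortProfile, other: CohortProfile,
                   effect_size: float) -> CohortProfile:
    """Interpolate *other* toward *base*: 0 -> base rates, 1 -> other unchanged."""
    rates = {
        room: tuple(
            b + effect_size * (o - b)
            for b, o in zip(base.rates[room], other.rates[room])
        )
        for room in other.rates
    }
    frag = 1.0 + (base.night_fragmentation - 1.0) + effect_size * (
        other.night_fragmentation - base.night_fragmentation)
    visits = other.visit_windows if effect_size > 0 else base.visit_windows
    return replace(other, rates=rates, night_fragmentation=max(frag, 1.0),
                   visit_windows=visits)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a two-cohort simulation run."""

    n_op: int = 5
    n_ci: int = 5
    n_days: int = 55
    seed: int = 0
    effect_size: float = 1.0
    op_profile: CohortProfile = DEFAULT_OP_PROFILE
    ci_profile: CohortProfile = DEFAULT_CI_PROFILE
    start_date: dt.date = dt.date(2024, 1, 1)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_op < 1 or self.n_ci < 1:
            raise ValueError("each cohort needs at least one participant")


# seconds after the logical day's 00:00 at which each phase starts; the
# night phase starts at 23:00 of the logical day's own calendar date
_PHASE_OFFSETS_S = {w.phase_id: w.start_minute * 60.0 for w in DEFAULT_SEGMENTATION}
_PHASE_LENGTHS_S = {w.phase_id: w.length_seconds for w in DEFAULT_SEGMENTATION}


def _burst_times(rng: np.random.Generator, lam: float, length_s: float,
                 frag: float) -> np.ndarray:
    """Night event times: Poisson bursts of mean size ``frag``, mean total ``lam``."""
    n_bursts = rng.poisson(lam / frag)
    if n_bursts == 0:
        return np.empty(0)
    onsets = rng.uniform(0.0, length_s, size=n_bursts)
    sizes = 1 + rng.poisson(frag - 1.0, size=n_bursts)
    times = []
    for onset, size in zip(onsets, sizes):
        gaps = rng.exponential(20.0, size=size)
        gaps[0] = 0.0
        times.append(onset + np.cumsum(gaps))
    t = np.concatenate(times)
    return t[t < length_s]


def _thin_blind_time(times_s: np.ndarray, blind_time_s: float) -> np.ndarray:
    """Forward-sequential PIR retrigger thinning on sorted times (one room)."""
    if blind_time_s <= 0 or times_s.size == 0:
        return times_s
    keep = np.zeros(times_s.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times_s):
        if t - last >= blind_time_s:
            keep[i] = True
            last = t
    return times_s[keep]


def simulate_stream(profile: CohortProfile, n_days: int,
                    seed: int | np.random.SeedSequence,
                    user_id: str = "U1",
                    start_date: dt.date = dt.date(2024, 1, 1)) -> EventStream:
    """Simulate one participant's event stream over ``n_days`` logical days.

    Within each (logical day, room, phase) cell, event times follow a
    homogeneous Poisson process at the profile's rate — replaced by a burst
    process at night when ``night_fragmentation`` > 1 — superposed with the
    profile's daily visit bursts (lounge), and finally thinned per room so
    consecutive events are at least ``blind_time_s`` apart.
    """
    rng = np.random.default_rng(seed)
    sigma = profile.rate_heterogeneity
    if sigma > 0:
        # personal tempo: one mean-1 lognormal multiplier per (room, phase)
        mult = {room: rng.lognormal(-sigma ** 2 / 2, sigma, size=N_PHASES)
                for room in ROOMS}
    else:
        mult = {room: np.ones(N_PHASES) for room in ROOMS}
    per_room: dict[str, list[np.ndarray]] = {room: [] for room in ROOMS}
    for day in range(n_days):
        day_offset = day * 86400.0
        for room in ROOMS:
            for phase in range(1, N_PHASES + 1):
                rate = profile.rates[room][phase - 1] * mult[room][phase - 1]
                length = _PHASE_LENGTHS_S[phase]
                lam = rate * length / 3600.0
                if lam == 0:
                    continue
                if phase == 1 and profile.night_fragmentation > 1:
                    t = _burst_times(rng, lam, length, profile.night_fragmentation)
                else:
                    t = rng.uniform(0.0, length, size=rng.poisson(lam))
                if t.size:
                    per_room[room].append(day_offset + _PHASE_OFFSETS_S[phase] + t)
        for visit in profile.visit_windows:
            length = _PHASE_LENGTHS_S[visit.phase_id]
            dur = min(visit.duration_s, length)
            onset = rng.uniform(0.0, length - dur) if length > dur else 0.0
            n = rng.poisson(visit.rate_per_hour * dur / 3600.0)
            if n:
                t = onset + rng.uniform(0.0, dur, size=n)
                per_room["lounge"].append(
                    day_offset + _PHASE_OFFSETS_S[visit.phase_id] + t)

    base = dt.datetime.combine(start_date, dt.time(0))
    events: list[SensorEvent] = []
    for room in ROOMS:
        if not per_room[room]:
            continue
        times = np.sort(np.concatenate(per_room[room]))
        times = _thin_blind_time(times, profile.blind_time_s)
        loc = Location(room)
        events.extend(
            SensorEvent(user_id, base + dt.timedelta(seconds=round(float(t), 3)), loc)
            for t in times
        )
    return EventStream(user_id, events)


def simulate_cohorts(spec: SimulationSpec) -> tuple[list[EventStream], pd.DataFrame]:
    """Simulate both cohorts; returns streams and a (user_id, cohort) label table.

    Each participant gets an independent sub-seed derived from
    ``spec.seed`` by counter (spawn key), so adding participants never
    perturbs earlier participants' streams.
    """
    ci_profile = blend_profiles(spec.op_profile, spec.ci_profile, spec.effect_size)
    streams: list[EventStream] = []
    labels: list[tuple[str, str]] = []
    roster = [("OP", spec.op_profile)] * spec.n_op + [("CI", ci_profile)] * spec.n_ci
    for i, (cohort, profile) in enumerate(roster):
        user_id = f"{cohort}{i + 1:02d}"
        sub_seed = np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,))
        streams.append(simulate_stream(profile, spec.n_days, sub_seed,
                                       user_id=user_id, start_date=spec.start_date))
        labels.append((user_id, cohort))
    return streams, pd.DataFrame(labels, columns=["user_id", "cohort"])
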