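"""Parsing of Fitbit-style wearable logs into typed records.

Two per-volunteer JSON streams are read:

``<id>.sleep.json``
    an array of sleep-session objects with keys ``startTime`` / ``endTime``
    (ISO-8601 local clock timestamps at minute resolution), ``minutesAsleep``,
    ``timeInBed`` and ``awakeningsCount``.

``<id>.days.json``
    an array of tracker-day objects with keys ``date`` (ISO calendar date),
    ``hrCoverageHours`` (hours of intraday heart-rate coverage, 0-24) and
    ``steps`` (daily step total).

All timestamps are naive local clock times; the study is single-timezone and
no timezone arithmetic is performed.  Sleep efficiency is always recomputed
from the minute counts (100 * minutes_asleep / minutes_in_bed) so that the
definition of SE is single-sourced here rather than trusted from the device
export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "SleepSession",
    "TrackerDay",
    "ParseError",
    "SchemaError",
    "RecordValidationError",
    "SleepParseResult",
    "parse_sleep_log",
    "parse_day_log",
    "sessions_to_frame",
    "days_to_frame",
    "serialize_sessions",
    "serialize_days",
]

_SESSION_KEYS = ("startTime", "endTime", "minutesAsleep", "timeInBed", "awakeningsCount")
_DAY_KEYS = ("date", "hrCoverageHours", "steps")


class ParseError(ValueError):
    """Raised when the input is not syntactically valid JSON."""


class SchemaError(ValueError):
    """Raised when a record is missing a required key or violates the dialect."""


class RecordValidationError(ValueError):
    """Raised when a record's fields violate a domain invariant."""


@dataclass(frozen=True)
class SleepSession:
    """One tracker-recorded sleep bout.

    ``efficiency_pct`` is recomputed as ``100 * minutes_asleep /
    minutes_in_bed`` and never read from the file.
    """

    volunteer_id: str
    start: datetime
    end: datetime
    minutes_asleep: int
    minutes_in_bed: int
    wake_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RecordValidationError(
                f"session end {self.end} not after start {self.start}"
            )
        if self.minutes_asleep < 0 or self.wake_count < 0:
            raise RecordValidationError("negative minutes_asleep or wake_count")
        if self.minutes_in_bed <= 0:
            raise RecordValidationError("minutes_in_bed must be positive")
        if self.minutes_asleep > self.minutes_in_bed:
            raise RecordValidationError(
                f"minutes_asleep ({self.minutes_asleep}) exceeds minutes_in_bed "
                f"({self.minutes_in_bed})"
            )
        span = (self.end - self.start).total_seconds() / 60.0
        if self.minutes_in_bed > span + 1:
            raise RecordValidationError(
                f"minutes_in_bed ({self.minutes_in_bed}) exceeds session span "
                f"({span:.0f} min) + 1"
            )

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.minutes_asleep / self.minutes_in_bed

    @property
    def duration_minutes(self) -> float:
        """Bed-interval span in minutes (end - start)."""
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class TrackerDay:
    """Per-day completeness inputs: heart-rate coverage hours and step total."""

    volunteer_id: str
    date: date
    hr_coverage_hours: float
    total_steps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.hr_coverage_hours <= 24.0:
            raise RecordValidationError(
                f"hr_coverage_hours {self.hr_coverage_hours} outside [0, 24]"
            )
        if self.total_steps < 0:
            raise RecordValidationError("total_steps must be non-negative")


@dataclass
class SleepParseResult(Sequence):
    """Sessions parsed from one sleep log, plus skip accounting.

    Behaves as a sequence of :class:`SleepSession` so callers that only want
    the records can iterate it directly; records skipped for record-level
    validation failures (end <= start) are counted, never silently dropped.
    """

    sessions: list[SleepSession]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __len__(self) -> int:
        return len(self.sessions)

    def __getitem__(self, i):
        return self.sessions[i]

    def __iter__(self) -> Iterator[SleepSession]:
        return iter(self.sessions)


def _load_array(raw_json_text: str) -> list:
    try:
        doc = json.loads(raw_json_text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(doc, list):
        raise SchemaError("top-level JSON value must be an array of records")
    return doc


def _parse_minute_timestamp(text: str, key: str, index: int) -> datetime:
    try:
        ts = datetime.fromisoformat(text)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"session {index}: {key} is not an ISO-8601 timestamp") from exc
    return ts.replace(second=0, microsecond=0)


def parse_sleep_log(raw_json_text: str, volunteer_id: str = "") -> SleepParseResult:
    """Parse one volunteer's sleep log.

    Parameters
    ----------
    raw_json_text:
        JSON array of session objects in the documented dialect.
    volunteer_id:
        Identifier to stamp on records that do not carry a ``volunteerId``
        key themselves (the per-volunteer file layout keeps the id in the
        filename).

    Returns
    -------
    SleepParseResult
        Sessions sorted by start time, with skipped-record accounting.
        An empty array parses to an empty result.

    Raises
    ------
    ParseError
        Malformed JSON (message names the byte offset).
    SchemaError
        A session object is missing a required key (message names the key
        and the session index).
    RecordValidationError
        A session violates a field invariant other than session ordering
        (e.g. minutes asleep exceeding minutes in bed).
    """
    sessions: list[SleepSession] = []
    skipped: list[tuple[int, str]] = []
    for i, obj in enumerate(_load_array(raw_json_text)):
        if not isinstance(obj, dict):
            raise SchemaError(f"session {i}: expected a JSON object")
        for key in _SESSION_KEYS:
            if key not in obj:
                raise SchemaError(f"session {i}: missing required key '{key}'")
        start = _parse_minute_timestamp(obj["startTime"], "startTime", i)
        end = _parse_minute_timestamp(obj["endTime"], "endTime", i)
        if end <= start:
            skipped.append((i, f"end {end} not after start {start}"))
            continue
        sessions.append(
            SleepSession(
                volunteer_id=str(obj.get("volunteerId", volunteer_id)),
                start=start,
                end=end,
                minutes_asleep=int(obj["minutesAsleep"]),
                minutes_in_bed=int(obj["timeInBed"]),
                wake_count=int(obj["awakeningsCount"]),
            )
        )
    sessions.sort(key=lambda s: s.start)
    return SleepParseResult(sessions=sessions, skipped=skipped)


def parse_day_log(raw_json_text: str, volunteer_id: str = "") -> list[TrackerDay]:
    """Parse one volunteer's tracker-day log.

    Duplicate dates are a schema error; coverage outside [0, 24] is a
    validation error.
    """
    days: list[TrackerDay] = []
    seen: set[date] = set()
    for i, obj in enumerate(_load_array(raw_json_text)):
        if not isinstance(obj, dict):
            raise SchemaError(f"day {i}: expected a JSON object")
        for key in _DAY_KEYS:
            if key not in obj:
                raise SchemaError(f"day {i}: missing required key '{key}'")
        try:
            d = date.fromisoformat(str(obj["date"]))
        except ValueError as exc:
            raise SchemaError(f"day {i}: date is not an ISO calendar date") from exc
        if d in seen:
            raise SchemaError(f"day {i}: duplicate date {d.isoformat()}")
        seen.add(d)
        days.append(
            TrackerDay(
                volunteer_id=str(obj.get("volunteerId", volunteer_id)),
                date=d,
                hr_coverage_hours=float(obj["hrCoverageHours"]),
                total_steps=int(obj["steps"]),
            )
        )
    days.sort(key=lambda d: d.date)
    return days


def serialize_sessions(sessions: Sequence[SleepSession]) -> str:
    """Write sessions back to the JSON dialect (round-trips with the parser)."""
    return json.dumps(
        [
            {
                "volunteerId": s.volunteer_id,
                "startTime": s.start.strftime("%Y-%m-%dT%H:%M"),
                "endTime": s.end.strftime("%Y-%m-%dT%H:%M"),
                "minutesAsleep": s.minutes_asleep,
                "timeInBed": s.minutes_in_bed,
                "awakeningsCount": s.wake_count,
            }
            for s in sessions
        ],
        indent=1,
    )


def serialize_days(days: Sequence[TrackerDay]) -> str:
    return json.dumps(
        [
            {
                "volunteerId": d.volunteer_id,
                "date": d.date.isoformat(),
                "hrCoverageHours": d.hr_coverage_hours,
                "steps": d.total_steps,
            }
            for d in days
        ],
        indent=1,
    )


def sessions_to_frame(sessions: Sequence[SleepSession]) -> pd.DataFrame:
    """Tidy one-row-per-session table for inspection/export."""
    return pd.DataFrame(
        {
            "volunteer_id": [s.volunteer_id for s in sessions],
            "start": [s.start for s in sessions],
            "end": [s.end for s in sessions],
            "minutes_asleep": [s.minutes_asleep for s in sessions],
            "minutes_in_bed": [s.minutes_in_bed for s in sessions],
            "wake_count": [s.wake_count for s in sessions],
            "efficiency_pct": [s.efficiency_pct for s in sessions],
        }
    )


def days_to_frame(days: Sequence[TrackerDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "volunteer_id": [d.volunteer_id for d in days],
            "date": [d.date for d in days],
            "hr_coverage_hours": [d.hr_coverage_hours for d in days],
            "total_steps": [d.total_steps for d in days],
        }
    )
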