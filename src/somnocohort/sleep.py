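"""Per-night and per-volunteer sleep metrics.

A *night* is keyed by the calendar day on which its window opens: a session
belongs to night D iff it starts in the half-open window [20:00 of D, 08:00
of D+1).  Sessions starting in [08:00, 20:00) are naps and are excluded from
every nightly metric (their counts are reported).

Nightly metrics: TST is the sum of the assigned sessions' sleep minutes; SE
is the unweighted mean of their efficiencies; awakenings is the sum of their
wake counts.  Volunteer metrics are plain means over that volunteer's
retained nights, with TST converted to hours.

Sleep hour / wake hour are circular means (computed as minutes past the
window origin, 20:00) of the start / end times of window-assigned sessions
whose bed interval lasts at least 3 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import SleepSession

__all__ = [
    "NightlySummary",
    "VolunteerSleepSummary",
    "NIGHT_WINDOW_START",
    "NIGHT_WINDOW_END",
    "MIN_MAIN_SLEEP_MINUTES",
    "assign_sessions_to_nights",
    "summarize_night",
    "circular_clock_mean",
    "summarize_volunteer",
    "derive_cohort_summary",
]

NIGHT_WINDOW_START = time(20, 0)  # 8 PM
NIGHT_WINDOW_END = time(8, 0)  # 8 AM next day
MIN_MAIN_SLEEP_MINUTES = 180  # >= 3 h bed interval feeds sleep/wake hour


@dataclass(frozen=True)
class NightlySummary:
    volunteer_id: str
    night_of: date
    tst_minutes: float
    se_pct: float
    awakenings: float
    n_sessions: int


@dataclass(frozen=True)
class VolunteerSleepSummary:
    volunteer_id: str
    tst_hours: float
    se_pct: float
    awakenings: float
    sleep_hour: time | None
    wake_hour: time | None
    n_nights: int


def _night_of(start: datetime, window_start: time, window_end: time) -> date | None:
    t = start.time()
    if t >= window_start:
        return start.date()
    if t < window_end:
        return start.date() - timedelta(days=1)
    return None


def assign_sessions_to_nights(
    sessions: Sequence[SleepSession],
    window_start: time = NIGHT_WINDOW_START,
    window_end: time = NIGHT_WINDOW_END,
) -> tuple[dict[date, list[SleepSession]], list[SleepSession]]:
    """Partition one volunteer's sessions into nights, dropping naps.

    Returns ``(by_night, naps)`` where ``by_night`` maps the night's start
    day to its sessions (in start order) and ``naps`` holds the sessions
    that start outside the night window.  Each session lands in at most one
    night.
    """
    by_night: dict[date, list[SleepSession]] = {}
    naps: list[SleepSession] = []
    for s in sorted(sessions, key=lambda s: s.start):
        night = _night_of(s.start, window_start, window_end)
        if night is None:
            naps.append(s)
        else:
            by_night.setdefault(night, []).append(s)
    return by_night, naps


def summarize_night(
    night_of: date, assigned_sessions: Sequence[SleepSession]
) -> NightlySummary:
    """Aggregate one night: TST = sum of sleep minutes, SE = unweighted mean
    of session efficiencies, awakenings = sum of wake counts."""
    if not assigned_sessions:
        raise ValueError("cannot summarize a night with no sessions")
    return NightlySummary(
        volunteer_id=assigned_sessions[0].volunteer_id,
        night_of=night_of,
        tst_minutes=float(sum(s.minutes_asleep for s in assigned_sessions)),
        se_pct=sum(s.efficiency_pct for s in assigned_sessions)
        / len(assigned_sessions),
        awakenings=float(sum(s.wake_count for s in assigned_sessions)),
        n_sessions=len(assigned_sessions),
    )


def minutes_since_origin(t: datetime | time, origin: time = NIGHT_WINDOW_START) -> int:
    """Clock offset of ``t`` past ``origin``, in [0, 1440)."""
    clock = t.time() if isinstance(t, datetime) else t
    delta = (clock.hour - origin.hour) * 60 + (clock.minute - origin.minute)
    return delta % 1440


def circular_clock_mean(
    times: Sequence[datetime | time], window_origin: time = NIGHT_WINDOW_START
) -> time:
    """Mean clock time of times lying within 24 h after ``window_origin``.

    Each time is mapped to its minute offset past the origin (in [0, 1440)),
    the offsets are averaged arithmetically, and the mean offset is mapped
    back to a clock time (rounded to the nearest minute).  This makes the
    mean of times spanning midnight well defined: 23:00 and 01:00 average to
    00:00, not 12:00.
    """
    if not times:
        raise ValueError("no times to average")
    offsets = [minutes_since_origin(t, window_origin) for t in times]
    mean_offset = sum(offsets) / len(offsets)
    total = (
        window_origin.hour * 60 + window_origin.minute + round(mean_offset)
    ) % 1440
    return time(total // 60, total % 60)


def summarize_volunteer(
    nights: Sequence[NightlySummary],
    assigned_sessions: Iterable[SleepSession],
    min_main_sleep_minutes: float = MIN_MAIN_SLEEP_MINUTES,
    duration_field: str = "minutes_in_bed",
) -> VolunteerSleepSummary:
    """Volunteer-level aggregates over nights plus sleep/wake clock hours.

    ``assigned_sessions`` are the window-assigned (non-nap) sessions; only
    those with ``duration_field`` >= ``min_main_sleep_minutes`` contribute to
    sleep hour (mean start) and wake hour (mean end).  If no session passes
    the duration filter, both hours are ``None``.
    """
    if not nights:
        raise ValueError("cannot summarize a volunteer with no nights")
    main = [
        s
        for s in assigned_sessions
        if getattr(s, duration_field) >= min_main_sleep_minutes
    ]
    sleep_hour = circular_clock_mean([s.start for s in main]) if main else None
    wake_hour = circular_clock_mean([s.end for s in main]) if main else None
    n = len(nights)
    return VolunteerSleepSummary(
        volunteer_id=nights[0].volunteer_id,
        tst_hours=sum(nt.tst_minutes for nt in nights) / n / 60.0,
        se_pct=sum(nt.se_pct for nt in nights) / n,
        awakenings=sum(nt.awakenings for nt in nights) / n,
        sleep_hour=sleep_hour,
        wake_hour=wake_hour,
        n_nights=n,
    )


def derive_cohort_summary(
    sessions_by_volunteer: Mapping[str, Sequence[SleepSession]],
    complete_dates_by_volunteer: Mapping[str, set[date]] | None = None,
    window_start: time = NIGHT_WINDOW_START,
    window_end: time = NIGHT_WINDOW_END,
    min_main_sleep_minutes: float = MIN_MAIN_SLEEP_MINUTES,
) -> pd.DataFrame:
    """Per-volunteer sleep-summary table for a whole cohort.

    When ``complete_dates_by_volunteer`` is given, a night is retained iff
    its start calendar day is in the volunteer's complete-day set (QC
    gating); otherwise every night is retained.  Volunteers with no retained
    nights are omitted.  Columns mirror the study's summary-table metric
    names: TST in hours, SE in percent, awakenings per night.
    """
    rows = []
    for vid in sorted(sessions_by_volunteer):
        by_night, _naps = assign_sessions_to_nights(
            sessions_by_volunteer[vid], window_start, window_end
        )
        if complete_dates_by_volunteer is not None:
            allowed = complete_dates_by_volunteer.get(vid, set())
            by_night = {d: s for d, s in by_night.items() if d in allowed}
        if not by_night:
            continue
        nights = [summarize_night(d, by_night[d]) for d in sorted(by_night)]
        retained_sessions = [s for d in sorted(by_night) for s in by_night[d]]
        summ = summarize_volunteer(
            nights, retained_sessions, min_main_sleep_minutes
        )
        rows.append(
            {
                "volunteer_id": vid,
                "tst_hours": summ.tst_hours,
                "se_pct": summ.se_pct,
                "awakenings": summ.awakenings,
                "sleep_hour": None
                if summ.sleep_hour is None
                else summ.sleep_hour.strftime("%H:%M"),
                "wake_hour": None
                if summ.wake_hour is None
                else summ.wake_hour.strftime("%H:%M"),
                "n_nights": summ.n_nights,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "volunteer_id",
            "tst_hours",
            "se_pct",
            "awakenings",
            "sleep_hour",
            "wake_hour",
            "n_nights",
        ],
    )
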