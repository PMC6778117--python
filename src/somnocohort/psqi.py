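"""Pittsburgh Sleep Quality Index (PSQI) scoring.

The PSQI is a 19-item self-report instrument covering the past month.  The
items combine into seven component scores, each 0-3, whose sum is the global
score (0-21, higher = worse sleep):

1. subjective sleep quality          (quality item)
2. sleep latency                     (latency minutes + item 5a)
3. sleep duration                    (self-reported hours of sleep)
4. habitual sleep efficiency         (hours slept / time in bed)
5. sleep disturbances                (items 5b-5j summed)
6. use of sleeping medication
7. daytime dysfunction               (sleepiness + enthusiasm items)

Frequency items use the instrument's codes: 0 = not during the past month,
1 = less than once a week, 2 = once or twice a week, 3 = three or more times
a week.  Item 5b (waking in the middle of the night or early morning) is the
self-reported counterpart of tracker-detected nocturnal awakenings and is
exposed on its own.

Band edges for components 3 and 4 are printed ambiguously in most summaries
of the instrument ("6 to 7 hours", "75-84%"); the edges used here follow the
original instrument convention and live in one place (`score_component3`,
`score_component4`) so they can be audited or changed together.  The five
bed-partner items are not part of scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from datetime import time

import pandas as pd

__all__ = [
    "PSQIResponse",
    "PSQIScores",
    "score_component3",
    "score_component4",
    "score_question5b",
    "score_global",
    "score_table",
    "DISTURBANCE_ITEMS",
]

DISTURBANCE_ITEMS = [f"item5{c}" for c in "bcdefghij"]
_FREQ_ITEMS = ["item5a", *DISTURBANCE_ITEMS]
_ORDINAL_ITEMS = ["item6_quality", "item7_medication", "item8_sleepiness", "item9_enthusiasm"]


@dataclass(frozen=True)
class PSQIResponse:
    """Raw 19-item self-rated answers for one volunteer."""

    volunteer_id: str
    bed_time: time
    rise_time: time
    sleep_latency_minutes: float
    sleep_hours: float  # self-reported TST, hours
    item5a: int  # cannot get to sleep within 30 minutes
    item5b: int  # wake up in the middle of the night or early morning
    item5c: int  # have to get up to use the bathroom
    item5d: int  # cannot breathe comfortably
    item5e: int  # cough or snore loudly
    item5f: int  # feel too cold
    item5g: int  # feel too hot
    item5h: int  # had bad dreams
    item5i: int  # have pain
    item5j: int  # other reason
    item6_quality: int  # subjective sleep quality, 0 (very good) - 3 (very bad)
    item7_medication: int  # sleeping medication frequency code
    item8_sleepiness: int  # trouble staying awake frequency code
    item9_enthusiasm: int  # problem keeping up enthusiasm, 0-3

    def __post_init__(self) -> None:
        if self.sleep_hours < 0:
            raise ValueError("sleep_hours must be non-negative")
        if self.sleep_latency_minutes < 0:
            raise ValueError("sleep_latency_minutes must be non-negative")
        for name in (*_FREQ_ITEMS, *_ORDINAL_ITEMS):
            code = getattr(self, name)
            if code not in (0, 1, 2, 3):
                raise ValueError(f"{name} code {code!r} outside {{0,1,2,3}}")


@dataclass(frozen=True)
class PSQIScores:
    volunteer_id: str
    component1: int
    component2: int
    component3: int
    component4: int
    component5: int
    component6: int
    component7: int
    global_score: int
    habitual_se_pct: float


def score_component3(sleep_hours: float) -> int:
    """Sleep-duration component: >7 h -> 0, (6,7] -> 1, [5,6] -> 2, <5 -> 3."""
    if sleep_hours < 0:
        raise ValueError("sleep_hours must be non-negative")
    if sleep_hours > 7:
        return 0
    if sleep_hours > 6:
        return 1
    if sleep_hours >= 5:
        return 2
    return 3


def _time_in_bed_hours(bed_time: time, rise_time: time) -> float:
    minutes = (
        (rise_time.hour - bed_time.hour) * 60 + (rise_time.minute - bed_time.minute)
    ) % 1440
    return minutes / 60.0


def score_component4(
    sleep_hours: float, bed_time: time, rise_time: time
) -> tuple[float, int]:
    """Habitual sleep efficiency and its component score.

    Time in bed is the clock difference rise - bed, wrapping midnight.
    SE% = 100 * hours slept / hours in bed; bands: >85 -> 0, [75,85] -> 1,
    [65,75) -> 2, <65 -> 3.
    """
    tib = _time_in_bed_hours(bed_time, rise_time)
    if tib <= 0:
        raise ValueError("time in bed is zero; bed and rise times coincide")
    se = 100.0 * sleep_hours / tib
    if se > 85:
        score = 0
    elif se >= 75:
        score = 1
    elif se >= 65:
        score = 2
    else:
        score = 3
    return se, score


def score_question5b(frequency_code: int) -> int:
    """Nocturnal-awakening frequency: the code is the score (identity)."""
    if frequency_code not in (0, 1, 2, 3):
        raise ValueError(f"frequency code {frequency_code!r} outside {{0,1,2,3}}")
    return frequency_code


def _band_sum(total: int, edges: tuple[int, int, int]) -> int:
    # common PSQI pattern: 0 -> 0, then three increasing bands
    if total == 0:
        return 0
    if total <= edges[0]:
        return 1
    if total <= edges[1]:
        return 2
    return 3


def _latency_minutes_code(minutes: float) -> int:
    if minutes <= 15:
        return 0
    if minutes <= 30:
        return 1
    if minutes <= 60:
        return 2
    return 3


def score_global(response: PSQIResponse) -> PSQIScores:
    """All seven components and the global score for one complete response.

    Missing items raise (no imputation); a dataclass input cannot carry a
    missing item, so the check guards table-driven callers passing NaN.
    """
    for f in fields(response):
        if pd.isna(getattr(response, f.name)):
            raise ValueError(f"missing PSQI item: {f.name}")
    c1 = response.item6_quality
    c2 = _band_sum(
        _latency_minutes_code(response.sleep_latency_minutes) + response.item5a,
        (2, 4, 6),
    )
    c3 = score_component3(response.sleep_hours)
    habitual_se, c4 = score_component4(
        response.sleep_hours, response.bed_time, response.rise_time
    )
    c5 = _band_sum(sum(getattr(response, it) for it in DISTURBANCE_ITEMS), (9, 18, 27))
    c6 = response.item7_medication
    c7 = _band_sum(response.item8_sleepiness + response.item9_enthusiasm, (2, 4, 6))
    comps = (c1, c2, c3, c4, c5, c6, c7)
    return PSQIScores(
        volunteer_id=response.volunteer_id,
        component1=c1,
        component2=c2,
        component3=c3,
        component4=c4,
        component5=c5,
        component6=c6,
        component7=c7,
        global_score=sum(comps),
        habitual_se_pct=habitual_se,
    )


def _parse_clock(value) -> time:
    if isinstance(value, time):
        return value
    hh, mm = str(value).split(":")
    return time(int(hh), int(mm))


def score_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a one-row-per-volunteer response table.

    Expects the documented column names (``volunteer_id``, ``bed_time``,
    ``rise_time``, ``sleep_latency_minutes``, ``sleep_hours``, ``item5a`` ..
    ``item5j``, ``item6_quality``, ``item7_medication``, ``item8_sleepiness``,
    ``item9_enthusiasm``); clock times as "HH:MM".  Returns component scores,
    global score and habitual SE per volunteer.
    """
    rows = []
    for _, r in responses.iterrows():
        resp = PSQIResponse(
            volunteer_id=str(r["volunteer_id"]),
            bed_time=_parse_clock(r["bed_time"]),
            rise_time=_parse_clock(r["rise_time"]),
            sleep_latency_minutes=float(r["sleep_latency_minutes"]),
            sleep_hours=float(r["sleep_hours"]),
            **{it: int(r[it]) for it in _FREQ_ITEMS},
            **{it: int(r[it]) for it in _ORDINAL_ITEMS},
        )
        s = score_global(resp)
        rows.append(
            {
                "volunteer_id": s.volunteer_id,
                **{f"component{i}": getattr(s, f"component{i}") for i in range(1, 8)},
                "global_score": s.global_score,
                "habitual_se_pct": s.habitual_se_pct,
                "selfreport_tst_hours": resp.sleep_hours,
                "item5b": resp.item5b,
            }
        )
    return pd.DataFrame(rows)
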