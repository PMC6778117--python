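"""Day-completeness and volunteer-inclusion filters.

A tracker day is *data-complete* when it has at least 20 h of heart-rate
coverage and a nonzero step count; a volunteer is included when they have at
least three data-complete days.  Both thresholds are arguments with those
defaults.  Coverage hours arrive precomputed in the day log; deriving them
from raw HR samples is out of scope.

An optional percentile filter on mean daily steps is provided for removing
extreme-activity outliers; it is off by default because "extreme" has no
canonical definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import TrackerDay

__all__ = [
    "QCReport",
    "assess_day",
    "build_qc_report",
    "qc_cohort",
    "complete_dates",
    "filter_extreme_activity",
    "MIN_COVERAGE_HOURS",
    "MIN_COMPLETE_DAYS",
]

MIN_COVERAGE_HOURS = 20.0
MIN_COMPLETE_DAYS = 3


@dataclass(frozen=True)
class QCReport:
    volunteer_id: str
    n_days_total: int
    n_days_complete: int
    included: bool
    exclusion_reason: str  # "none" or "too_few_complete_days"


def assess_day(day: TrackerDay, min_hours: float = MIN_COVERAGE_HOURS) -> bool:
    """True iff the day is data-complete: coverage >= min_hours and steps > 0."""
    return day.hr_coverage_hours >= min_hours and day.total_steps > 0


def build_qc_report(
    days: Sequence[TrackerDay],
    min_hours: float = MIN_COVERAGE_HOURS,
    min_complete_days: int = MIN_COMPLETE_DAYS,
) -> QCReport:
    """Inclusion decision for one volunteer from their tracker days.

    An empty day list yields an excluded report with zero counts.
    """
    vid = days[0].volunteer_id if days else ""
    n_complete = sum(assess_day(d, min_hours) for d in days)
    included = n_complete >= min_complete_days
    return QCReport(
        volunteer_id=vid,
        n_days_total=len(days),
        n_days_complete=n_complete,
        included=included,
        exclusion_reason="none" if included else "too_few_complete_days",
    )


def complete_dates(
    days: Iterable[TrackerDay], min_hours: float = MIN_COVERAGE_HOURS
) -> set[date]:
    """Set of calendar dates that pass the completeness predicate.

    Used to gate sleep nights: a night is retained iff its start calendar
    day is complete.
    """
    return {d.date for d in days if assess_day(d, min_hours)}


def qc_cohort(
    days_by_volunteer: Mapping[str, Sequence[TrackerDay]],
    min_hours: float = MIN_COVERAGE_HOURS,
    min_complete_days: int = MIN_COMPLETE_DAYS,
) -> pd.DataFrame:
    """One QC row per volunteer, in sorted volunteer order."""
    reports = []
    for vid in sorted(days_by_volunteer):
        rep = build_qc_report(days_by_volunteer[vid], min_hours, min_complete_days)
        reports.append(
            {
                "volunteer_id": vid,
                "n_days_total": rep.n_days_total,
                "n_days_complete": rep.n_days_complete,
                "included": rep.included,
                "exclusion_reason": rep.exclusion_reason,
            }
        )
    return pd.DataFrame(
        reports,
        columns=[
            "volunteer_id",
            "n_days_total",
            "n_days_complete",
            "included",
            "exclusion_reason",
        ],
    )


def filter_extreme_activity(
    mean_daily_steps: pd.Series,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> pd.Series:
    """Boolean keep-mask dropping volunteers outside the given step percentiles.

    Off by default in the pipeline; apply only when requested.
    """
    lo, hi = np.percentile(mean_daily_steps.dropna(), [lower_pct, upper_pct])
    return (mean_daily_steps >= lo) & (mean_daily_steps <= hi)
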