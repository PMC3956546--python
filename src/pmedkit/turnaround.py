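"""Clinical turnaround-time accounting.

Elapsed time between timestamped sample-processing events is reported in
*business hours*: all timestamps are converted to US Eastern civil time
and every hour falling on a weekend day or a holiday date is subtracted
from the wall-clock span.  A business "day" is the full 24 hours of a
non-excluded calendar day — this is the convention under which a span of
116.46 business hours equals 4.85 days (116.46 / 24).

Rounding to two decimals happens only at the reporting layer; internal
arithmetic is exact to the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

EASTERN = ZoneInfo("America/New_York")

#: US federal holidays observed during 2011 (the study window was
#: May-October 2011; the full year is shipped for completeness).
US_HOLIDAYS_2011 = frozenset({
    date(2010, 12, 31),  # New Year's Day 2011 (observed)
    date(2011, 1, 17),   # Martin Luther King Jr. Day
    date(2011, 2, 21),   # Washington's Birthday
    date(2011, 5, 30),   # Memorial Day
    date(2011, 7, 4),    # Independence Day
    date(2011, 9, 5),    # Labor Day
    date(2011, 10, 10),  # Columbus Day
    date(2011, 11, 11),  # Veterans Day
    date(2011, 11, 24),  # Thanksgiving Day
    date(2011, 12, 26),  # Christmas Day (observed)
})


@dataclass(frozen=True)
class BusinessCalendar:
    """Weekend-day indices (Monday=0) and holiday dates to exclude."""

    weekend_days: tuple[int, ...] = (5, 6)  # Saturday, Sunday
    holidays: frozenset[date] = US_HOLIDAYS_2011

    def __post_init__(self) -> None:
        if not set(self.weekend_days) <= set(range(7)):
            raise ValueError("weekend_days must be weekday indices 0-6")

    def is_excluded(self, d: date) -> bool:
        return d.weekday() in self.weekend_days or d in self.holidays


@dataclass
class EventLog:
    """Ordered, timezone-aware events for one sample."""

    sample_id: str
    cohort: str
    events: list[tuple[str, datetime]]

    def __post_init__(self) -> None:
        for label, ts in self.events:
            if ts.tzinfo is None:
                raise ValueError(f"{self.sample_id}/{label}: timestamp lacks a zone offset")
        est = [ts.astimezone(EASTERN) for _, ts in self.events]
        if any(b < a for a, b in zip(est, est[1:])):
            raise ValueError(f"{self.sample_id}: events not in chronological order")

    def span(self, start_label: str | None = None, end_label: str | None = None
             ) -> tuple[datetime, datetime]:
        labels = {lab: ts for lab, ts in self.events}
        start = labels[start_label] if start_label else self.events[0][1]
        end = labels[end_label] if end_label else self.events[-1][1]
        return start, end


def _day_bounds(d: date) -> tuple[datetime, datetime]:
    start = datetime.combine(d, time(0), tzinfo=EASTERN)
    end = datetime.combine(d + timedelta(days=1), time(0), tzinfo=EASTERN)
    return start, end


def elapsed_business_hours(start: datetime, end: datetime,
                           cal: BusinessCalendar = BusinessCalendar()) -> float:
    """Wall hours from ``start`` to ``end`` minus weekend/holiday hours (Eastern)."""
    if start.tzinfo is None or end.tzinfo is None:
        raise ValueError("timestamps must carry a zone offset")
    start = start.astimezone(EASTERN)
    end = end.astimezone(EASTERN)
    if end < start:
        raise ValueError("end precedes start after conversion to Eastern time")
    total = (end - start).total_seconds()
    excluded = 0.0
    d = start.date()
    while d <= end.date():
        if cal.is_excluded(d):
            lo, hi = _day_bounds(d)
            overlap = (min(end, hi) - max(start, lo)).total_seconds()
            if overlap > 0:
                excluded += overlap
        d += timedelta(days=1)
    return (total - excluded) / 3600.0


def add_business_hours(start: datetime, hours: float,
                       cal: BusinessCalendar = BusinessCalendar()) -> datetime:
    """Earliest timestamp ``end`` with ``elapsed_business_hours(start, end) == hours``."""
    if hours < 0:
        raise ValueError("hours must be non-negative")
    cur = start.astimezone(EASTERN)
    remaining = hours * 3600.0
    while True:
        if cal.is_excluded(cur.date()):
            cur = _day_bounds(cur.date())[1]
            continue
        day_end = _day_bounds(cur.date())[1]
        avail = (day_end - cur).total_seconds()
        if remaining <= avail:
            return cur + timedelta(seconds=remaining)
        remaining -= avail
        cur = day_end


def hours_to_days(hours: float) -> float:
    """Hour count expressed in 24-hour days, rounded to 2 decimals (91 h -> 3.79)."""
    if hours < 0:
        raise ValueError("hours must be non-negative")
    return round(hours / 24.0, 2)


def check_deadline(business_hours: float, threshold: float = 168.0) -> bool:
    """Whether a case met the prospective deadline (<= 168 business hours = 7 days)."""
    if business_hours < 0:
        raise ValueError("hours must be non-negative")
    return business_hours <= threshold


@dataclass
class TurnaroundSummary:
    per_cohort: dict[str, dict]   # cohort -> {n, business_hours, business_days, total_hours}
    all_cases: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, s in self.per_cohort.items():
            rows.append({"cohort": cohort, **s})
        rows.append({"cohort": "All Cases", **self.all_cases})
        return pd.DataFrame(rows)


def summarize_cohorts(cases: Sequence[tuple[str, float, float]]) -> TurnaroundSummary:
    """Cohort means and the case-weighted all-cases row.

    ``cases`` holds (cohort label, business hours, total wall hours) per
    case.  The all-cases mean is weighted by cohort size, i.e. it is the
    plain mean over cases.  Reported values are rounded to 2 decimals.
    """
    if not cases:
        raise ValueError("summarize_cohorts requires at least one case")
    df = pd.DataFrame(cases, columns=["cohort", "business_hours", "total_hours"])
    per_cohort: dict[str, dict] = {}
    for cohort, grp in df.groupby("cohort", sort=False):
        bh = float(grp["business_hours"].mean())
        per_cohort[cohort] = {
            "n": int(len(grp)),
            "business_hours": round(bh, 2),
            "business_days": hours_to_days(bh),
            "total_hours": round(float(grp["total_hours"].mean()), 2),
        }
    bh_all = float(df["business_hours"].mean())
    all_cases = {
        "n": int(len(df)),
        "business_hours": round(bh_all, 2),
        "business_days": hours_to_days(bh_all),
        "total_hours": round(float(df["total_hours"].mean()), 2),
    }
    return TurnaroundSummary(per_cohort, all_cases)


def log_business_hours(log: EventLog, cal: BusinessCalendar = BusinessCalendar(),
                       start_label: str | None = None,
                       end_label: str | None = None) -> float:
    start, end = log.span(start_label, end_label)
    return elapsed_business_hours(start, end, cal)


def read_event_logs(path) -> list[EventLog]:
    """Read event logs from CSV columns (sample_id, cohort, event, timestamp ISO-8601)."""
    df = pd.read_csv(path)
    logs = []
    for (sid, cohort), grp in df.groupby(["sample_id", "cohort"], sort=False):
        events = [(row.event, datetime.fromisoformat(row.timestamp))
                  for row in grp.itertuples()]
        logs.append(EventLog(str(sid), str(cohort), events))
    return logs


def write_event_logs(logs: Iterable[EventLog], path) -> None:
    rows = [
        {"sample_id": lg.sample_id, "cohort": lg.cohort,
         "event": label, "timestamp": ts.isoformat()}
        for lg in logs for label, ts in lg.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
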