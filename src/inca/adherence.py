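"""Adherence series and the weekly cumulative-dose regression slope.

Temporal adherence asks only whether the prescribed number of doses
(2/day by default) was taken each day; combined adherence additionally
requires correct technique, counting technique errors the same as missed
doses. For each 7-day week the cumulative number of credited doses is
regressed on the day index; the slope (r·s_y/s_x, identical to ordinary
least squares) is the weekly adherence rate, with slope = 2 meaning
perfect adherence for a twice-daily prescription.

Daily temporal credit is capped at the prescription so excessive use
cannot inflate adherence; excess doses are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .technique import TechniqueLabel

__all__ = [
    "DoseLog",
    "adherence_slope",
    "weekly_series",
    "temporal_series",
    "combined_series",
    "overall_adherence",
    "read_dose_logs",
    "write_dose_logs",
]


def _label_value(label) -> str:
    return label.value if isinstance(label, TechniqueLabel) else str(label)


@dataclass
class DoseLog:
    """Per-subject history of dose attempts.

    ``events`` is an ordered list of ``(timestamp, label)`` pairs, where
    the label is a :class:`~inca.technique.TechniqueLabel` or its string
    value.
    """

    subject_id: str
    events: list[tuple[datetime, TechniqueLabel | str]] = field(default_factory=list)
    prescribed_per_day: int = 2

    def __post_init__(self) -> None:
        if self.prescribed_per_day < 1:
            raise ValueError("prescribed_per_day must be >= 1")
        self.events = sorted(self.events, key=lambda e: e[0])

    def __len__(self) -> int:
        return len(self.events)

    @property
    def start_date(self) -> date | None:
        return self.events[0][0].date() if self.events else None

    @property
    def end_date(self) -> date | None:
        return self.events[-1][0].date() if self.events else None

    def daily_counts(
        self, start: date, n_days: int
    ) -> pd.DataFrame:
        """Per-day taken/correct counts over ``n_days`` from ``start``.

        Returns a frame indexed 0..n_days-1 with columns ``n_taken``,
        ``n_correct``, and the capped credits ``credit_temporal`` /
        ``credit_combined`` (each at most ``prescribed_per_day``) plus
        ``n_excess`` (doses beyond the prescription that day).
        """
        taken = np.zeros(n_days, dtype=int)
        correct = np.zeros(n_days, dtype=int)
        for ts, label in self.events:
            d = (ts.date() - start).days
            if 0 <= d < n_days:
                taken[d] += 1
                if _label_value(label) == "correct":
                    correct[d] += 1
        cap = self.prescribed_per_day
        return pd.DataFrame(
            {
                "n_taken": taken,
                "n_correct": correct,
                "credit_temporal": np.minimum(taken, cap),
                "credit_combined": np.minimum(correct, cap),
                "n_excess": np.maximum(taken - cap, 0),
            }
        )


def adherence_slope(daily_counts: Sequence[float]) -> float:
    """Slope of cumulative credited doses regressed on the day index.

    Computed as r·s_y/s_x — algebraically the ordinary-least-squares
    slope of cumulative doses (Y) on day number (X). A window with no
    credited doses returns 0 (the correlation is undefined when s_y = 0,
    and a flat cumulative curve is zero adherence). Requires >= 2 days.
    """
    y = np.cumsum(np.asarray(daily_counts, dtype=float))
    if y.size < 2:
        raise ValueError("need a window of at least 2 days")
    if y[-1] == 0:
        return 0.0
    x = np.arange(1, y.size + 1, dtype=float)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * sy / sx)


def weekly_series(
    log: DoseLog,
    start: date | None = None,
    weeks: int | None = None,
) -> pd.DataFrame:
    """Weekly temporal and combined adherence rates for one subject.

    Weeks are consecutive 7-day blocks from ``start`` (default: the date
    of the first event); a trailing partial week is excluded. For an
    empty log an explicit observation window (``start`` and ``weeks``)
    is required and yields all-zero slopes.

    Returns columns ``week, n_taken, n_correct, n_excess, temporal_slope,
    combined_slope, error_fraction``.
    """
    if start is None:
        start = log.start_date
    if start is None:
        if weeks is None:
            raise ValueError("empty log: an explicit start and weeks are required")
    if weeks is None:
        span = (log.end_date - start).days + 1
        weeks = span // 7
    if weeks < 1:
        raise ValueError("log must span at least one full 7-day week")
    if start is None:
        raise ValueError("weeks given without a start date for an empty log")

    daily = log.daily_counts(start, weeks * 7)
    rows = []
    for w in range(weeks):
        block = daily.iloc[w * 7 : (w + 1) * 7]
        n_taken = int(block["n_taken"].sum())
        n_correct = int(block["n_correct"].sum())
        rows.append(
            {
                "week": w,
                "n_taken": n_taken,
                "n_correct": n_correct,
                "n_excess": int(block["n_excess"].sum()),
                "temporal_slope": adherence_slope(block["credit_temporal"]),
                "combined_slope": adherence_slope(block["credit_combined"]),
                "error_fraction": (n_taken - n_correct) / n_taken if n_taken else 0.0,
            }
        )
    return pd.DataFrame(rows)


def temporal_series(log: DoseLog, **kwargs) -> pd.DataFrame:
    """Weekly series using time-of-use only (see :func:`weekly_series`)."""
    return weekly_series(log, **kwargs)


def combined_series(log: DoseLog, **kwargs) -> pd.DataFrame:
    """Weekly series crediting only technique-correct doses."""
    return weekly_series(log, **kwargs)


def overall_adherence(
    log: DoseLog,
    domain: str = "temporal",
    start: date | None = None,
    days: int | None = None,
) -> float:
    """Percentage of prescribed doses credited over the observation window.

    The window defaults to first-through-last event date (inclusive).
    ``domain`` is ``"temporal"`` (any dose taken, capped at the daily
    prescription) or ``"combined"`` (correct doses only).
    """
    if domain not in ("temporal", "combined"):
        raise ValueError(f"unknown adherence domain: {domain!r}")
    if start is None:
        start = log.start_date
    if days is None:
        if start is None or log.end_date is None:
            raise ValueError("empty log: an explicit window is required")
        days = (log.end_date - start).days + 1
    if days < 1 or start is None:
        raise ValueError("observation window must cover at least one day")
    daily = log.daily_counts(start, days)
    credited = daily[f"credit_{domain}"].sum()
    prescribed = days * log.prescribed_per_day
    return 100.0 * float(credited) / prescribed


def write_dose_logs(logs: Iterable[DoseLog], path: str | Path) -> Path:
    """Write dose logs as CSV with columns subject_id,timestamp,label."""
    rows = [
        {
            "subject_id": log.subject_id,
            "timestamp": ts.isoformat(),
            "label": _label_value(label),
        }
        for log in logs
        for ts, label in log.events
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "timestamp", "label"]).to_csv(
        path, index=False
    )
    return path


def read_dose_logs(path: str | Path, prescribed_per_day: int = 2) -> list[DoseLog]:
    """Read per-subject dose logs from a subject_id,timestamp,label CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    logs = []
    for sid, grp in df.groupby("subject_id", sort=True):
        events = [
            (datetime.fromisoformat(str(ts)), TechniqueLabel.of(str(lb)))
            for ts, lb in zip(grp["timestamp"], grp["label"])
        ]
        logs.append(DoseLog(subject_id=str(sid), events=events,
                            prescribed_per_day=prescribed_per_day))
    return logs
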