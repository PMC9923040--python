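"""Merging device sessions into person-days and workday calendar grids.

The unit of analysis is the *person-day*: all runs of one worker's
monitor on one calendar date, merged.  Day-to-day autocorrelation is
computed on calendar grids of workdays (Mon-Fri, public holidays
excluded, vacation days included) under three imputation schemes that
differ in how unmeasured and non-detect days are treated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .instrument_io import SessionLog

SCHEMES = ("calendar_zero", "detected_zero", "detected_only")


@dataclass
class PersonDay:
    """All sessions of one worker on one calendar date."""

    person_id: str
    seg: str
    date: date
    sessions: list[SessionLog]

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.sessions)

    @property
    def duration_min(self) -> float:
        """Measured duration: reading count x 15 s, in minutes."""
        return sum(s.duration_s for s in self.sessions) / 60.0


def measured_duration(day: PersonDay) -> float:
    """Measured duration of a person-day in minutes (reading count x 0.25)."""
    return day.duration_min


def assemble_person_days(sessions: Iterable[SessionLog]) -> list[PersonDay]:
    """Group sessions into person-days.

    A session belongs wholly to the calendar date of its start (device
    runs are at most 16 h, so a run spans at most one midnight and is not
    split).  Sessions with zero readings are skipped with a warning.
    Output is sorted by person then date.
    """
    groups: dict[tuple[str, date], PersonDay] = {}
    for s in sessions:
        if s.n_samples == 0:
            warnings.warn(
                f"skipping empty session for {s.person_id} at {s.start.isoformat()}",
                stacklevel=2,
            )
            continue
        key = (s.person_id, s.start.date())
        day = groups.get(key)
        if day is None:
            groups[key] = PersonDay(s.person_id, s.seg, s.start.date(), [s])
        else:
            if s.seg != day.seg:
                raise ValueError(f"conflicting SEG labels for person {s.person_id}")
            day.sessions.append(s)
    for day in groups.values():
        day.sessions.sort(key=lambda s: s.start)
    return [groups[k] for k in sorted(groups)]


@dataclass
class WorkdayGrid:
    """Per-person ordered day series with an imputation scheme applied.

    ``frame`` columns: person_id, date, value, status; ``status`` is
    ``measured`` for days with readings and ``imputed_zero`` for workdays
    filled in with 0.
    """

    scheme: str
    value_field: str
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def _workdays(start: date, end: date, holidays: frozenset[date]) -> list[date]:
    days = []
    d = start
    while d <= end:
        if d.weekday() < 5 and d not in holidays:
            days.append(d)
        d += timedelta(days=1)
    return days


def build_workday_grid(
    days,
    period: tuple[date, date] | None = None,
    holidays: Sequence[date] = (),
    scheme: str = "calendar_zero",
    value_field: str = "max_level",
) -> WorkdayGrid:
    """Build the day-series grid used for lag-1 autocorrelation.

    ``days`` is a DataFrame (or list of objects) with per-day fields
    ``person_id``, ``date``, ``above_lod`` and the chosen value column.

    Schemes:

    * ``calendar_zero`` - every workday in each person's measured span
      (or in ``period`` when given) is present; unmeasured workdays are
      imputed with 0.  Measured days falling on weekends/holidays are
      kept as well.
    * ``detected_zero`` - only measured days; days without detectable
      readings carry value 0.
    * ``detected_only`` - only days with readings above the LOD.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if period is not None and period[0] > period[1]:
        raise ValueError("reversed period")

    if not isinstance(days, pd.DataFrame):
        days = pd.DataFrame(
            {
                "person_id": [d.person_id for d in days],
                "date": [d.date for d in days],
                "above_lod": [d.above_lod for d in days],
                value_field: [getattr(d, value_field) for d in days],
            }
        )
    frame = days.loc[:, ["person_id", "date", "above_lod", value_field]].copy()
    frame = frame.rename(columns={value_field: "value"})
    if frame.duplicated(["person_id", "date"]).any():
        raise ValueError("duplicate person-day rows")

    if scheme == "detected_only":
        out = frame.loc[frame["above_lod"], ["person_id", "date", "value"]].copy()
        out["status"] = "measured"
    elif scheme == "detected_zero":
        out = frame[["person_id", "date", "value"]].copy()
        out.loc[~frame["above_lod"].to_numpy(), "value"] = 0.0
        out["status"] = "measured"
    else:  # calendar_zero
        hol = frozenset(holidays)
        pieces = []
        for person, g in frame.groupby("person_id", sort=True):
            lo, hi = g["date"].min(), g["date"].max()
            if period is not None:
                lo, hi = period
            grid_dates = set(_workdays(lo, hi, hol)) | set(g["date"])
            piece = pd.DataFrame({"person_id": person, "date": sorted(grid_dates)})
            piece = piece.merge(g[["date", "value"]], on="date", how="left")
            piece["status"] = np.where(piece["value"].isna(), "imputed_zero", "measured")
            piece["value"] = piece["value"].fillna(0.0)
            pieces.append(piece)
        out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
            columns=["person_id", "date", "value", "status"]
        )
    out = out.sort_values(["person_id", "date"]).reset_index(drop=True)
    return WorkdayGrid(scheme=scheme, value_field=value_field, frame=out)
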