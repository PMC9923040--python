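"""Daily exposure metrics: TWA, rolling STEL, peak detection, exceedance flags.

All metrics are computed on the coded 15-s series of a person-day with the
censoring conventions made explicit:

* below-LOD readings (coded 0.0) contribute a configurable substitution
  value (default 0) to averages;
* overload readings contribute their recorded code 101 - they are never
  clipped, so TWA/STEL on overload days are themselves lower bounds;
* the 8-h TWA uses a fixed 480-min basis by default (readings are treated
  as interval means over their 15 s), with the measured duration available
  as an alternative basis;
* 15-min STEL windows are confined within sessions, mirroring a device
  that restarts its running averages at every power-on;
* a peak is a maximal contiguous run of readings at or above the LOD;
  runs separated by at most ``gap_merge`` below-LOD samples can be merged,
  with the gap counting toward the peak duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .day_assembly import PersonDay

_EPS = 1e-9


@dataclass(frozen=True)
class Thresholds:
    """Regulatory limits and instrument constants, all in ppm/minutes.

    Defaults are the Norwegian H2S limits: 8-h OEL 5 ppm, ceiling value
    (CV) 10 ppm, action level 1/10 OEL, 15-min STEL window, LOD 1.6 ppm.
    """

    oel_twa: float = 5.0
    cv: float = 10.0
    oel_tenth: float = 0.5
    stel_window: float = 15.0
    twa_basis: float = 480.0
    lod: float = 1.6

    def __post_init__(self) -> None:
        vals = (self.oel_twa, self.cv, self.oel_tenth, self.stel_window, self.twa_basis, self.lod)
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if abs(self.oel_tenth - self.oel_twa / 10) > _EPS:
            raise ValueError("oel_tenth must equal oel_twa / 10")


BANDS = ("low", "mid", "high")


def band_peak(height: float, th: Thresholds = Thresholds()) -> str:
    """Band a peak height: low <= 5.0 < mid <= 10.0 < high (ppm).

    At the 0.1 ppm instrument resolution the bands low / 5.1-10.0 / >10.0
    are exhaustive.  Heights below the LOD are not peaks.
    """
    if height < th.lod - _EPS:
        raise ValueError(f"peak height {height} below LOD {th.lod}")
    if height <= th.oel_twa + _EPS:
        return "low"
    if height <= th.cv + _EPS:
        return "mid"
    return "high"


@dataclass(frozen=True)
class Peak:
    """One above-LOD excursion: start, duration, max height, band."""

    t_start: datetime
    duration_s: float
    height: float
    band: str
    right_censored: bool


@dataclass
class DayMetrics:
    """All daily exposure measures of one person-day."""

    person_id: str
    seg: str
    date: date
    duration_min: float
    twa: float
    stel_max: float
    max_level: float
    peaks: list[Peak] = field(default_factory=list)
    n_peaks: int = 0
    above_lod: bool = False
    above_cv: bool = False
    twa_gt_oel: bool = False
    twa_gt_tenth_oel: bool = False


def _sub_values(v: np.ndarray, lod: float, substitution: float) -> np.ndarray:
    if substitution == 0:
        return v
    return np.where(v < lod, substitution, v)


def compute_twa(
    day: PersonDay,
    th: Thresholds = Thresholds(),
    substitution: float = 0.0,
    basis: str = "fixed",
) -> float:
    """8-h time-weighted average of a person-day in ppm.

    Each 15-s reading is treated as the mean over its interval.  With
    ``basis="fixed"`` the denominator is the 480-min reference period
    regardless of measured duration; ``basis="measured"`` divides by the
    summed session time instead.  Below-LOD readings contribute
    ``substitution`` (0, LOD/2, LOD/sqrt(2), ...); overloads contribute
    their code 101.  An empty day has TWA 0.
    """
    dose = 0.0
    total_s = 0.0
    for s in day.sessions:
        v = _sub_values(s.values, th.lod, substitution)
        dose += float(v.sum()) * s.device.sampling_interval
        total_s += s.duration_s
    if basis == "fixed":
        denom = th.twa_basis * 60.0
    elif basis == "measured":
        denom = total_s
    else:
        raise ValueError(f"unknown TWA basis {basis!r}")
    return dose / denom if denom > 0 else 0.0


def rolling_stel_max(
    day: PersonDay, th: Thresholds = Thresholds(), substitution: float = 0.0
) -> float:
    """Maximum 15-min rolling mean over the day, windows confined to sessions.

    Sessions shorter than the window use the mean over their available
    samples.  An empty day returns 0.
    """
    best = 0.0
    for s in day.sessions:
        v = _sub_values(s.values, th.lod, substitution)
        if v.size == 0:
            continue
        w = int(round(th.stel_window * 60.0 / s.device.sampling_interval))
        if v.size <= w:
            best = max(best, float(v.mean()))
        else:
            csum = np.concatenate([[0.0], np.cumsum(v)])
            means = (csum[w:] - csum[:-w]) / w
            best = max(best, float(means.max()))
    return best


def _runs_at_or_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, mask.size]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if mask[a]]


def detect_peaks(
    day: PersonDay, th: Thresholds = Thresholds(), gap_merge: int = 0
) -> list[Peak]:
    """Find above-LOD peaks in each session of a person-day.

    A peak is a maximal contiguous run of readings >= LOD; runs separated
    by at most ``gap_merge`` below-LOD samples are merged, the gap samples
    counting toward the duration.  Height is the run maximum; a height at
    the overload code marks the peak right-censored.
    """
    if gap_merge < 0:
        raise ValueError("gap_merge must be >= 0")
    peaks: list[Peak] = []
    for s in day.sessions:
        v = s.values
        runs = _runs_at_or_above(v >= th.lod)
        merged: list[tuple[int, int]] = []
        for a, b in runs:
            if merged and a - merged[-1][1] <= gap_merge:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        step = s.device.sampling_interval
        for a, b in merged:
            height = float(v[a:b].max())
            peaks.append(
                Peak(
                    t_start=s.start + a * s.device.step,
                    duration_s=(b - a) * step,
                    height=height,
                    band=band_peak(height, th),
                    right_censored=height >= s.device.overload_code,
                )
            )
    return peaks


def flag_day(
    day: PersonDay,
    th: Thresholds = Thresholds(),
    substitution: float = 0.0,
    gap_merge: int = 0,
    basis: str = "fixed",
) -> DayMetrics:
    """Compute the full :class:`DayMetrics` record for one person-day.

    Flags follow the instrument's reporting conventions: a day is above
    the CV only when its maximum strictly exceeds 10.0 ppm (i.e. is at
    least 10.1 at device resolution); TWA flags use strict inequalities.
    """
    max_level = 0.0
    for s in day.sessions:
        if s.n_samples:
            max_level = max(max_level, float(s.values.max()))
    twa = compute_twa(day, th, substitution=substitution, basis=basis)
    peaks = detect_peaks(day, th, gap_merge=gap_merge)
    return DayMetrics(
        person_id=day.person_id,
        seg=day.seg,
        date=day.date,
        duration_min=day.duration_min,
        twa=twa,
        stel_max=rolling_stel_max(day, th, substitution=substitution),
        max_level=max_level,
        peaks=peaks,
        n_peaks=len(peaks),
        above_lod=max_level >= th.lod - _EPS,
        above_cv=max_level > th.cv + _EPS,
        twa_gt_oel=twa > th.oel_twa + _EPS,
        twa_gt_tenth_oel=twa > th.oel_tenth + _EPS,
    )


def compute_day_metrics(
    days: Iterable[PersonDay], th: Thresholds = Thresholds(), **kwargs
) -> list[DayMetrics]:
    return [flag_day(d, th, **kwargs) for d in days]


def metrics_frame(metrics: Sequence[DayMetrics]) -> pd.DataFrame:
    """Tabulate DayMetrics, one row per person-day."""
    return pd.DataFrame(
        {
            "person_id": [m.person_id for m in metrics],
            "seg": [m.seg for m in metrics],
            "date": [m.date for m in metrics],
            "duration_min": [m.duration_min for m in metrics],
            "twa": [m.twa for m in metrics],
            "stel_max": [m.stel_max for m in metrics],
            "max_level": [m.max_level for m in metrics],
            "n_peaks": [m.n_peaks for m in metrics],
            "above_lod": [m.above_lod for m in metrics],
            "above_cv": [m.above_cv for m in metrics],
            "twa_gt_oel": [m.twa_gt_oel for m in metrics],
            "twa_gt_tenth_oel": [m.twa_gt_tenth_oel for m in metrics],
        }
    )


def peaks_frame(metrics: Sequence[DayMetrics]) -> pd.DataFrame:
    """Side table with one row per detected peak."""
    rows = [
        (m.person_id, m.seg, m.date, p.t_start, p.duration_s, p.height, p.band, p.right_censored)
        for m in metrics
        for p in m.peaks
    ]
    return pd.DataFrame(
        rows,
        columns=["person_id", "seg", "date", "t_start", "duration_s", "height", "band", "right_censored"],
    )
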