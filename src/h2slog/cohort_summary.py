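"""Cohort-level summary tables over day metrics.

Reproduces the structure of the study-style outputs: a per-SEG
descriptive table (counts and integer percentages of days above LOD /
above the ceiling value, measured durations), central tendencies of TWA
and maximum level on detected days, per-band peak-count summaries, the
day-maximum histogram with a bin edge at the ceiling value, and
log-log OLS fits of day maximum against TWA.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure_metrics import BANDS, DayMetrics, Thresholds, metrics_frame
from .instrument_io import SEGS

TOTAL = "total"


def percent(numerator, denominator, decimals: int = 0):
    """``100 * numerator / denominator`` rounded half away from zero.

    Returns an int for ``decimals=0`` (the convention of printed summary
    tables), a float otherwise, and ``None`` for a zero denominator.
    """
    if denominator == 0:
        return None
    q = Decimal(str(numerator)) / Decimal(str(denominator)) * 100
    out = q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    return int(out) if decimals == 0 else float(out)


def _as_frame(days) -> pd.DataFrame:
    if isinstance(days, pd.DataFrame):
        return days
    return metrics_frame(days)


def _check_segs(frame: pd.DataFrame) -> None:
    unknown = set(frame["seg"]) - set(SEGS)
    if unknown:
        raise ValueError(f"unknown SEG label(s): {sorted(unknown)}")


def seg_summary_table(days) -> pd.DataFrame:
    """Descriptive per-SEG table plus a pooled total row.

    Columns: person and day counts, per-person day-count range, days
    above LOD, days with TWA > 1/10 OEL, days above the CV (with integer
    percentages, overall and conditional on detection), and mean/median
    measured duration in minutes.
    """
    frame = _as_frame(days)
    _check_segs(frame)
    rows = []
    for seg in (*SEGS, TOTAL):
        g = frame if seg == TOTAL else frame[frame["seg"] == seg]
        n_days = len(g)
        per_person = g.groupby("person_id").size() if n_days else pd.Series(dtype=int)
        n_lod = int(g["above_lod"].sum()) if n_days else 0
        n_cv = int(g["above_cv"].sum()) if n_days else 0
        rows.append(
            {
                "seg": seg,
                "n_persons": int(g["person_id"].nunique()) if n_days else 0,
                "n_days": n_days,
                "days_per_person_min": int(per_person.min()) if n_days else 0,
                "days_per_person_max": int(per_person.max()) if n_days else 0,
                "n_above_lod": n_lod,
                "pct_above_lod": percent(n_lod, n_days),
                "n_twa_gt_tenth": int(g["twa_gt_tenth_oel"].sum()) if n_days else 0,
                "n_above_cv": n_cv,
                "pct_above_cv": percent(n_cv, n_days),
                "pct_above_cv_given_lod": percent(n_cv, n_lod),
                "mean_duration": float(g["duration_min"].mean()) if n_days else 0.0,
                "median_duration": float(g["duration_min"].median()) if n_days else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("seg")


def day_max_histogram(
    days,
    bin_width: float = 0.5,
    cv_boundary: bool = True,
    th: Thresholds = Thresholds(),
    overload_code: float = 101.0,
) -> pd.DataFrame:
    """Histogram of daily maximum levels over detected days.

    Accepts DayMetrics (restricted to days above LOD) or a plain array of
    above-LOD values.  Right-censored values (the overload code) are
    pooled into the terminal bin.  With ``cv_boundary`` one bin edge sits
    exactly between 10.0 and 10.1 ppm so that the first bin past it
    contains only CV exceedances.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(days, (np.ndarray, pd.Series)) or (
        isinstance(days, (list, tuple)) and (not days or np.isscalar(days[0]))
    ):
        values = np.asarray(days, dtype=float)
    else:
        frame = _as_frame(days)
        values = frame.loc[frame["above_lod"], "max_level"].to_numpy(dtype=float)
    if values.size and values.min() < th.lod:
        raise ValueError("histogram input must be restricted to above-LOD values")

    half_res = 0.05  # half the 0.1 ppm instrument resolution
    anchor = th.cv + half_res if cv_boundary else th.lod - half_res
    lo_edge = anchor - bin_width * np.ceil((anchor - (th.lod - half_res)) / bin_width - 1e-12)
    hi_target = 100.0 + half_res
    n_bins = int(np.ceil((hi_target - lo_edge) / bin_width - 1e-12))
    edges = lo_edge + bin_width * np.arange(n_bins + 1)

    censored = values >= overload_code
    counts, _ = np.histogram(values[~censored], bins=edges)
    counts[-1] += int(censored.sum())
    return pd.DataFrame({"left": edges[:-1], "right": edges[1:], "count": counts})


def tendency_table(days, overload_ppm: float = 100.0) -> pd.DataFrame:
    """Central tendencies of TWA and maximum level on days above LOD.

    Mode of TWA is taken after rounding to 0.01 ppm (ties broken toward
    the smaller value); a mode or median below 0.01 is displayed as
    "<0.01".  The maximum level is rendered ">100" on right-censored days.
    """
    frame = _as_frame(days)
    _check_segs(frame)
    det = frame[frame["above_lod"]]
    rows = []
    for seg in (*SEGS, TOTAL):
        g = det if seg == TOTAL else det[det["seg"] == seg]
        pos = g.loc[g["twa"] > 0, "twa"]
        if len(g) == 0:
            rows.append({"seg": seg, "n_days": 0, "max_twa": np.nan, "median_twa_pos": np.nan,
                         "mode_twa_pos": np.nan, "mode_twa_n": 0, "max_level": np.nan,
                         "max_level_display": ""})
            continue
        rounded = pos.round(2)
        if len(rounded):
            counts = rounded.value_counts()
            top = counts.max()
            mode_val = float(min(counts[counts == top].index))
            mode_n = int(top)
        else:
            mode_val, mode_n = np.nan, 0
        max_level = float(g["max_level"].max())
        rows.append(
            {
                "seg": seg,
                "n_days": len(g),
                "max_twa": float(g["twa"].max()),
                "median_twa_pos": float(pos.median()) if len(pos) else np.nan,
                "mode_twa_pos": mode_val,
                "mode_twa_n": mode_n,
                "max_level": max_level,
                "max_level_display": f">{overload_ppm:g}" if max_level > overload_ppm
                else f"{max_level:g}",
            }
        )
    return pd.DataFrame(rows).set_index("seg")


def peak_count_table(days) -> pd.DataFrame:
    """Max and median per-day peak counts, per height band and overall.

    Counts are per person-day over days above the LOD; a day's all-band
    count is the sum of its band counts.  The per-SEG maximum is the
    largest per-day count observed for any worker of the SEG.
    """
    metrics: Sequence[DayMetrics] = list(days)
    rows_per_day = []
    for m in metrics:
        if not m.above_lod:
            continue
        counts = {b: 0 for b in BANDS}
        for p in m.peaks:
            counts[p.band] += 1
        rows_per_day.append({"seg": m.seg, **counts, "all": m.n_peaks})
    per_day = pd.DataFrame(rows_per_day, columns=["seg", *BANDS, "all"])
    _check_segs(per_day) if len(per_day) else None
    rows = []
    for seg in (*SEGS, TOTAL):
        g = per_day if seg == TOTAL else per_day[per_day["seg"] == seg]
        row = {"seg": seg, "n_days": len(g)}
        for b in (*BANDS, "all"):
            row[f"{b}_max"] = int(g[b].max()) if len(g) else 0
            row[f"{b}_median"] = float(g[b].median()) if len(g) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("seg")


@dataclass(frozen=True)
class FitResult:
    """OLS fit of day maximum on TWA for one SEG (or pooled)."""

    seg: str
    n: int
    r_squared: float
    slope: float
    intercept: float


def max_twa_fit(days, seg: str | None = None, log_scale: bool = True) -> FitResult:
    """OLS of (log10) day maximum on (log10) TWA over detected days.

    Requires at least 3 days with positive TWA (for the log transform).
    The log-log scale is the default since both quantities span orders of
    magnitude; a linear-scale fit is available via ``log_scale=False``.
    """
    frame = _as_frame(days)
    if seg is not None:
        frame = frame[frame["seg"] == seg]
    sel = frame[frame["above_lod"] & (frame["twa"] > 0)]
    if len(sel) < 3:
        raise ValueError("need at least 3 detected days with positive TWA")
    x = sel["twa"].to_numpy(dtype=float)
    y = sel["max_level"].to_numpy(dtype=float)
    if log_scale:
        x, y = np.log10(x), np.log10(y)
    fit = stats.linregress(x, y)
    return FitResult(
        seg=seg or TOTAL,
        n=len(sel),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def max_twa_fits(days, log_scale: bool = True) -> list[FitResult]:
    """Per-SEG fits, skipping SEGs with too few points."""
    out = []
    for seg in SEGS:
        try:
            out.append(max_twa_fit(days, seg=seg, log_scale=log_scale))
        except ValueError:
            continue
    return out
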