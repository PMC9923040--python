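"""Synthetic instrument-log cohorts with recorded ground truth.

The generator emulates the statistical structure the day-level analysis
assumes: per-worker Mon-Fri workday calendars, a SEG-dependent
probability that a day carries any detectable H2S (with worker-level
heterogeneity around the SEG mean), about one short peak per detected
day with an overdispersed count, heavy-tailed peak heights truncated at
the LOD and right-censored at the instrument range, measured durations
from minutes up to 16 h split over one or two device runs, and the
docking station's zero-compression.  Every emitted day is paired with a
ground-truth record so parameter-recovery tests can compare pipeline
estimates against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .instrument_io import (
    SEGS,
    DeviceMeta,
    ReadingBlock,
    SessionLog,
    compress_zero_runs,
    write_canonical_log,
)

# the dock-transfer compression is exactly the zero-run elision inverse
compress_like_dock = compress_zero_runs


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a cohort.

    Defaults mirror the study conditions: 23/15/6/15 workers per SEG,
    detectable-day probabilities of 18/21/23/5% per SEG, about one third
    of detected days exceeding the 10 ppm ceiling value, a median of one
    peak per detected day with a long-tailed count, lognormal peak
    heights above the 1.6 ppm LOD, and median measured duration near
    293 min (mean ~342).  120 workdays per worker yield a cohort of
    roughly 7100 person-days.
    """

    n_workers: Mapping[str, int] = field(
        default_factory=lambda: {
            "sewerage_net": 23, "plant": 15, "pumping_station": 6, "water_net": 15,
        }
    )
    p_detect_day: Mapping[str, float] = field(
        default_factory=lambda: {
            "sewerage_net": 0.18, "plant": 0.21, "pumping_station": 0.23, "water_net": 0.05,
        }
    )
    p_cv_given_detect: float = 1.0 / 3.0
    start: date = date(2019, 1, 1)
    n_workdays: int = 120
    holidays: tuple = ()
    worker_sd_logit: float = 0.8
    peak_extra_r: float = 0.35      # extra peaks ~ NegBinom(r, p); count = 1 + extra
    peak_extra_p: float = 0.45
    height_log_mu: float = 1.0      # log(height/LOD) ~ Normal(mu, sigma) truncated >= 0
    height_log_sigma: float = 1.3
    peak_len_p: float = 0.3         # peak length in 15-s samples ~ Geometric(p)
    duration_median_min: float = 293.0
    duration_log_sigma: float = 0.556
    p_two_sessions: float = 0.3
    peak_shape: str = "plateau"     # or "triangle"
    compression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in self.n_workers:
            if seg not in SEGS:
                raise ValueError(f"unknown SEG {seg!r}")
        probs = [*self.p_detect_day.values(), self.p_cv_given_detect,
                 self.p_two_sessions]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_workdays < 1:
            raise ValueError("n_workdays must be >= 1")
        if self.peak_shape not in ("plateau", "triangle"):
            raise ValueError("peak_shape must be 'plateau' or 'triangle'")


def workday_calendar(start: date, n_workdays: int, holidays: Sequence[date] = ()) -> list[date]:
    """First ``n_workdays`` Mon-Fri non-holiday dates from ``start``."""
    hol = frozenset(holidays)
    out: list[date] = []
    d = start
    while len(out) < n_workdays:
        if d.weekday() < 5 and d not in hol:
            out.append(d)
        d += timedelta(days=1)
    return out


def _worker_probs(rng: np.random.Generator, p: float, n: int, sd: float) -> np.ndarray:
    """Worker detection probabilities with mean pinned at the SEG value."""
    if p <= 0.0 or sd == 0.0 or n == 1:
        return np.full(n, p)
    logit = math.log(p / (1 - p))
    probs = 1.0 / (1.0 + np.exp(-(logit + sd * rng.standard_normal(n))))
    for _ in range(4):  # rescale-and-clip to pin the mean despite Jensen shift
        probs = np.clip(probs * (p / probs.mean()), 1e-4, 0.999)
    return probs


def _heights(
    rng: np.random.Generator, cfg: SyntheticConfig, n: int, region: str, device: DeviceMeta
) -> np.ndarray:
    """Peak heights in raw ppm from the truncated lognormal, by region.

    ``region`` selects the support of log(h/LOD): "any" >= 0, "low"
    capped so the coded height stays <= the CV, "high" beyond it.
    """
    mu, sig = cfg.height_log_mu, cfg.height_log_sigma
    cut = math.log((10.0 + device.resolution / 2) / device.lod)  # codes to > 10.0 above
    lo, hi = {"any": (0.0, np.inf), "low": (0.0, cut), "high": (cut, np.inf)}[region]
    x = truncnorm.rvs((lo - mu) / sig, (hi - mu) / sig, loc=mu, scale=sig,
                      size=n, random_state=rng)
    return device.lod * np.exp(x)


def _peak_values(height: float, length: int, shape: str, device: DeviceMeta) -> np.ndarray:
    if shape == "plateau" or length <= 2:
        raw = np.full(length, height)
    else:
        up = np.linspace(device.lod, height, (length + 1) // 2)
        down = up[::-1]
        raw = np.concatenate([up, down[1:]] if length % 2 else [up, down])[:length]
        raw[np.argmax(raw)] = height
    return device.code_values(raw)


def _place_runs(
    rng: np.random.Generator, capacity: int, lens: list[int], keep_first: bool
) -> tuple[list[int], list[int]]:
    """Fit run lengths into ``capacity`` samples with >= 1 zero between runs.

    Returns (kept indices, start offsets).  Runs that do not fit are
    dropped from the back (the first run is protected when
    ``keep_first``); a single over-long run is truncated instead.
    """
    order = list(range(len(lens)))
    while order:
        need = sum(lens[i] for i in order) + len(order) - 1
        if need <= capacity:
            break
        if len(order) == 1:
            lens[order[0]] = capacity
            break
        drop_at = len(order) - 1 if not (keep_first and order[-1] == 0) else len(order) - 2
        order.pop(drop_at)
    kept = order
    k = len(kept)
    slack = capacity - (sum(lens[i] for i in kept) + k - 1)
    gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    starts = []
    pos = 0
    for j, i in enumerate(kept):
        pos += gaps[j] + (1 if j > 0 else 0)
        starts.append(pos)
        pos += lens[i]
    return kept, starts


def simulate_day_trace(
    cfg: SyntheticConfig,
    seg: str,
    rng: np.random.Generator,
    person_id: str = "W00",
    day_date: date | None = None,
    detected: bool | None = None,
    cv: bool | None = None,
    device: DeviceMeta | None = None,
) -> tuple[list[SessionLog], dict]:
    """Generate one person-day of sessions plus its ground-truth record.

    Baseline zeros on the 15-s grid with planted peaks; session on/off
    pattern applied; overloads recorded as 101.  Peaks that cannot fit
    the session capacity are dropped or truncated and the truth updated
    accordingly.
    """
    day_date = day_date or cfg.start
    device = device or DeviceMeta(serial_id=f"BW-{person_id}")
    if detected is None:
        detected = bool(rng.random() < cfg.p_detect_day.get(seg, 0.0))
    if cv is None:
        cv = bool(detected and rng.random() < cfg.p_cv_given_detect)

    dur_min = float(np.exp(math.log(cfg.duration_median_min)
                           + cfg.duration_log_sigma * rng.standard_normal()))
    dur_min = float(np.clip(dur_min, 15.0, device.max_log_hours * 60.0))
    n_tot = int(round(dur_min * 60.0 / device.sampling_interval))
    if rng.random() < cfg.p_two_sessions and n_tot >= 160:
        frac = rng.uniform(0.3, 0.7)
        session_lens = [int(n_tot * frac), n_tot - int(n_tot * frac)]
    else:
        session_lens = [n_tot]

    arrays = [np.zeros(n) for n in session_lens]
    heights: list[float] = []
    lens: list[int] = []
    if detected:
        n_peaks = 1 + int(rng.negative_binomial(cfg.peak_extra_r, cfg.peak_extra_p))
        raw_heights = (
            np.concatenate([_heights(rng, cfg, 1, "high", device),
                            _heights(rng, cfg, n_peaks - 1, "any", device)])
            if cv
            else _heights(rng, cfg, n_peaks, "low", device)
        )
        run_lens = rng.geometric(cfg.peak_len_p, size=n_peaks).astype(int).tolist()
        # assign each peak to a session, the protected peak to the largest
        sess_of = rng.integers(0, len(session_lens), size=n_peaks)
        if cv:
            sess_of[0] = int(np.argmax(session_lens))
        for si, arr in enumerate(arrays):
            idx = [i for i in range(n_peaks) if sess_of[i] == si]
            if not idx:
                continue
            local_lens = [run_lens[i] for i in idx]
            kept_local, starts = _place_runs(
                rng, len(arr), local_lens, keep_first=cv and 0 in idx and idx[0] == 0
            )
            for j, start in zip(kept_local, starts):
                i = idx[j]
                vals = _peak_values(float(raw_heights[i]), local_lens[j], cfg.peak_shape, device)
                arr[start : start + len(vals)] = vals
                heights.append(float(vals.max()))
                lens.append(len(vals))

    sessions: list[SessionLog] = []
    t = datetime.combine(day_date, time(8, 0))
    for arr in arrays:
        s = SessionLog(device, person_id, seg, t, [ReadingBlock(arr)])
        sessions.append(compress_zero_runs(s) if cfg.compression else s)
        t = s.end + timedelta(minutes=60)

    dose = sum(float(s.values.sum()) * device.sampling_interval for s in sessions)
    max_h = max(heights) if heights else 0.0
    truth = {
        "person_id": person_id,
        "seg": seg,
        "date": day_date,
        "detected": bool(heights),
        "cv_exceeded": max_h > 10.0,
        "n_peaks": len(heights),
        "n_high_peaks": sum(h > 10.0 for h in heights),
        "max_height": max_h,
        "planted_twa": dose / (480.0 * 60.0),
        "duration_min": n_tot * device.sampling_interval / 60.0,
        "n_samples": n_tot,
    }
    return sessions, truth


@dataclass
class Cohort:
    """A generated cohort: raw sessions, ground truth, worker table."""

    sessions: list[SessionLog]
    truth: pd.DataFrame
    workers: pd.DataFrame
    config: SyntheticConfig


def simulate_cohort(cfg: SyntheticConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort, reproducible under ``cfg.seed``.

    With ``out_dir`` the sessions are written as a canonical CSV log
    (compressed per the config) together with a ``truth.csv`` sidecar.
    """
    rng = np.random.default_rng(cfg.seed)
    calendar = workday_calendar(cfg.start, cfg.n_workdays, cfg.holidays)
    sessions: list[SessionLog] = []
    truth_rows: list[dict] = []
    worker_rows: list[dict] = []
    for seg in SEGS:
        n = int(cfg.n_workers.get(seg, 0))
        if n == 0:
            continue
        probs = _worker_probs(rng, cfg.p_detect_day.get(seg, 0.0), n, cfg.worker_sd_logit)
        for w in range(n):
            person = f"{seg}-{w:02d}"
            device = DeviceMeta(serial_id=f"BW-{person}")
            worker_rows.append({"person_id": person, "seg": seg, "p_detect": probs[w]})
            det = rng.random(len(calendar)) < probs[w]
            cvs = rng.random(len(calendar)) < cfg.p_cv_given_detect
            for d, day_date in enumerate(calendar):
                day_sessions, truth = simulate_day_trace(
                    cfg, seg, rng, person_id=person, day_date=day_date,
                    detected=bool(det[d]), cv=bool(det[d] and cvs[d]), device=device,
                )
                sessions.extend(day_sessions)
                truth_rows.append(truth)
    cohort = Cohort(
        sessions=sessions,
        truth=pd.DataFrame(truth_rows),
        workers=pd.DataFrame(worker_rows),
        config=cfg,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_canonical_log(sessions, out / "sessions.csv", compressed=cfg.compression)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        cohort.workers.to_csv(out / "workers.csv", index=False)
    return cohort


def recovery_report(
    truth: pd.DataFrame, metrics, cfg: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Estimated-vs-planted comparison table for a matched cohort.

    Rows cover the detectable-day rate (per SEG and overall), the
    CV-given-detected rate, exact agreement of day flags and peak counts
    with the planted truth, and the largest absolute TWA discrepancy.
    ``ok`` applies a 3-standard-error binomial bound to rates and
    exactness to flags.
    """
    from .exposure_metrics import metrics_frame  # local import avoids cycle at module load

    est = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    merged = truth.merge(est, on=["person_id", "date"], suffixes=("_true", ""))
    if len(merged) != len(truth) or len(merged) != len(est):
        raise ValueError("truth and metrics do not describe the same cohort")

    rows = []

    def rate_row(quantity, seg, est_mean, target, n):
        se = math.sqrt(target * (1 - target) / n) if n else float("nan")
        ok = abs(est_mean - target) <= 3 * se if n and se > 0 else est_mean == target
        rows.append({"quantity": quantity, "seg": seg, "estimate": est_mean,
                     "target": target, "n": n, "se": se, "ok": bool(ok)})

    segs = sorted(merged["seg"].unique())
    for seg in segs:
        g = merged[merged["seg"] == seg]
        target = (cfg.p_detect_day[seg] if cfg is not None else g["detected"].mean())
        rate_row("p_detect", seg, float(g["above_lod"].mean()), float(target), len(g))
    if cfg is not None:
        overall_target = float(
            np.mean([cfg.p_detect_day[s] for s in merged["seg"]])
        )
    else:
        overall_target = float(merged["detected"].mean())
    rate_row("p_detect", "total", float(merged["above_lod"].mean()), overall_target, len(merged))

    det = merged[merged["above_lod"]]
    cv_target = cfg.p_cv_given_detect if cfg is not None else float(det["cv_exceeded"].mean())
    rate_row("p_cv_given_detect", "total", float(det["above_cv"].mean()),
             float(cv_target), len(det))

    for quantity, lhs, rhs in [
        ("flag_agreement_detect", "above_lod", "detected"),
        ("flag_agreement_cv", "above_cv", "cv_exceeded"),
        ("n_peaks_agreement", "n_peaks", "n_peaks_true"),
    ]:
        frac = float((merged[lhs] == merged[rhs]).mean())
        rows.append({"quantity": quantity, "seg": "total", "estimate": frac,
                     "target": 1.0, "n": len(merged), "se": 0.0, "ok": frac == 1.0})

    twa_err = float((merged["twa"] - merged["planted_twa"]).abs().max())
    rows.append({"quantity": "twa_max_abs_error", "seg": "total", "estimate": twa_err,
                 "target": 0.0, "n": len(merged), "se": 0.0, "ok": twa_err <= 1e-9})
    return pd.DataFrame(rows)
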