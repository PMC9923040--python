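"""Reading, validating and writing gas-monitor session logs.

A personal H2S monitor records an instantaneous concentration every 15 s
for up to 16 h per run ("session", bounded by power on/off log events).
The sensor reports on a coded scale: readings below the 1.6 ppm limit of
detection (LOD) are left-censored and stored as 0.0, readings beyond the
100 ppm range are right-censored and stored as the overload code 101.
Docking stations may additionally *zero-compress* a log: maximal runs of
consecutive below-LOD readings are elided and only their count is kept.

This module defines a canonical plain-CSV dialect for such logs (the
vendor export format is proprietary) and round-trip safe readers/writers
for both the full and the zero-compressed variant.  The dialect:

    #dialect: h2slog-csv/1
    serial,person,seg,timestamp,value_ppm,row_type,n_or_code
    BW-01,W1,plant,2019-01-07T08:00:00,,log_event,on
    BW-01,W1,plant,2019-01-07T08:00:00,0.0,zero_run,4
    BW-01,W1,plant,2019-01-07T08:01:00,2.4,reading,
    BW-01,W1,plant,2019-01-07T08:01:15,,log_event,off

Timestamps are local wall clock on a 15-s grid anchored at session start;
no timezone arithmetic is performed.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import numpy as np
import yaml

DIALECT = "h2slog-csv/1"
_DIALECT_PREFIX = "#dialect:"
_COLUMNS = ["serial", "person", "seg", "timestamp", "value_ppm", "row_type", "n_or_code"]

#: Similar exposed groups of the cohort.
SEGS = ("sewerage_net", "plant", "pumping_station", "water_net")


class LogFormatError(ValueError):
    """File does not conform to the canonical dialect (missing/bad header)."""


class LogValidationError(ValueError):
    """A structurally valid row carries an invalid value; message cites the line."""


class Censor(str, Enum):
    BELOW_LOD = "below_lod"
    IN_RANGE = "in_range"
    OVERLOAD = "overload"


@dataclass(frozen=True)
class DeviceMeta:
    """Static metadata of one monitor.

    Defaults model the instrument used in the field: 15-s sampling,
    detection range 1.6-100 ppm at 0.1 ppm resolution, overload coded as
    101, ring buffer good for 16 h of readings.
    """

    serial_id: str = "BW-0000"
    sampling_interval: float = 15.0
    lod: float = 1.6
    overload_ppm: float = 100.0
    overload_code: float = 101.0
    resolution: float = 0.1
    max_log_hours: float = 16.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not (self.lod < self.overload_ppm < self.overload_code):
            raise ValueError("require lod < overload_ppm < overload_code")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def step(self) -> timedelta:
        return timedelta(seconds=self.sampling_interval)

    @property
    def _decimals(self) -> int:
        return max(0, -math.floor(math.log10(self.resolution) + 1e-9))

    def code_value(self, value: float) -> float:
        """Map a raw ppm value onto the device reporting scale.

        Rounds to the instrument resolution, coerces sub-LOD values to 0.0
        (the real device cannot emit them) and values beyond the range to
        the overload code.  Negative concentrations are invalid.
        """
        if not np.isfinite(value) or value < 0:
            raise LogValidationError(f"invalid concentration {value!r}")
        v = round(round(value / self.resolution) * self.resolution, self._decimals)
        if v < self.lod:
            return 0.0
        if v > self.overload_ppm:
            return self.overload_code
        return v

    def code_values(self, values: Iterable[float]) -> np.ndarray:
        return np.array([self.code_value(v) for v in np.asarray(values, dtype=float)])

    def censor_of(self, value: float) -> Censor:
        if value >= self.overload_code:
            return Censor.OVERLOAD
        if value < self.lod:
            return Censor.BELOW_LOD
        return Censor.IN_RANGE

    def is_coded(self, values: np.ndarray) -> bool:
        """True when every value is already on the device reporting scale."""
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return True
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            return False
        on_grid = np.abs(v / self.resolution - np.round(v / self.resolution)) < 1e-6
        in_range = (v == 0.0) | (v == self.overload_code) | ((v >= self.lod) & (v <= self.overload_ppm))
        return bool(np.all(on_grid & in_range))


def device_from_yaml(source: Union[str, Path, Mapping]) -> DeviceMeta:
    """Build a DeviceMeta from a YAML file/string of field overrides."""
    if isinstance(source, Mapping):
        overrides = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        overrides = yaml.safe_load(text) or {}
    return DeviceMeta(**overrides)


@dataclass(frozen=True)
class Reading:
    """One 15-s sample: instant coded value plus its censoring state."""

    t: datetime
    value: float
    censor: Censor


@dataclass(frozen=True)
class CompressedRun:
    """``n`` consecutive below-LOD readings elided by the docking station."""

    n: int

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("CompressedRun.n must be an integer >= 1")


class ReadingBlock:
    """A contiguous block of coded readings, stored as a float array."""

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float]):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ReadingBlock values must be one-dimensional")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReadingBlock) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        return f"ReadingBlock(n={len(self)})"


Item = Union[ReadingBlock, CompressedRun]


def _normalize_items(items: Iterable) -> list[Item]:
    """Merge adjacent blocks/runs and drop empties, keeping sample order."""
    out: list[Item] = []
    for item in items:
        if isinstance(item, Reading):  # tolerate scalar readings
            item = ReadingBlock([item.value])
        if isinstance(item, ReadingBlock):
            if len(item) == 0:
                continue
            if out and isinstance(out[-1], ReadingBlock):
                out[-1] = ReadingBlock(np.concatenate([out[-1].values, item.values]))
            else:
                out.append(ReadingBlock(item.values.copy()))
        elif isinstance(item, CompressedRun):
            if out and isinstance(out[-1], CompressedRun):
                out[-1] = CompressedRun(out[-1].n + item.n)
            else:
                out.append(item)
        else:
            raise TypeError(f"unsupported session item {item!r}")
    return out


@dataclass
class SessionLog:
    """One device run (power-on to power-off) of 15-s readings.

    ``items`` is an ordered mix of :class:`ReadingBlock` and
    :class:`CompressedRun`; the session is contiguous on the 15-s grid
    anchored at ``start``.
    """

    device: DeviceMeta
    person_id: str
    seg: str
    start: datetime
    items: list

    def __post_init__(self) -> None:
        if self.seg not in SEGS:
            raise ValueError(f"unknown SEG {self.seg!r}; expected one of {SEGS}")
        self.items = _normalize_items(self.items)
        for item in self.items:
            if isinstance(item, ReadingBlock) and not self.device.is_coded(item.values):
                raise LogValidationError(
                    "session readings are not on the device reporting scale"
                )
        if self.duration_s > self.device.max_log_hours * 3600:
            raise ValueError("session exceeds the device's maximum log length")

    @property
    def n_samples(self) -> int:
        return sum(len(i) if isinstance(i, ReadingBlock) else i.n for i in self.items)

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.device.sampling_interval

    @property
    def end(self) -> datetime:
        return self.start + self.n_samples * self.device.step

    @property
    def is_expanded(self) -> bool:
        return not any(isinstance(i, CompressedRun) for i in self.items)

    @property
    def values(self) -> np.ndarray:
        """Expanded coded values (compressed runs virtually filled with 0.0)."""
        parts = [
            i.values if isinstance(i, ReadingBlock) else np.zeros(i.n)
            for i in self.items
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def readings(self) -> Iterator[Reading]:
        for k, v in enumerate(self.values):
            yield Reading(self.start + k * self.device.step, float(v), self.device.censor_of(v))

    @property
    def log_events(self) -> list[tuple[datetime, str]]:
        return [(self.start, "on"), (self.end, "off")]


def session_from_values(
    device: DeviceMeta, person_id: str, seg: str, start: datetime, values: Iterable[float]
) -> SessionLog:
    """Convenience constructor coding raw ppm values onto the device scale."""
    return SessionLog(device, person_id, seg, start, [ReadingBlock(device.code_values(values))])


def expand_zero_runs(s: SessionLog) -> SessionLog:
    """Replace every compressed run by explicit 0.0 readings on the grid."""
    return SessionLog(s.device, s.person_id, s.seg, s.start, [ReadingBlock(s.values)])


def compress_zero_runs(s: SessionLog) -> SessionLog:
    """Elide maximal runs of below-LOD readings, like a docking transfer.

    Exact inverse of :func:`expand_zero_runs`: ``expand(compress(s))``
    reproduces the expanded readings bit for bit.
    """
    v = s.values
    items: list[Item] = []
    if v.size:
        below = v < s.device.lod
        edges = np.flatnonzero(np.diff(below)) + 1
        for lo, hi in zip(np.r_[0, edges], np.r_[edges, v.size]):
            if below[lo]:
                items.append(CompressedRun(int(hi - lo)))
            else:
                items.append(ReadingBlock(v[lo:hi]))
    return SessionLog(s.device, s.person_id, s.seg, s.start, items)


def _parse_timestamp(text: str, lineno: int) -> datetime:
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise LogValidationError(f"line {lineno}: bad timestamp {text!r}") from exc


def parse_canonical_log(
    path: Union[str, Path, io.TextIOBase], device: DeviceMeta | None = None
) -> list[SessionLog]:
    """Parse a canonical CSV log into a list of sessions.

    Sessions are split at on/off log events; zero-run rows stay compressed
    (use :func:`expand_zero_runs` downstream if needed).  Malformed rows
    raise :class:`LogValidationError` citing the 1-based line number.
    """
    device = device or DeviceMeta()
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, newline="")
        close = True
    else:
        handle, close = path, False
    try:
        first = handle.readline()
        if not first.startswith(_DIALECT_PREFIX) or first.split(":", 1)[1].strip() != DIALECT:
            raise LogFormatError(f"missing or unsupported dialect header: {first.strip()!r}")
        reader = csv.DictReader(handle, fieldnames=None)
        if reader.fieldnames is None:
            return []
        if list(reader.fieldnames) != _COLUMNS:
            raise LogFormatError(f"bad column header {reader.fieldnames!r}")

        sessions: list[SessionLog] = []
        open_sessions: dict[str, dict] = {}  # serial -> accumulator

        def _flush(acc: dict) -> None:
            if acc["buf"]:
                acc["items"].append(ReadingBlock(acc["buf"]))
                acc["buf"] = []

        for row in reader:
            lineno = reader.line_num + 1  # +1 for the dialect line
            serial = row["serial"]
            row_type = row["row_type"]
            t = _parse_timestamp(row["timestamp"], lineno)
            if row_type == "log_event":
                code = row["n_or_code"]
                if code == "on":
                    if serial in open_sessions:
                        raise LogValidationError(f"line {lineno}: 'on' while session open")
                    open_sessions[serial] = {
                        "person": row["person"], "seg": row["seg"],
                        "start": t, "n": 0, "items": [], "buf": [],
                        "device": device if device.serial_id == serial
                        else DeviceMeta(serial_id=serial, sampling_interval=device.sampling_interval,
                                        lod=device.lod, overload_ppm=device.overload_ppm,
                                        overload_code=device.overload_code,
                                        resolution=device.resolution,
                                        max_log_hours=device.max_log_hours),
                    }
                elif code == "off":
                    acc = open_sessions.pop(serial, None)
                    if acc is None:
                        raise LogValidationError(f"line {lineno}: 'off' without open session")
                    _flush(acc)
                    sessions.append(SessionLog(acc["device"], acc["person"], acc["seg"],
                                               acc["start"], acc["items"]))
                else:
                    raise LogValidationError(f"line {lineno}: unknown log event {code!r}")
                continue

            acc = open_sessions.get(serial)
            if acc is None:
                raise LogValidationError(f"line {lineno}: data row outside a session")
            expected = acc["start"] + acc["n"] * acc["device"].step
            if t != expected:
                raise LogValidationError(
                    f"line {lineno}: off-grid timestamp {t.isoformat()} "
                    f"(expected {expected.isoformat()})"
                )
            if row_type == "reading":
                try:
                    raw = float(row["value_ppm"])
                except (TypeError, ValueError) as exc:
                    raise LogValidationError(f"line {lineno}: bad value {row['value_ppm']!r}") from exc
                try:
                    coded = acc["device"].code_value(raw)
                except LogValidationError as exc:
                    raise LogValidationError(f"line {lineno}: {exc}") from exc
                acc["buf"].append(coded)
                acc["n"] += 1
            elif row_type == "zero_run":
                try:
                    n = int(row["n_or_code"])
                except (TypeError, ValueError) as exc:
                    raise LogValidationError(f"line {lineno}: bad run length") from exc
                if n < 1:
                    raise LogValidationError(f"line {lineno}: run length must be >= 1")
                _flush(acc)
                acc["items"].append(CompressedRun(n))
                acc["n"] += n
            else:
                raise LogValidationError(f"line {lineno}: unknown row_type {row_type!r}")
        if open_sessions:
            serials = sorted(open_sessions)
            raise LogValidationError(f"unterminated session(s) for serial(s) {serials}")
        return sessions
    finally:
        if close:
            handle.close()


def write_canonical_log(
    sessions: Iterable[SessionLog],
    path: Union[str, Path, io.TextIOBase],
    compressed: bool = False,
) -> None:
    """Write sessions to the canonical CSV dialect.

    With ``compressed=True`` maximal below-LOD runs are elided as
    ``zero_run`` rows; re-parsing yields sessions equal to
    ``compress_zero_runs(s)`` (respectively ``expand_zero_runs(s)``).
    """
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "w", newline="")
        close = True
    else:
        handle, close = path, False
    try:
        handle.write(f"{_DIALECT_PREFIX} {DIALECT}\n")
        writer = csv.writer(handle)
        writer.writerow(_COLUMNS)
        for s in sessions:
            s = compress_zero_runs(s) if compressed else expand_zero_runs(s)
            dec = s.device._decimals
            base = [s.device.serial_id, s.person_id, s.seg]
            writer.writerow(base + [s.start.isoformat(), "", "log_event", "on"])
            t = s.start
            for item in s.items:
                if isinstance(item, CompressedRun):
                    writer.writerow(base + [t.isoformat(), "0.0", "zero_run", item.n])
                    t += item.n * s.device.step
                else:
                    for v in item.values:
                        writer.writerow(base + [t.isoformat(), f"{v:.{dec}f}", "reading", ""])
                        t += s.device.step
            writer.writerow(base + [t.isoformat(), "", "log_event", "off"])
    finally:
        if close:
            handle.close()
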