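"""Ingest and quality control of station-level hourly pollutant measurements.

Raw agency exports arrive as delimited text with one row per (station, hour)
measurement.  This module parses them into :class:`StationRecord` streams,
applies the quality-control rules used for hourly PM2.5 data (implausible
exact zeros, duplicated records, extreme values above 1,000 µg/m³), averages
the stations of a city into a single hourly :class:`SiteSeries`, re-labels
timezones so every city shares one clock, and slices calendar-month analysis
windows.

Missing hours are represented as explicit NaN gaps on a regular hourly grid
and are never imputed; downstream correlation works on pairwise-complete
overlap.  Timestamps are treated as left-labelled hourly intervals.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyAfterQCError

#: Concentrations strictly above this value (µg/m³) are removed as outliers.
OUTLIER_THRESHOLD = 1000.0

#: Default minimum fraction of hours present for a calendar-month window to
#: be considered usable.
DEFAULT_COMPLETENESS_MIN = 0.75


def _tz(offset_hours: int) -> timezone:
    return timezone(timedelta(hours=int(offset_hours)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationRecord:
    """One hourly measurement at one monitoring station.

    ``timestamp`` always carries an explicit UTC offset; ``value`` is a
    concentration in µg/m³ or NaN for a reported-but-missing measurement.
    """

    station_id: str
    city_id: str
    timestamp: pd.Timestamp
    value: float

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            raise ValueError("StationRecord timestamp must carry a UTC offset")


@dataclass
class SiteSeries:
    """One city's hourly concentration series on a regular grid.

    ``values[i]`` is the concentration for the hour starting at
    ``start + i hours`` (left-labelled intervals), NaN where no station
    reported.  ``qc_log`` carries the removal counters from quality control.
    """

    city_id: str
    tz_offset_hours: int
    start: pd.Timestamp
    values: np.ndarray
    qc_log: dict = field(default_factory=dict)
    completeness: float | None = None
    usable: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.start.tzinfo is None:
            raise ValueError("SiteSeries start must carry a UTC offset")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq="h")

    @property
    def epoch_hours(self) -> np.ndarray:
        """Integer hours since the Unix epoch for each slot (timezone-free)."""
        first = int(self.start.timestamp() // 3600)
        return first + np.arange(len(self.values))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (city_id, timestamp, value) frame."""
        return pd.DataFrame(
            {"city_id": self.city_id, "timestamp": self.index, "value": self.values}
        )

    def fraction_present(self) -> float:
        if len(self.values) == 0:
            return 0.0
        return float(np.isfinite(self.values).mean())


@dataclass
class SiteTable:
    """Per-city metadata: coordinates, timezone offset, country label."""

    frame: pd.DataFrame  # columns: city_id, lat, lon, tz_offset_hours, country

    REQUIRED = ("city_id", "lat", "lon", "tz_offset_hours", "country")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"site table missing columns: {missing}")
        if self.frame["city_id"].duplicated().any():
            dups = self.frame.loc[self.frame["city_id"].duplicated(), "city_id"]
            raise ConfigurationError(f"duplicate city_id in site table: {list(dups)}")
        if (self.frame["lat"].abs() > 90).any() or (self.frame["lon"].abs() > 180).any():
            raise ConfigurationError("site table has out-of-range coordinates")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SiteTable":
        return cls(pd.read_csv(path))

    def lookup(self, city_id: str) -> pd.Series:
        rows = self.frame[self.frame["city_id"] == city_id]
        if rows.empty:
            raise KeyError(f"unknown city_id: {city_id!r}")
        return rows.iloc[0]

    def __contains__(self, city_id: str) -> bool:
        return bool((self.frame["city_id"] == city_id).any())


@dataclass(frozen=True)
class FormatSpec:
    """Column mapping and timestamp convention for a delimited input file.

    ``columns`` maps the canonical names {station_id, city_id, timestamp,
    value} to the file's column headers.  If timestamps in the file carry no
    UTC offset, ``default_tz_offset_hours`` must be given.
    """

    columns: Mapping[str, str]
    timestamp_format: str | None = None
    default_tz_offset_hours: int | None = None
    delimiter: str = ","

    CANONICAL = ("station_id", "city_id", "timestamp", "value")

    def __post_init__(self):
        missing = [k for k in self.CANONICAL if k not in self.columns]
        if missing:
            raise ConfigurationError(f"format_spec missing column mapping for {missing}")


#: Convention used by the synthetic simulator's writer and the CLI defaults.
DEFAULT_FORMAT = FormatSpec(
    columns={
        "station_id": "station_id",
        "city_id": "city_id",
        "timestamp": "timestamp",
        "value": "value",
    }
)


@dataclass
class ParseResult:
    """Parsed records plus an account of every rejected row."""

    records: list[StationRecord]
    n_rows: int = 0
    n_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class QCReport:
    """Removal counts by class, overall and per station.

    Count conservation holds per station and overall:
    retained + zeros + outliers + duplicates + missing == input rows.
    """

    n_input: int = 0
    retained: int = 0
    zeros: int = 0
    outliers: int = 0
    duplicates: int = 0
    missing: int = 0
    per_station: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "retained": self.retained,
            "removed": {
                "zeros": self.zeros,
                "outliers": self.outliers,
                "duplicates": self.duplicates,
                "missing": self.missing,
            },
            "per_station": self.per_station,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def conserves_counts(self) -> bool:
        total = self.retained + self.zeros + self.outliers + self.duplicates + self.missing
        if total != self.n_input:
            return False
        return all(
            c["retained"] + c["zeros"] + c["outliers"] + c["duplicates"] + c["missing"]
            == c["n_input"]
            for c in self.per_station.values()
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_station_records(path, format_spec: FormatSpec = DEFAULT_FORMAT) -> ParseResult:
    """Read a delimited file of station measurements.

    Every row is either parsed into a :class:`StationRecord` or counted in
    ``reject_reasons`` — nothing is silently dropped.  A row whose value
    field is empty parses as a missing measurement (NaN), which quality
    control later counts as a gap.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"input file not found: {path}")
    cols = format_spec.columns
    try:
        df = pd.read_csv(path, sep=format_spec.delimiter, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise IOError(f"cannot read {path}: {exc}") from exc
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(f"input file {path} missing required columns: {missing}")

    ts = pd.to_datetime(
        df[cols["timestamp"]], format=format_spec.timestamp_format, errors="coerce", utc=False
    )
    raw_values = df[cols["value"]]

    result = ParseResult(records=[], n_rows=len(df))
    default_tz = (
        _tz(format_spec.default_tz_offset_hours)
        if format_spec.default_tz_offset_hours is not None
        else None
    )
    for i in range(len(df)):
        t = ts.iloc[i]
        if pd.isna(t):
            result.n_rejected += 1
            result.reject_reasons["unparseable_timestamp"] += 1
            continue
        if t.tzinfo is None:
            if default_tz is None:
                result.n_rejected += 1
                result.reject_reasons["timestamp_missing_offset"] += 1
                continue
            t = t.tz_localize(default_tz)
        raw = raw_values.iloc[i]
        if pd.isna(raw) or str(raw).strip() == "":
            v = float("nan")  # reported-but-missing measurement
        else:
            try:
                v = float(raw)  # exact round-trip parse
            except ValueError:
                result.n_rejected += 1
                result.reject_reasons["unparseable_value"] += 1
                continue
            if not np.isfinite(v) or v < 0:
                result.n_rejected += 1
                result.reject_reasons["negative_or_nonfinite_value"] += 1
                continue
        result.records.append(
            StationRecord(
                station_id=str(df[cols["station_id"]].iloc[i]),
                city_id=str(df[cols["city_id"]].iloc[i]),
                timestamp=pd.Timestamp(t),
                value=v,
            )
        )
    return result


def qc_filter(records: Iterable[StationRecord]) -> tuple[list[StationRecord], QCReport]:
    """Apply the quality-control rules and account for every removal.

    Removal classes, applied in this order:

    1. *missing*: records whose value is NaN (leave a gap, never imputed);
    2. *zeros*: implausible exact 0.0 readings;
    3. *outliers*: values strictly above 1,000 µg/m³;
    4. *duplicates*: repeated (station, timestamp) keys among the survivors.
       Exact duplicates collapse to one survivor; conflicting duplicates
       (same key, different values) are all dropped — conservative and
       auditable.

    Idempotent: filtering already-filtered records changes nothing.
    """
    records = list(records)
    report = QCReport(n_input=len(records))

    def station_counts(sid: str) -> dict:
        return report.per_station.setdefault(
            sid,
            {"n_input": 0, "retained": 0, "zeros": 0, "outliers": 0,
             "duplicates": 0, "missing": 0},
        )

    survivors: list[StationRecord] = []
    for rec in records:
        c = station_counts(rec.station_id)
        c["n_input"] += 1
        if not np.isfinite(rec.value):
            report.missing += 1
            c["missing"] += 1
        elif rec.value == 0.0:
            report.zeros += 1
            c["zeros"] += 1
        elif rec.value > OUTLIER_THRESHOLD:
            report.outliers += 1
            c["outliers"] += 1
        else:
            survivors.append(rec)

    # duplicate resolution among value-valid survivors
    by_key: dict[tuple, list[StationRecord]] = {}
    for rec in survivors:
        by_key.setdefault((rec.station_id, rec.timestamp.timestamp()), []).append(rec)

    kept: list[StationRecord] = []
    for group in by_key.values():
        sid = group[0].station_id
        c = station_counts(sid)
        distinct_values = {r.value for r in group}
        if len(group) == 1:
            kept.append(group[0])
            report.retained += 1
            c["retained"] += 1
        elif len(distinct_values) == 1:
            kept.append(group[0])
            report.retained += 1
            c["retained"] += 1
            report.duplicates += len(group) - 1
            c["duplicates"] += len(group) - 1
        else:  # conflicting duplicates: drop all
            report.duplicates += len(group)
            c["duplicates"] += len(group)

    if records and not kept:
        raise EmptyAfterQCError("quality control removed every record")
    kept.sort(key=lambda r: (r.city_id, r.station_id, r.timestamp.timestamp()))
    return kept, report


def average_stations(
    records: Sequence[StationRecord],
    city_id: str,
    qc_log: dict | None = None,
) -> SiteSeries:
    """Average all stations of one city onto a single hourly grid.

    The per-hour value is the arithmetic mean over the stations reporting
    that hour; hours with no reporting station are NaN gaps.  Timestamps are
    floored to the hour (left-labelled intervals); the series is expressed at
    the UTC offset of the city's first record.
    """
    city_recs = [r for r in records if r.city_id == city_id]
    if not city_recs:
        raise KeyError(f"no records for city_id {city_id!r}")
    tzinfo = city_recs[0].timestamp.tzinfo
    offset = int(tzinfo.utcoffset(None).total_seconds() // 3600)

    df = pd.DataFrame(
        {
            "timestamp": [r.timestamp.tz_convert(tzinfo).floor("h") for r in city_recs],
            "value": [r.value for r in city_recs],
        }
    )
    hourly = df.groupby("timestamp")["value"].mean()
    full = pd.date_range(hourly.index.min(), hourly.index.max(), freq="h")
    hourly = hourly.reindex(full)
    return SiteSeries(
        city_id=city_id,
        tz_offset_hours=offset,
        start=pd.Timestamp(full[0]),
        values=hourly.to_numpy(dtype=float),
        qc_log=dict(qc_log or {}),
    )


def align_timezone(series: SiteSeries, target_offset_hours: int) -> SiteSeries:
    """Re-express the series' wall-clock labels at another UTC offset.

    The underlying instants and values are untouched; only the labels (and
    ``tz_offset_hours``) change.  Relabelling a UTC+9 series to UTC+8 shifts
    every wall-clock label one hour earlier.
    """
    if target_offset_hours == series.tz_offset_hours:
        return replace(series)
    new_start = series.start.tz_convert(_tz(target_offset_hours))
    return replace(series, start=new_start, tz_offset_hours=int(target_offset_hours))


def window(
    series: SiteSeries,
    year: int,
    month: int,
    completeness_min: float = DEFAULT_COMPLETENESS_MIN,
) -> SiteSeries:
    """Restrict a series to one calendar month in its own timezone.

    The returned series covers every hourly slot of the month (744 for
    January, 672 for February 2018, ...), with NaN wherever the input had no
    value or did not extend.  ``completeness`` records the fraction of slots
    present; a window below ``completeness_min`` is flagged unusable rather
    than raising, so callers can log and skip it.
    """
    tzinfo = _tz(series.tz_offset_hours)
    month_start = pd.Timestamp(year=year, month=month, day=1, tz=tzinfo)
    next_month = (month_start + pd.offsets.MonthBegin(1)).tz_convert(tzinfo)
    n_slots = int((next_month - month_start) / pd.Timedelta(hours=1))

    if month_start >= series.index[-1] + pd.Timedelta(hours=1) or next_month <= series.start:
        raise ValueError(
            f"month {year}-{month:02d} outside span of series for {series.city_id}"
        )

    out = np.full(n_slots, np.nan)
    # overlap of [month_start, next_month) with the series' own grid
    off = int((month_start - series.start) / pd.Timedelta(hours=1))
    src_lo, src_hi = max(0, off), min(len(series), off + n_slots)
    if src_lo < src_hi:
        out[src_lo - off: src_hi - off] = series.values[src_lo:src_hi]

    completeness = float(np.isfinite(out).mean())
    return replace(
        series,
        start=month_start,
        values=out,
        completeness=completeness,
        usable=completeness >= completeness_min,
    )


def series_to_csv(series_by_city: Mapping[str, SiteSeries], path) -> None:
    """Write per-city hourly series as tidy CSV (city_id, timestamp, value)."""
    frames = [series_by_city[c].to_frame() for c in sorted(series_by_city)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def series_from_csv(path) -> dict[str, SiteSeries]:
    """Read the tidy per-city CSV written by :func:`series_to_csv`."""
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip")
    out: dict[str, SiteSeries] = {}
    for city, sub in df.groupby("city_id"):
        ts = pd.DatetimeIndex(sub["timestamp"])
        if ts.tz is None:
            raise ConfigurationError(f"series CSV timestamps for {city} lack UTC offsets")
        offset = int(ts[0].utcoffset().total_seconds() // 3600)
        full = pd.date_range(ts.min(), ts.max(), freq="h")
        vals = pd.Series(sub["value"].to_numpy(), index=ts).reindex(full)
        out[str(city)] = SiteSeries(
            city_id=str(city),
            tz_offset_hours=offset,
            start=pd.Timestamp(full[0]),
            values=vals.to_numpy(dtype=float),
        )
    return out
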