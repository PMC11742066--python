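"""Reader/writer for the CDC Downscaler daily county-level PM2.5 CSV schema.

The expected schema has one row per county-day with columns STATEFIPS,
COUNTYFIPS, YEAR, DATE and four predicted 24-hour concentrations in
micrograms per cubic metre: maximum, median, mean and population-weighted
mean.  Header aliases are matched case- and punctuation-insensitively
("PM2.5-MAX-PRED", "pm25_max_pred" and "PM2.5 Max Pred" all resolve to the
same column).  Malformed rows are collected into a rejects report instead
of being silently dropped.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CdcRecord",
    "RejectedRow",
    "ReadResult",
    "DescriptiveStats",
    "InputError",
    "CONCENTRATION_COLUMNS",
    "read_cdc_csv",
    "write_cdc_csv",
    "select_series",
    "descriptive_stats",
    "write_report",
]

CONCENTRATION_COLUMNS = (
    "pm25_max_pred",
    "pm25_med_pred",
    "pm25_mean_pred",
    "pm25_pop_pred",
)

_CANONICAL_HEADER = {
    "STATEFIPS": "statefips",
    "COUNTYFIPS": "countyfips",
    "YEAR": "year",
    "DATE": "date",
    "PM25MAXPRED": "pm25_max_pred",
    "PM25MEDPRED": "pm25_med_pred",
    "PM25MEANPRED": "pm25_mean_pred",
    "PM25POPPRED": "pm25_pop_pred",
}

_OUTPUT_HEADER = (
    "STATEFIPS",
    "COUNTYFIPS",
    "YEAR",
    "DATE",
    "PM2.5-MAX-PRED",
    "PM2.5-MED-PRED",
    "PM2.5-MEAN-PRED",
    "PM2.5-POP-PRED",
)

_DATE_FORMATS = ("%d-%m-%Y", "%Y-%m-%d", "%m/%d/%Y", "%d/%m/%Y", "%d%b%Y")


class InputError(ValueError):
    """A structural problem with an input file (missing columns, etc.)."""


@dataclass(frozen=True)
class CdcRecord:
    statefips: int
    countyfips: int
    year: int
    date: dt.date
    pm25_max_pred: float
    pm25_med_pred: float
    pm25_mean_pred: float
    pm25_pop_pred: float


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based, counting the header as row 1
    reason: str
    raw: dict


@dataclass
class ReadResult:
    records: list[CdcRecord]
    rejects: list[RejectedRow]
    date_format: str

    def write_rejects(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row_number", "reason", "raw"])
            for r in self.rejects:
                writer.writerow([r.row_number, r.reason, json.dumps(r.raw)])


def _normalize_header(name: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", name.upper())


def _detect_date_format(samples: Iterable[str]) -> str | None:
    samples = [s for s in samples if s]
    for fmt in _DATE_FORMATS:
        try:
            for s in samples:
                dt.datetime.strptime(s, fmt)
            return fmt
        except ValueError:
            continue
    return None


def read_cdc_csv(
    path: str | Path,
    date_format: str | None = None,
    aliases: dict[str, str] | None = None,
) -> ReadResult:
    """Parse a Downscaler-schema CSV into records plus a rejects report.

    ``date_format`` is a ``strptime`` pattern; when omitted the reader
    tries day-month-year first and falls back to a small set of common
    dialects, inferring from the first rows.  ``aliases`` maps extra
    header spellings (already normalised to upper-case alphanumerics) to
    canonical field names.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputError(f"{path} is empty or has no header row")
        header_map: dict[str, str] = {}
        lookup = dict(_CANONICAL_HEADER)
        if aliases:
            lookup.update(aliases)
        for col in reader.fieldnames:
            canon = lookup.get(_normalize_header(col))
            if canon is not None:
                header_map[col] = canon
        missing = set(_CANONICAL_HEADER.values()) - set(header_map.values())
        if missing:
            raise InputError(f"missing mandatory columns: {sorted(missing)}")
        rows = list(reader)

    if date_format is None:
        date_format = _detect_date_format(
            [(r.get(c) or "").strip() for r in rows[:20] for c in header_map if header_map[c] == "date"]
        ) or _DATE_FORMATS[0]

    records: list[CdcRecord] = []
    rejects: list[RejectedRow] = []
    for idx, raw in enumerate(rows, start=2):
        fields = {header_map[c]: (raw.get(c) or "").strip() for c in header_map}
        try:
            date = dt.datetime.strptime(fields["date"], date_format).date()
            year = int(fields["year"])
            if date.year != year:
                raise ValueError(f"DATE year {date.year} contradicts YEAR {year}")
            conc = {}
            for col in CONCENTRATION_COLUMNS:
                value = float(fields[col])
                if not math.isfinite(value) or value < 0:
                    raise ValueError(f"{col} must be a finite non-negative number, got {value}")
                conc[col] = value
            records.append(
                CdcRecord(
                    statefips=int(fields["statefips"]),
                    countyfips=int(fields["countyfips"]),
                    year=year,
                    date=date,
                    **conc,
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(row_number=idx, reason=str(exc), raw=dict(raw)))
    return ReadResult(records=records, rejects=rejects, date_format=date_format)


def write_cdc_csv(records: Sequence[CdcRecord], path: str | Path, date_format: str = "%d-%m-%Y") -> None:
    """Write records back in the canonical schema at full float precision."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OUTPUT_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.statefips,
                    r.countyfips,
                    r.year,
                    r.date.strftime(date_format),
                    repr(r.pm25_max_pred),
                    repr(r.pm25_med_pred),
                    repr(r.pm25_mean_pred),
                    repr(r.pm25_pop_pred),
                ]
            )


def select_series(
    records: Sequence[CdcRecord], countyfips: int, variable: str = "pm25_max_pred"
) -> pd.Series:
    """Date-ordered concentration series of one county and one column."""
    if variable not in CONCENTRATION_COLUMNS:
        raise InputError(
            f"unknown variable {variable!r}; choose one of {CONCENTRATION_COLUMNS}"
        )
    pairs = [(r.date, getattr(r, variable)) for r in records if r.countyfips == countyfips]
    if not pairs:
        raise InputError(f"no records for county FIPS {countyfips}")
    pairs.sort(key=lambda p: p[0])
    dates = [p[0] for p in pairs]
    dupes = {d for i, d in enumerate(dates[1:], 1) if d == dates[i - 1]}
    if dupes:
        raise InputError(f"duplicate dates for county {countyfips}: {sorted(dupes)}")
    return pd.Series(
        [p[1] for p in pairs], index=pd.DatetimeIndex(dates, name="date"), name=variable
    )


@dataclass(frozen=True)
class DescriptiveStats:
    """Spreadsheet-style descriptive summary of a concentration series."""

    mean: float
    standard_error: float
    median: float
    mode: float
    standard_deviation: float
    sample_variance: float
    kurtosis: float
    skewness: float
    range: float
    minimum: float
    maximum: float
    sum: float
    count: int


def descriptive_stats(series) -> DescriptiveStats:
    """Mean/SE/median/mode, sample SD and variance (n-1), bias-corrected
    skewness and excess kurtosis, min/max/range/sum/count.

    Skewness and kurtosis use the spreadsheet estimators
    ``n/((n-1)(n-2)) * sum(((x-m)/s)^3)`` and
    ``n(n+1)/((n-1)(n-2)(n-3)) * sum(((x-m)/s)^4) - 3(n-1)^2/((n-2)(n-3))``;
    they are NaN when the sample is too small (n < 3 resp. n < 4) or
    constant.  Mode is the most frequent exact value, smallest value
    winning ties — fragile on continuous data and reported as such.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = float(x.mean())
    sd = float(np.std(x, ddof=1))
    values, counts = np.unique(x, return_counts=True)
    mode = float(values[np.argmax(counts)])  # unique() sorts, argmax takes first

    if sd > 0 and n >= 3:
        z = (x - m) / sd
        skew = n / ((n - 1) * (n - 2)) * float(np.sum(z**3))
    else:
        skew = float("nan")
    if sd > 0 and n >= 4:
        z = (x - m) / sd
        kurt = (
            n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(z**4))
            - 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        )
    else:
        kurt = float("nan")

    return DescriptiveStats(
        mean=m,
        standard_error=sd / math.sqrt(n),
        median=float(np.median(x)),
        mode=mode,
        standard_deviation=sd,
        sample_variance=sd**2,
        kurtosis=kurt,
        skewness=skew,
        range=float(x.max() - x.min()),
        minimum=float(x.min()),
        maximum=float(x.max()),
        sum=float(x.sum()),
        count=n,
    )


# Column order of the published per-method summary tables.
_RUNREPORT_CSV_COLUMNS = (
    "best",
    "worst",
    "average",
    "sd",
    "cpu_time",
    "best_C",
    "best_sigma",
)


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a run report, rank result or descriptive summary.

    JSON keeps every field in declaration order with explicit nulls; CSV
    (run reports only) emits one row in the published summary-table column
    order Best, Worst, Average, SD, CPU time, C, sigma.
    """
    path = Path(path)
    if hasattr(report, "as_dict"):
        payload = report.as_dict()
    elif dataclasses.is_dataclass(report):
        payload = dataclasses.asdict(report)
    elif isinstance(report, dict):
        payload = report
    else:
        raise TypeError(f"cannot serialize report of type {type(report)!r}")

    def _sanitize(obj):
        if isinstance(obj, np.ndarray):
            obj = obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            obj = obj.item()
        if isinstance(obj, float) and not math.isfinite(obj):
            return None  # explicit null instead of non-standard NaN/Infinity
        if isinstance(obj, dict):
            return {k: _sanitize(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_sanitize(v) for v in obj]
        return obj

    if format == "json":
        path.write_text(json.dumps(_sanitize(payload), indent=2))
    elif format == "csv":
        row = {k: payload.get(k) for k in _RUNREPORT_CSV_COLUMNS}
        if any(v is None for v in row.values()):
            missing = [k for k, v in row.items() if v is None]
            raise InputError(f"report lacks fields for CSV layout: {missing}")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_RUNREPORT_CSV_COLUMNS)
            writer.writerow([repr(float(v)) for v in row.values()])
    else:
        raise InputError(f"unknown report format {format!r}")
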