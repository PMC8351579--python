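"""Domain tables and plain-text I/O for interval-binned acoustic survey data.

The package works with four tabular objects, all plain :class:`pandas.DataFrame`
with fixed column schemas (local naive timestamps throughout):

``detection events``
    one row per verified vocalization event —
    ``site_id`` (str), ``start`` (datetime64), ``duration_s`` (float, >= 0).

``interval table``
    one row per 5-minute recorder bin —
    ``site_id`` (str), ``date`` (datetime64, midnight-normalized calendar date),
    ``bin_start`` (int minutes after midnight, multiple of 5), ``detected``
    (int, 0/1). ``(site_id, date, bin_start)`` is unique. An interval belongs
    to the calendar date containing ``bin_start``, so one night spans two
    date keys.

``hourly environment``
    ``timestamp`` (datetime64, hourly), ``temp_c``, ``rh_pct``, ``wind_kmph``,
    ``pressure`` (barometric pressure in the station's native unit, carried
    opaquely; thresholds must be expressed in the same unit), ``precip_mm``.
    Two derived columns, ``pressure_change_24h`` and ``cum_precip_24h``, are
    added by :func:`surveypower.env_features.derive_env_features` and are NaN
    where the 24-h look-back window is unavailable.

``moon table``
    ``date`` (datetime64, midnight), ``illumination`` (fraction in [0, 1]).

Missing observations are represented as absent rows (gaps), never as zeros.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: width of one detection bin, minutes
BIN_MINUTES = 5
#: bins per calendar day
BINS_PER_DAY = 24 * 60 // BIN_MINUTES
#: events no longer than this many seconds are discarded as false positives
DEFAULT_MIN_EVENT_S = 3.0

EVENT_COLUMNS = ["site_id", "start", "duration_s"]
INTERVAL_COLUMNS = ["site_id", "date", "bin_start", "detected"]
ENV_COLUMNS = ["timestamp", "temp_c", "rh_pct", "wind_kmph", "pressure", "precip_mm"]
DERIVED_ENV_COLUMNS = ["pressure_change_24h", "cum_precip_24h"]
MOON_COLUMNS = ["date", "illumination"]


class FormatError(ValueError):
    """A delimited input file violates the expected schema or an invariant."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# detection events
# ---------------------------------------------------------------------------

def read_detection_events(path) -> pd.DataFrame:
    """Read verified detection events from a CSV file.

    Expected columns: ``site_id``, ``start_iso8601``, ``duration_s``.
    Row order is preserved. Raises :class:`FormatError` naming the offending
    column or line for schema violations, unparseable timestamps, or negative
    durations.
    """
    raw = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(raw, ["site_id", "start_iso8601", "duration_s"], path)
    start = pd.to_datetime(raw["start_iso8601"], errors="coerce", format="mixed")
    bad = start.isna() & raw["start_iso8601"].notna()
    if raw["start_iso8601"].isna().any():
        bad |= raw["start_iso8601"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise FormatError(f"{path}: unparseable timestamp at line {line}")
    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    bad = duration.isna() | (duration < 0)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: invalid duration_s at line {line} (must be a number >= 0)")
    return pd.DataFrame(
        {"site_id": raw["site_id"].astype(str), "start": start, "duration_s": duration.astype(float)}
    )


def write_detection_events(events: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "site_id": events["site_id"],
            "start_iso8601": events["start"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "duration_s": events["duration_s"],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# recording coverage and binning
# ---------------------------------------------------------------------------

def full_coverage(
    sites: Iterable[str],
    dates: Iterable,
    bin_starts: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Enumerate every (site, date, bin) a continuously running recorder covers.

    ``bin_starts`` defaults to all 288 five-minute bins of the day; pass a
    subset (minutes after midnight) for recorders on a schedule.
    """
    if bin_starts is None:
        bin_starts = range(0, 24 * 60, BIN_MINUTES)
    bins = np.asarray(list(bin_starts), dtype=np.int64)
    if np.any(bins % BIN_MINUTES) or np.any(bins < 0) or np.any(bins >= 24 * 60):
        raise ValueError("bin_starts must be minutes after midnight on the 5-minute grid")
    dates = pd.to_datetime(pd.Index(list(dates))).normalize()
    sites = list(sites)
    frame = pd.MultiIndex.from_product(
        [sites, dates, bins], names=["site_id", "date", "bin_start"]
    ).to_frame(index=False)
    return frame


def bin_events_to_intervals(
    events: pd.DataFrame,
    coverage: pd.DataFrame,
    min_event_s: float = DEFAULT_MIN_EVENT_S,
) -> pd.DataFrame:
    """Bin detection events onto the 5-minute grid of covered recorder time.

    ``coverage`` enumerates every (site, date, bin) the recorder actually ran
    (see :func:`full_coverage`); every covered bin appears exactly once in the
    output, sorted by (site, date, bin). A bin is ``detected = 1`` iff at
    least one event with ``duration_s > min_event_s`` overlaps its half-open
    span ``[bin_start, bin_start + 5 min)``; shorter events are ignored
    entirely (they are overwhelmingly false positives). Bins are
    calendar-aligned to the clock, and an event spanning a bin boundary marks
    every bin it touches.

    Events falling entirely on (site, date) pairs with no declared coverage
    are dropped with a single warning giving the count.
    """
    cov = coverage[["site_id", "date", "bin_start"]].copy()
    cov["date"] = pd.to_datetime(cov["date"]).dt.normalize()
    cov = cov.sort_values(["site_id", "date", "bin_start"], kind="stable").reset_index(drop=True)
    keys = list(zip(cov["site_id"], cov["date"], cov["bin_start"]))
    if len(set(keys)) != len(keys):
        raise ValueError("coverage contains duplicate (site, date, bin) rows")
    pos_of = {k: i for i, k in enumerate(keys)}
    covered_site_dates = set(zip(cov["site_id"], cov["date"]))

    detected = np.zeros(len(cov), dtype=np.int64)
    step = pd.Timedelta(minutes=BIN_MINUTES)
    n_dropped = 0
    retained = events[events["duration_s"] > min_event_s]
    for site, start, dur in zip(retained["site_id"], retained["start"], retained["duration_s"]):
        t0 = pd.Timestamp(start)
        t1 = t0 + pd.Timedelta(seconds=float(dur))  # event span [t0, t1)
        bin_ts = t0.floor(f"{BIN_MINUTES}min")
        on_coverage = False
        while bin_ts < t1:
            date = bin_ts.normalize()
            key = (site, date, int((bin_ts - date).total_seconds() // 60))
            if key in pos_of:
                detected[pos_of[key]] = 1
            if (site, date) in covered_site_dates:
                on_coverage = True
            bin_ts += step
        if not on_coverage:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped} event(s) fell outside declared recording coverage and were dropped",
            stacklevel=2,
        )
    cov["detected"] = detected
    return cov[INTERVAL_COLUMNS]


# ---------------------------------------------------------------------------
# interval tables
# ---------------------------------------------------------------------------

def _minutes_to_hhmm(minutes: pd.Series) -> pd.Series:
    return (minutes // 60).map("{:02d}".format) + ":" + (minutes % 60).map("{:02d}".format)


def read_interval_table(path) -> pd.DataFrame:
    """Read an interval table CSV (columns site_id, date, bin_start, detected)."""
    raw = pd.read_csv(path, dtype={"site_id": str, "bin_start": str})
    _require_columns(raw, INTERVAL_COLUMNS, path)
    if raw.empty:
        return pd.DataFrame(
            {
                "site_id": pd.Series(dtype=str),
                "date": pd.Series(dtype="datetime64[ns]"),
                "bin_start": pd.Series(dtype=np.int64),
                "detected": pd.Series(dtype=np.int64),
            }
        )
    date = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    if date.isna().any():
        line = int(date.isna().idxmax()) + 2
        raise FormatError(f"{path}: unparseable date at line {line}")
    parts = raw["bin_start"].str.split(":", expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise FormatError(f"{path}: bin_start must be HH:MM")
    minutes = pd.to_numeric(parts[0], errors="coerce") * 60 + pd.to_numeric(parts[1], errors="coerce")
    bad = minutes.isna() | (minutes % BIN_MINUTES != 0) | (minutes < 0) | (minutes >= 24 * 60)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: bin_start off the 5-minute grid at line {line}")
    det = pd.to_numeric(raw["detected"], errors="coerce")
    bad = ~det.isin([0, 1])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: detected must be 0 or 1 at line {line}")
    table = pd.DataFrame(
        {
            "site_id": raw["site_id"].astype(str),
            "date": date,
            "bin_start": minutes.astype(np.int64),
            "detected": det.astype(np.int64),
        }
    )
    if table.duplicated(["site_id", "date", "bin_start"]).any():
        raise FormatError(f"{path}: duplicate (site_id, date, bin_start) rows")
    return table


def write_interval_table(table: pd.DataFrame, path) -> None:
    """Write an interval table CSV; ``read_interval_table`` round-trips exactly."""
    out = pd.DataFrame(
        {
            "site_id": table["site_id"],
            "date": pd.to_datetime(table["date"]).dt.strftime("%Y-%m-%d"),
            "bin_start": _minutes_to_hhmm(table["bin_start"].astype(np.int64)),
            "detected": table["detected"].astype(np.int64),
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# environment and moon
# ---------------------------------------------------------------------------

def read_hourly_environment(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read hourly weather observations from a CSV file.

    Default columns: ``timestamp_iso8601, temp_c, rh_pct, wind_kmph, pressure,
    precip_mm``. ``column_map`` maps file column names onto these canonical
    names, adapting e.g. NOAA Local Climatological Data exports without
    editing the file. Duplicate timestamps and out-of-range humidity are
    rejected; gaps are simply absent rows.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    _require_columns(raw, ["timestamp_iso8601"] + ENV_COLUMNS[1:], path)
    ts = pd.to_datetime(raw["timestamp_iso8601"], errors="coerce", format="mixed")
    if ts.isna().any():
        line = int(ts.isna().idxmax()) + 2
        raise FormatError(f"{path}: unparseable timestamp at line {line}")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated timestamp {dup}")
    env = pd.DataFrame({"timestamp": ts})
    for col in ENV_COLUMNS[1:]:
        env[col] = pd.to_numeric(raw[col], errors="coerce")
    rh = env["rh_pct"].dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise FormatError(f"{path}: rh_pct outside [0, 100]")
    for col in ("wind_kmph", "precip_mm"):
        if (env[col].dropna() < 0).any():
            raise FormatError(f"{path}: negative {col}")
    return env


def write_hourly_environment(env: pd.DataFrame, path) -> None:
    out = env[ENV_COLUMNS].copy()
    out.insert(0, "timestamp_iso8601", out.pop("timestamp").dt.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)


def read_moon(path) -> pd.DataFrame:
    """Read per-date moon illumination (columns ``date``, ``illumination``).

    Illumination may be given as a fraction in [0, 1] or as a percent; any
    value above 1 switches the whole column to the percent interpretation.
    """
    raw = pd.read_csv(path)
    _require_columns(raw, MOON_COLUMNS, path)
    date = pd.to_datetime(raw["date"], errors="coerce")
    if date.isna().any():
        line = int(date.isna().idxmax()) + 2
        raise FormatError(f"{path}: unparseable date at line {line}")
    if date.duplicated().any():
        raise FormatError(f"{path}: duplicated date")
    illum = pd.to_numeric(raw["illumination"], errors="coerce")
    if illum.isna().any():
        line = int(illum.isna().idxmax()) + 2
        raise FormatError(f"{path}: non-numeric illumination at line {line}")
    if (illum > 1).any():
        illum = illum / 100.0
    if ((illum < 0) | (illum > 1)).any():
        raise FormatError(f"{path}: illumination outside [0, 1] after unit detection")
    return pd.DataFrame({"date": date.dt.normalize(), "illumination": illum.astype(float)})


def write_moon(moon: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"date": pd.to_datetime(moon["date"]).dt.strftime("%Y-%m-%d"), "illumination": moon["illumination"]}
    )
    out.to_csv(path, index=False)
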