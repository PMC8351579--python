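"""24-hour derived weather features and detection-night condition summaries.

Chorusing anurans respond less to the instantaneous weather than to what the
last day did: recent rainfall and a falling barometer are the classic triggers.
This module derives those look-back features from the hourly record and
summarizes conditions on the dates when the target species was actually heard.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: minimum hourly observations required inside a 24-h window for a derived
#: feature to be considered defined (18 of 24 = 75% coverage)
MIN_WINDOW_HOURS = 18

#: quantile interpolation used everywhere in the package
QUANTILE_METHOD = "linear"

SUMMARY_STATS = ["min", "q1", "median", "mean", "q3", "max"]


def derive_env_features(env: pd.DataFrame, min_window_hours: int = MIN_WINDOW_HOURS) -> pd.DataFrame:
    """Add ``pressure_change_24h`` and ``cum_precip_24h`` to an hourly table.

    ``pressure_change_24h(t) = pressure(t) - pressure(t - 24 h)``, defined only
    when both endpoint observations exist. ``cum_precip_24h(t)`` sums hourly
    precipitation over the preceding 24 hours, window ``[t - 24 h, t)`` (the
    current hour is excluded: the feature describes what has already fallen),
    and requires at least ``min_window_hours`` of the 24 hourly observations;
    otherwise it is NaN. Both features are NaN throughout the first 24 h of
    the series. Input must be sorted by timestamp; gaps (absent rows) are
    allowed and count as missing hours.
    """
    if not env["timestamp"].is_monotonic_increasing:
        raise ValueError("environment table must be sorted by timestamp")
    out = env.copy()
    if out.empty:
        out["pressure_change_24h"] = pd.Series(dtype=float)
        out["cum_precip_24h"] = pd.Series(dtype=float)
        return out
    t0, t1 = out["timestamp"].iloc[0], out["timestamp"].iloc[-1]
    grid = pd.date_range(t0, t1, freq="h")
    full = out.set_index("timestamp").reindex(grid)

    pressure_change = full["pressure"] - full["pressure"].shift(24)
    cum_precip = full["precip_mm"].shift(1).rolling(24, min_periods=min_window_hours).sum()
    early = grid < t0 + pd.Timedelta(hours=24)
    pressure_change[early] = np.nan
    cum_precip[early] = np.nan

    out["pressure_change_24h"] = pressure_change.loc[out["timestamp"]].to_numpy()
    out["cum_precip_24h"] = cum_precip.loc[out["timestamp"]].to_numpy()
    return out


def _stats(values: np.ndarray) -> dict:
    q = lambda p: float(np.quantile(values, p, method=QUANTILE_METHOD))
    return {
        "min": float(values.min()),
        "q1": q(0.25),
        "median": q(0.5),
        "mean": float(values.mean()),
        "q3": q(0.75),
        "max": float(values.max()),
    }


def summarize_detection_conditions(
    intervals: pd.DataFrame, env: pd.DataFrame, moon: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Summarize weather on calendar dates with at least one detection.

    For every environmental variable (including derived features when
    present), reports min / Q1 / median / mean / Q3 / max over all hourly
    observations falling on detection-positive dates — the whole day, not just
    night hours, since the survey-eligibility rules themselves look at the
    whole calendar date. Moon illumination, one value per date, is reported
    in percent. Returns an empty frame (with a warning) when no date has a
    detection.
    """
    pos_dates = pd.to_datetime(intervals.loc[intervals["detected"] == 1, "date"]).unique()
    columns = pd.Index(SUMMARY_STATS)
    if len(pos_dates) == 0:
        warnings.warn("no detection-positive dates; condition summary is empty", stacklevel=2)
        return pd.DataFrame(columns=columns)
    pos_dates = pd.DatetimeIndex(pos_dates)
    on = env[env["timestamp"].dt.normalize().isin(pos_dates)]

    rows = {}
    variables = ["temp_c", "rh_pct", "wind_kmph", "pressure", "pressure_change_24h",
                 "precip_mm", "cum_precip_24h"]
    for var in variables:
        if var not in on.columns:
            continue
        values = on[var].dropna().to_numpy()
        if values.size:
            rows[var] = _stats(values)
    if moon is not None and not moon.empty:
        values = moon.loc[pd.to_datetime(moon["date"]).isin(pos_dates), "illumination"]
        values = values.dropna().to_numpy() * 100.0
        if values.size:
            rows["moon_illumination_pct"] = _stats(values)
    summary = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_STATS]
    summary.index.name = "variable"
    return summary


def write_condition_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path)
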