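"""Survey-eligibility scenarios: which nights and 5-minute bins may be surveyed.

A :class:`Scenario` is a named rule set — calendar months, a nightly time
window, and optional environmental threshold rules — that defines the pool of
surveyable intervals. Because field surveys are scheduled a day ahead from
forecasts, eligibility is resolved per *calendar date*: if the thresholds are
met at any point within a date, every night interval of that date may be
surveyed.

Three presets ship with the package:

``random``
    peak season (Feb-Apr) nights, no environmental restriction;
``usfws``
    the U.S. Fish and Wildlife Service protocol thresholds for the Houston
    Toad — temperature > 14 °C, relative humidity > 70%, wind < 24 km/h,
    moon illumination < 0.5 (fraction, i.e. half illuminated);
``optimized``
    thresholds found by the detection:non-detection ratio search —
    temperature > 16 °C, any rain in the last 24 h, barometric pressure
    falling by more than 0.07 units over 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: feature names a threshold rule may reference
RULE_VARIABLES = (
    "temp_c",
    "rh_pct",
    "wind_kmph",
    "moon_illumination",
    "pressure_change_24h",
    "cum_precip_24h",
)

#: default nightly window: before 06:00 or at/after 18:00 (minutes after midnight)
DEFAULT_NIGHT_WINDOW = (6 * 60, 18 * 60)
DEFAULT_MONTHS = (2, 3, 4)


@dataclass(frozen=True)
class ThresholdRule:
    """One environmental eligibility rule, e.g. ``temp_c greater_than 14``."""

    variable: str
    direction: str  # "greater_than" | "less_than"
    value: float

    def __post_init__(self):
        if self.variable not in RULE_VARIABLES:
            raise ValueError(f"unknown rule variable {self.variable!r}; known: {RULE_VARIABLES}")
        if self.direction not in ("greater_than", "less_than"):
            raise ValueError(f"direction must be greater_than or less_than, got {self.direction!r}")
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")

    def mask(self, values: pd.Series) -> pd.Series:
        """Boolean satisfaction per observation; missing values never satisfy."""
        if self.direction == "greater_than":
            out = values > self.value
        else:
            out = values < self.value
        return out.fillna(False)

    def __str__(self):
        op = ">" if self.direction == "greater_than" else "<"
        return f"{self.variable} {op} {self.value:g}"


@dataclass(frozen=True)
class Scenario:
    """A named survey-eligibility rule set."""

    name: str
    months: tuple = DEFAULT_MONTHS
    night_window: tuple = DEFAULT_NIGHT_WINDOW
    rules: tuple = ()
    #: True: all rules must hold at the same hourly observation (default);
    #: False: each rule must hold at some, possibly different, hour of the date.
    simultaneous: bool = True

    def filter_pool(self, intervals: pd.DataFrame, env: pd.DataFrame, moon: pd.DataFrame) -> "IntervalPool":
        """Apply the season/night filter, then the threshold rules, and build the pool."""
        peak = peak_period_filter(intervals, self.months, self.night_window)
        eligible = None
        if self.rules:
            eligible = eligible_dates(env, moon, self.rules, simultaneous=self.simultaneous)
        return build_pool(peak, eligible)

    @classmethod
    def from_dict(cls, spec: Mapping) -> "Scenario":
        """Build a scenario from a config mapping (see the CLI docs)."""
        rules = tuple(
            ThresholdRule(r["variable"], r["direction"], float(r["value"]))
            for r in spec.get("rules", ())
        )
        window = spec.get("night_window", DEFAULT_NIGHT_WINDOW)
        return cls(
            name=spec["name"],
            months=tuple(spec.get("months", DEFAULT_MONTHS)),
            night_window=(int(window[0]), int(window[1])),
            rules=rules,
            simultaneous=bool(spec.get("simultaneous", True)),
        )


def random_scenario() -> Scenario:
    return Scenario(name="random")


def usfws_scenario() -> Scenario:
    return Scenario(
        name="usfws",
        rules=(
            ThresholdRule("temp_c", "greater_than", 14.0),
            ThresholdRule("rh_pct", "greater_than", 70.0),
            ThresholdRule("wind_kmph", "less_than", 24.0),
            ThresholdRule("moon_illumination", "less_than", 0.5),
        ),
    )


def optimized_scenario() -> Scenario:
    return Scenario(
        name="optimized",
        rules=(
            ThresholdRule("temp_c", "greater_than", 16.0),
            ThresholdRule("cum_precip_24h", "greater_than", 0.0),
            ThresholdRule("pressure_change_24h", "less_than", -0.07),
        ),
    )


SCENARIO_PRESETS = {
    "random": random_scenario,
    "usfws": usfws_scenario,
    "optimized": optimized_scenario,
}


def resolve_scenario(spec) -> Scenario:
    """Turn a preset name, mapping, or Scenario into a Scenario."""
    if isinstance(spec, Scenario):
        return spec
    if isinstance(spec, str):
        try:
            return SCENARIO_PRESETS[spec]()
        except KeyError:
            raise ValueError(f"unknown scenario preset {spec!r}; presets: {sorted(SCENARIO_PRESETS)}")
    return Scenario.from_dict(spec)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def peak_period_filter(
    intervals: pd.DataFrame,
    months: Iterable[int] = DEFAULT_MONTHS,
    night_window: tuple = DEFAULT_NIGHT_WINDOW,
) -> pd.DataFrame:
    """Retain intervals in the peak months and nightly window.

    The window is (morning_end, evening_start) in minutes after midnight: a
    bin is kept iff ``bin_start < morning_end`` or ``bin_start >= evening_start``
    — by default before 06:00 or at/after 18:00.
    """
    morning_end, evening_start = night_window
    month = pd.to_datetime(intervals["date"]).dt.month
    keep = month.isin(list(months)) & (
        (intervals["bin_start"] < morning_end) | (intervals["bin_start"] >= evening_start)
    )
    return intervals.loc[keep].reset_index(drop=True)


def feature_frame(env: pd.DataFrame, moon: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hourly frame holding every rule variable plus a ``date`` key.

    Moon illumination is constant over a calendar date, so it is broadcast to
    every hour of its date.
    """
    frame = pd.DataFrame({"timestamp": env["timestamp"]})
    frame["date"] = env["timestamp"].dt.normalize()
    for col in ("temp_c", "rh_pct", "wind_kmph", "pressure_change_24h", "cum_precip_24h"):
        if col in env.columns:
            frame[col] = env[col].to_numpy()
    if moon is not None and not moon.empty:
        lookup = pd.Series(
            moon["illumination"].to_numpy(), index=pd.to_datetime(moon["date"]).dt.normalize()
        )
        frame["moon_illumination"] = frame["date"].map(lookup)
    return frame


def eligible_dates(
    env: pd.DataFrame,
    moon: pd.DataFrame | None,
    rules: Sequence[ThresholdRule],
    simultaneous: bool = True,
) -> set:
    """Calendar dates on which the threshold rules are met.

    With ``simultaneous=True`` (default) a date qualifies iff at least one
    hourly observation satisfies *all* rules at once; otherwise each rule must
    be met at some (possibly different) hour of the date. Missing feature
    values never satisfy a rule. An empty rule list makes every date with any
    environmental coverage eligible. Referencing a variable absent from the
    feature frame raises ``ValueError`` naming it.
    """
    frame = feature_frame(env, moon)
    if not rules:
        return set(frame["date"].unique())
    for rule in rules:
        if rule.variable not in frame.columns:
            raise ValueError(f"rule variable {rule.variable!r} not available in environment data")
    if simultaneous:
        mask = np.ones(len(frame), dtype=bool)
        for rule in rules:
            mask &= rule.mask(frame[rule.variable]).to_numpy()
        ok = frame.loc[mask, "date"].unique()
        return set(ok)
    per_rule = [set(frame.loc[rule.mask(frame[rule.variable]).to_numpy(), "date"].unique()) for rule in rules]
    return set.intersection(*per_rule)


# ---------------------------------------------------------------------------
# interval pools
# ---------------------------------------------------------------------------

@dataclass
class IntervalPool:
    """Surveyable intervals grouped per date for the simulator.

    ``by_date`` maps each date to a list of ``(site_id, slots, detected)``
    with ``slots`` the sorted 5-minute slot indices (``bin_start // 5``) and
    ``detected`` the aligned 0/1 flags.
    """

    intervals: pd.DataFrame
    dates: list = field(default_factory=list)
    by_date: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def n_positive(self) -> int:
        return int(self.intervals["detected"].sum())


def build_pool(intervals: pd.DataFrame, eligible: set | None = None) -> IntervalPool:
    """Restrict intervals to eligible dates and index them for simulation.

    ``eligible=None`` means no environmental restriction (the whole input is
    the pool). An empty result is returned as an empty pool, not an error.
    """
    table = intervals
    if eligible is not None:
        eligible_idx = pd.DatetimeIndex(sorted(eligible))
        table = intervals[pd.to_datetime(intervals["date"]).isin(eligible_idx)]
    table = table.sort_values(["date", "site_id", "bin_start"], kind="stable").reset_index(drop=True)
    by_date: dict = {}
    for (date, site), group in table.groupby(["date", "site_id"], sort=True):
        slots = (group["bin_start"].to_numpy() // 5).astype(np.int64)
        det = group["detected"].to_numpy().astype(np.int64)
        by_date.setdefault(date, []).append((site, slots, det))
    dates = sorted(by_date)
    return IntervalPool(intervals=table, dates=dates, by_date=by_date)
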