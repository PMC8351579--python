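"""Grid search for environmental thresholds that concentrate detections.

The search scores a candidate rule combination by the ratio of
detection-positive to detection-negative intervals left in the surveyable
pool: a good threshold set throws away quiet nights while keeping chorusing
ones. Candidates are the observed values of each variable (optionally
decimated to a quantile grid), with both directions (> and <) tried per
value, and the Cartesian product of one choice per variable is enumerated
exhaustively. A ``min_dates`` floor guards against degenerate optima that
leave almost no surveyable dates.

No train/test split is performed; the thresholds are descriptive of the data
they were searched on, and out-of-sample evaluation (e.g. on fresh synthetic
seasons) is the caller's job.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scenarios import ThresholdRule, build_pool, eligible_dates, feature_frame


@dataclass(frozen=True)
class ThresholdCombo:
    """One scored rule combination: pool composition and detection ratio."""

    rules: tuple
    n_dates: int
    n_pos: int
    n_neg: int
    ratio: float  # n_pos / n_neg; inf if n_neg == 0 < n_pos; nan if pool empty

    def as_row(self) -> dict:
        row = {f"rule_{i + 1}": str(r) for i, r in enumerate(self.rules)}
        row.update(n_dates=self.n_dates, n_pos=self.n_pos, n_neg=self.n_neg, ratio=self.ratio)
        return row


def _ratio(n_pos: int, n_neg: int) -> float:
    if n_pos == 0 and n_neg == 0:
        return float("nan")
    if n_neg == 0:
        return float("inf")
    return n_pos / n_neg


def candidate_grid(
    features: pd.DataFrame, variables: Sequence[str], resolution: int | None = None
) -> dict:
    """Sorted candidate threshold values per variable.

    Candidates are the unique observed values; with ``resolution`` set, they
    are decimated to at most that many evenly spaced quantile points of the
    distinct values. A constant variable degenerates to a single candidate.
    """
    out = {}
    for var in variables:
        if var not in features.columns:
            raise ValueError(f"variable {var!r} not present in the feature table")
        values = np.unique(features[var].dropna().to_numpy())
        if values.size == 0:
            raise ValueError(f"variable {var!r} has no observed values")
        if resolution is not None and values.size > resolution:
            values = np.unique(np.quantile(values, np.linspace(0, 1, resolution), method="linear"))
        out[var] = values
    return out


def threshold_options(candidates: np.ndarray, directions: Sequence[str] = ("greater_than", "less_than")):
    """All (direction, value) pairs emitted for one variable's candidates."""
    return [(d, float(v)) for v in candidates for d in directions]


def evaluate_combo(
    intervals: pd.DataFrame,
    env: pd.DataFrame,
    moon: pd.DataFrame | None,
    rules: Sequence[ThresholdRule],
    simultaneous: bool = True,
) -> ThresholdCombo:
    """Score one rule combination on peak-period-filtered intervals."""
    eligible = eligible_dates(env, moon, list(rules), simultaneous=simultaneous)
    pool = build_pool(intervals, eligible)
    n_pos = pool.n_positive
    n_neg = pool.n_intervals - n_pos
    return ThresholdCombo(
        rules=tuple(rules), n_dates=len(pool.dates), n_pos=n_pos, n_neg=n_neg,
        ratio=_ratio(n_pos, n_neg),
    )


def _rank_key(combo: ThresholdCombo):
    # ratio desc (nan last), then n_pos desc, n_dates desc, lexicographic rules
    ratio = combo.ratio if not np.isnan(combo.ratio) else -np.inf
    rules_key = tuple((r.variable, r.direction, r.value) for r in combo.rules)
    return (-ratio, -combo.n_pos, -combo.n_dates, rules_key)


def grid_search(
    intervals: pd.DataFrame,
    env: pd.DataFrame,
    moon: pd.DataFrame | None,
    variables: Sequence[str],
    directions: Mapping[str, Sequence[str]] | None = None,
    resolution: int | None = None,
    min_dates: int = 0,
    top_n: int = 20,
    simultaneous: bool = True,
) -> list:
    """Exhaustively rank threshold combinations by detection ratio.

    Evaluates the Cartesian product of one (direction, value) choice per
    variable over the candidate grids, keeps combos leaving at least
    ``min_dates`` surveyable dates, and returns the ``top_n`` best. Ranking
    is ratio descending, ties broken by larger ``n_pos``, then larger
    ``n_dates``, then lexicographic rule order — a total order, so the output
    is deterministic. Returns an empty list (with a warning) when nothing is
    feasible.
    """
    frame = feature_frame(env, moon)
    grids = candidate_grid(frame, variables, resolution)
    if directions is None:
        directions = {}

    # per-date interval counts, restricted to dates present in the intervals
    per_date = intervals.groupby(pd.to_datetime(intervals["date"]))["detected"].agg(["sum", "size"])
    date_index = per_date.index
    pos_per_date = per_date["sum"].to_numpy(dtype=np.int64)
    tot_per_date = per_date["size"].to_numpy(dtype=np.int64)
    codes = date_index.get_indexer(frame["date"])  # -1 for hours on non-interval dates
    on_interval_dates = codes >= 0
    codes_valid = codes[on_interval_dates]
    n_dates_total = len(date_index)

    # precompute per-option hourly masks (restricted to interval dates)
    option_masks = {}
    option_lists = []
    for var in variables:
        opts = threshold_options(grids[var], directions.get(var, ("greater_than", "less_than")))
        option_lists.append([(var, d, v) for d, v in opts])
        col = frame[var]
        for d, v in opts:
            option_masks[(var, d, v)] = (
                ThresholdRule(var, d, v).mask(col).to_numpy()[on_interval_dates]
            )

    results = []
    for combo_spec in itertools.product(*option_lists):
        if simultaneous:
            mask = option_masks[combo_spec[0]]
            for opt in combo_spec[1:]:
                mask = mask & option_masks[opt]
            hit = np.bincount(codes_valid[mask], minlength=n_dates_total) > 0
        else:
            hit = np.ones(n_dates_total, dtype=bool)
            for opt in combo_spec:
                hit &= np.bincount(codes_valid[option_masks[opt]], minlength=n_dates_total) > 0
        n_dates = int(hit.sum())
        if n_dates < min_dates:
            continue
        n_pos = int(pos_per_date[hit].sum())
        n_tot = int(tot_per_date[hit].sum())
        rules = tuple(ThresholdRule(var, d, v) for var, d, v in combo_spec)
        results.append(
            ThresholdCombo(rules=rules, n_dates=n_dates, n_pos=n_pos, n_neg=n_tot - n_pos,
                           ratio=_ratio(n_pos, n_tot - n_pos))
        )
    if not results:
        warnings.warn("no threshold combination satisfies the min_dates constraint", stacklevel=2)
        return []
    results.sort(key=_rank_key)
    return results[:top_n]


def combos_to_frame(combos: Sequence[ThresholdCombo]) -> pd.DataFrame:
    """Ranked combos as a flat table for CSV output."""
    return pd.DataFrame([c.as_row() for c in combos])
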