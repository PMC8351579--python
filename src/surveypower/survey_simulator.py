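"""Monte-Carlo resampling of human audio surveys from an interval pool.

Each permutation simulates one field season: for every eligible calendar date
exactly one survey is placed uniformly at random (so no date is surveyed
twice within a permutation), and the detection probability is estimated as
the fraction of surveys that contained at least one detection-positive bin.
Repeating this ``n_permutations`` times yields a sampling distribution whose
mean and 2.5/97.5% quantiles summarize per-survey detection probability for a
given survey duration.

A survey of ``k`` bins (5k minutes) is, by default, a *contiguous* run of k
five-minute bins at a single site within one date — a surveyor staying at one
listening post. The alternative ``independent`` mode draws k distinct bins
(any site, any time of the date's night) without replacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .env_features import QUANTILE_METHOD
from .scenarios import IntervalPool


@dataclass(frozen=True)
class SurveyDesign:
    """Survey length (in 5-minute bins), permutation count, seed, and mode."""

    duration_bins: int
    n_permutations: int = 1000
    seed: int = 0
    mode: str = "contiguous"  # or "independent"

    def __post_init__(self):
        if not 1 <= self.duration_bins:
            raise ValueError("duration_bins must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mode not in ("contiguous", "independent"):
            raise ValueError("mode must be 'contiguous' or 'independent'")

    @property
    def duration_min(self) -> int:
        return 5 * self.duration_bins


@dataclass
class DetectionProbabilityDistribution:
    """Per-permutation detection-probability estimates for one (pool, k) cell."""

    estimates: np.ndarray
    mean: float
    q025: float
    q975: float
    n_dates: int
    n_dropped_dates: int
    duration_bins: int


def _contiguous_start_flags(slots: np.ndarray, detected: np.ndarray, k: int) -> np.ndarray:
    """0/1 positivity of every valid contiguous k-bin start within one site-date.

    A start at position i is valid iff slots[i..i+k-1] are consecutive (no
    temporal gap); it is positive iff any of those bins is detected.
    """
    n = len(slots)
    if n < k:
        return np.zeros(0, dtype=np.int64)
    # slots strictly increasing: a window is gap-free iff its span is exactly k-1
    span_ok = slots[k - 1 :] - slots[: n - k + 1] == k - 1
    csum = np.concatenate([[0], np.cumsum(detected)])
    positive = (csum[k:] - csum[: n - k + 1]) > 0
    return positive[span_ok].astype(np.int64)


def enumerate_survey_starts(pool: IntervalPool, k: int) -> dict:
    """Valid (site, bin_start-minutes) survey start positions per date."""
    out = {}
    for date in pool.dates:
        starts = []
        for site, slots, _det in pool.by_date[date]:
            n = len(slots)
            if n < k:
                continue
            ok = slots[k - 1 :] - slots[: n - k + 1] == k - 1
            for slot in slots[: n - k + 1][ok]:
                starts.append((site, int(slot) * 5))
        out[date] = starts
    return out


def _per_date_tables(pool: IntervalPool, k: int, mode: str):
    """Per-date sampling tables; dates without capacity for k are dropped.

    Contiguous mode returns one 0/1 flag array per date (positivity of every
    valid start, pooled across sites). Independent mode returns the exact
    Bernoulli probability that k bins drawn without replacement from the
    date's bins contain at least one positive: 1 - C(neg, k)/C(total, k).
    """
    tables, dropped = [], 0
    for date in pool.dates:
        if mode == "contiguous":
            flags = [
                _contiguous_start_flags(slots, det, k) for _site, slots, det in pool.by_date[date]
            ]
            flags = np.concatenate(flags) if flags else np.zeros(0, dtype=np.int64)
            if flags.size == 0:
                dropped += 1
            else:
                tables.append(flags)
        else:
            total = sum(len(slots) for _s, slots, _d in pool.by_date[date])
            pos = sum(int(det.sum()) for _s, _slots, det in pool.by_date[date])
            if total < k:
                dropped += 1
            else:
                p = 1.0 - math.comb(total - pos, k) / math.comb(total, k) if total - pos >= k else 1.0
                tables.append(p)
    return tables, dropped


def simulate_surveys(pool: IntervalPool, design: SurveyDesign) -> DetectionProbabilityDistribution:
    """Monte-Carlo distribution of detection probability for one survey length.

    Per permutation, one survey per date is drawn uniformly over the date's
    valid starts (pooled across sites, so a site's chance is proportional to
    its number of valid starts); the estimate is positives / dates surveyed.
    A single seeded generator drives all permutations, so identical seeds give
    bit-identical estimate vectors. Dates that cannot hold a survey of the
    requested length are dropped with a warning.
    """
    if pool.is_empty:
        raise ValueError("cannot simulate surveys on an empty interval pool")
    k = design.duration_bins
    tables, dropped = _per_date_tables(pool, k, design.mode)
    if not tables:
        raise ValueError(f"no date in the pool can hold a {design.duration_min}-minute survey")
    if dropped:
        warnings.warn(
            f"{dropped} date(s) lack {design.duration_min} contiguous minutes and were dropped",
            stacklevel=2,
        )
    rng = np.random.default_rng(design.seed)
    n_perm = design.n_permutations
    positives = np.zeros(n_perm, dtype=np.int64)
    if design.mode == "contiguous":
        for flags in tables:
            draws = rng.integers(0, flags.size, size=n_perm)
            positives += flags[draws]
    else:
        for p in tables:
            positives += rng.random(n_perm) < p
    estimates = positives / len(tables)
    return DetectionProbabilityDistribution(
        estimates=estimates,
        mean=float(estimates.mean()),
        q025=float(np.quantile(estimates, 0.025, method=QUANTILE_METHOD)),
        q975=float(np.quantile(estimates, 0.975, method=QUANTILE_METHOD)),
        n_dates=len(tables),
        n_dropped_dates=dropped,
        duration_bins=k,
    )


def analytic_mean(pool: IntervalPool, k: int, mode: str = "contiguous") -> float:
    """Exact expectation of the per-permutation estimate (simulation oracle).

    The estimate averages independent uniform per-date draws, so its
    expectation is the mean over dates of (positive starts / valid starts) —
    no Monte-Carlo involved. Dates without capacity for k are dropped exactly
    as in :func:`simulate_surveys`.
    """
    if pool.is_empty:
        raise ValueError("cannot evaluate an empty interval pool")
    tables, _dropped = _per_date_tables(pool, k, mode)
    if not tables:
        raise ValueError(f"no date in the pool can hold a {5 * k}-minute survey")
    if mode == "contiguous":
        return float(np.mean([flags.mean() for flags in tables]))
    return float(np.mean(tables))
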