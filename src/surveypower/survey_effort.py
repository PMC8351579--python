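"""Minimum survey effort for confidence in absence, and the effort grid.

If each survey independently detects the species with probability ``p``, then
after ``N`` negative surveys the chance of having missed a present species is
``(1 - p)^N``. The minimum number of surveys for 95% confidence in absence is

    N_min = ceil( log(0.05) / log(1 - p) )

and :func:`effort_table` tabulates detection probability and N_min over a
scenario x survey-duration grid, with 95% bounds taken from the permutation
distribution (the low-N bound pairs with the upper p quantile and vice versa).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scenarios import IntervalPool
from .survey_simulator import SurveyDesign, simulate_surveys

EFFORT_COLUMNS = [
    "scenario",
    "duration_min",
    "p_q025",
    "p_mean",
    "p_q975",
    "n_high",
    "n_mean",
    "n_low",
    "n_dates",
    "n_permutations",
]


def min_surveys(p: float, confidence: float = 0.95) -> int:
    """Minimum number of surveys to reach ``confidence`` in absence.

    Rounds up — "at least N surveys" semantics. ``p >= 1`` needs a single
    survey; ``p <= 0`` is an error because absence can then never be
    confirmed. A 1e-9 slack absorbs floating-point noise when the log ratio
    lands on an integer.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if p <= 0:
        raise ValueError("detection probability must be positive to ever confirm absence")
    if p >= 1:
        return 1
    ratio = math.log(1.0 - confidence) / math.log(1.0 - p)
    return max(1, math.ceil(ratio - 1e-9))


def _n_or_nan(p: float, confidence: float) -> float:
    if p <= 0:
        return float("nan")
    return float(min_surveys(p, confidence))


def effort_table(
    pools: Mapping[str, IntervalPool],
    durations_bins: Sequence[int],
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "contiguous",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Detection probability and N_min over a scenario x duration grid.

    One simulation per (scenario, duration) cell; each cell draws its own
    seed from a single root ``SeedSequence`` so the whole grid is reproducible
    and cells are independent. ``n_mean`` maps ``p_mean`` through
    :func:`min_surveys`; ``n_low`` pairs with ``p_q975`` and ``n_high`` with
    ``p_q025``. A cell whose p estimate is zero gets NaN survey counts (with
    a warning): no finite effort can confirm absence there.
    """
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(pools) * len(durations_bins)))
    rows = []
    for name, pool in pools.items():
        for k in durations_bins:
            cell_seed = int(next(children).generate_state(1, dtype=np.uint32)[0])
            design = SurveyDesign(duration_bins=int(k), n_permutations=n_permutations,
                                  seed=cell_seed, mode=mode)
            dist = simulate_surveys(pool, design)
            if dist.mean <= 0 or dist.q025 <= 0:
                warnings.warn(
                    f"scenario {name!r}, duration {design.duration_min} min: zero detection "
                    "probability estimate; survey counts undefined",
                    stacklevel=2,
                )
            rows.append(
                {
                    "scenario": name,
                    "duration_min": design.duration_min,
                    "p_q025": dist.q025,
                    "p_mean": dist.mean,
                    "p_q975": dist.q975,
                    "n_high": _n_or_nan(dist.q025, confidence),
                    "n_mean": _n_or_nan(dist.mean, confidence),
                    "n_low": _n_or_nan(dist.q975, confidence),
                    "n_dates": dist.n_dates,
                    "n_permutations": n_permutations,
                }
            )
    return pd.DataFrame(rows, columns=EFFORT_COLUMNS)


def plot_effort(table: pd.DataFrame, path=None):
    """Two-panel plot of p and N_min vs survey duration, one column per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(dict.fromkeys(table["scenario"]))
    fig, axes = plt.subplots(2, len(scenarios), figsize=(4 * len(scenarios), 6),
                             sharex=True, squeeze=False)
    for j, name in enumerate(scenarios):
        sub = table[table["scenario"] == name].sort_values("duration_min")
        ax = axes[0][j]
        ax.plot(sub["duration_min"], sub["n_mean"], "o-", color="tab:blue")
        ax.fill_between(sub["duration_min"], sub["n_low"], sub["n_high"], alpha=0.2)
        ax.set_title(name)
        if j == 0:
            ax.set_ylabel("surveys for 95% confidence")
        ax = axes[1][j]
        ax.plot(sub["duration_min"], sub["p_mean"], "o-", color="tab:green")
        ax.fill_between(sub["duration_min"], sub["p_q025"], sub["p_q975"], alpha=0.2)
        ax.set_xlabel("survey duration (min)")
        if j == 0:
            ax.set_ylabel("detection probability")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
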