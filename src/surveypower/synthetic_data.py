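"""Synthetic weather, moon, and chorus-detection data generators.

The generators emulate the statistical structure of a multi-year continuous
acoustic monitoring deployment at a small number of pond sites:

* hourly weather with a seasonal + diel temperature cycle and AR(1) noise,
  sparse rain events, a mean-reverting barometric-pressure walk, humidity
  anti-phased with the diel temperature cycle and boosted by rain, and a
  deterministic 29.53-day moon cycle;
* nightly chorus initiation following a logistic model in night temperature,
  24-h cumulative rainfall, and 24-h barometric pressure change, gated by a
  Gaussian breeding-phenology bump peaking in mid-March — warm, wet,
  falling-pressure spring nights chorus most;
* within a chorus night, detections arrive in one or two contiguous bouts of
  5-minute bins (a chorus is a sustained event, not independent per-bin
  noise), so longer surveys genuinely gain less than independent sampling
  would suggest;
* whole recorder-days lost at random (battery/SD failures).

Defaults are calibrated so that, in expectation over seeds, a few percent of
recorded bins are detection-positive, positives fall on a minority (roughly a
fifth to a quarter) of recorded dates, and at least 95% of positives occur in
February-April.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import BIN_MINUTES, BINS_PER_DAY
from .env_features import derive_env_features


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults describe a central-Texas-like deployment."""

    years: tuple = (2015, 2016, 2017, 2018)
    n_sites: int = 2
    season_start: tuple = (1, 1)  # (month, day)
    season_end: tuple = (7, 31)

    # hourly temperature: seasonal cosine + diel cosine + AR(1) noise (deg C)
    temp_mean_c: float = 20.0
    temp_seasonal_amp_c: float = 9.0
    temp_coldest_doy: float = 15.0
    temp_diel_amp_c: float = 4.0
    temp_diel_peak_hour: float = 15.0
    temp_ar1_phi: float = 0.9
    temp_noise_sd_c: float = 1.2

    # relative humidity (%): anti-phased with the diel temperature cycle
    rh_mean_pct: float = 72.0
    rh_diel_amp_pct: float = 14.0
    rh_noise_sd_pct: float = 7.0
    rh_rain_boost_pct: float = 12.0

    # wind (km/h): AR(1) around a mean, clipped at zero
    wind_mean_kmph: float = 8.0
    wind_ar1_phi: float = 0.8
    wind_noise_sd_kmph: float = 3.0

    # rain: per-date event probability, gamma event totals spread over hours
    rain_day_prob: float = 0.22
    rain_event_mm_shape: float = 0.9
    rain_event_mm_scale: float = 9.0
    rain_event_max_hours: int = 5

    # barometric pressure: mean-reverting random walk (opaque station unit)
    pressure_mean: float = 29.5
    pressure_step_sd: float = 0.02
    pressure_reversion: float = 0.02

    # moon: deterministic synodic cycle
    moon_period_d: float = 29.53
    moon_new_moon_epoch: str = "2015-01-20"

    # nightly chorus initiation: logistic in night conditions + phenology bump
    chorus_beta0: float = -9.2
    chorus_beta_temp: float = 0.12
    chorus_beta_cum_precip: float = 0.12
    chorus_beta_dpressure: float = -8.0
    chorus_season_peak_doy: float = 75.0
    chorus_season_sd_days: float = 20.0
    chorus_beta_season: float = 9.4

    # chorus bout structure within a night (night runs 18:00 -> 06:00)
    bout_start_mean_hour: float = 21.5  # clock hours; values > 24 spill past midnight
    bout_start_sd_hours: float = 1.5
    bout_mean_bins: float = 50.0  # geometric mean length, 5-min bins
    bout_detect_prob: float = 0.92
    extra_bout_prob: float = 0.45

    dropout_day_prob: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "rain_day_prob": self.rain_day_prob,
            "bout_detect_prob": self.bout_detect_prob,
            "extra_bout_prob": self.extra_bout_prob,
            "dropout_day_prob": self.dropout_day_prob,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("temp_noise_sd_c", "rh_noise_sd_pct", "wind_noise_sd_kmph",
                     "pressure_step_sd", "bout_start_sd_hours", "chorus_season_sd_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, phi in (("temp_ar1_phi", self.temp_ar1_phi), ("wind_ar1_phi", self.wind_ar1_phi)):
            if not 0 <= phi < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.bout_mean_bins < 1:
            raise ValueError("bout_mean_bins must be >= 1")
        if self.n_sites < 1 or not self.years:
            raise ValueError("need at least one site and one year")

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "SyntheticParams":
        overrides = dict(overrides)
        for key in ("years", "season_start", "season_end"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)


def _season_dates(params: SyntheticParams) -> pd.DatetimeIndex:
    pieces = []
    for year in params.years:
        start = pd.Timestamp(year, *params.season_start)
        end = pd.Timestamp(year, *params.season_end)
        pieces.append(pd.date_range(start, end, freq="D"))
    return pieces[0].append(pieces[1:]) if len(pieces) > 1 else pieces[0]


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + noise[i]
        out[i] = acc
    return out


def generate_environment(params: SyntheticParams, seed: int | None = None):
    """Hourly weather and per-date moon tables for the recording span.

    Returns ``(env, moon)``; reproducible for a fixed seed (default:
    ``params.seed``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dates = _season_dates(params)
    ts = pd.DatetimeIndex(
        np.repeat(dates.values, 24) + np.tile(pd.to_timedelta(np.arange(24), unit="h"), len(dates))
    )
    n = len(ts)
    doy = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    hour = ts.hour.to_numpy()

    seasonal = params.temp_mean_c - params.temp_seasonal_amp_c * np.cos(
        2 * np.pi * (doy - params.temp_coldest_doy) / 365.25
    )
    diel = params.temp_diel_amp_c * np.cos(2 * np.pi * (hour - params.temp_diel_peak_hour) / 24.0)
    temp = seasonal + diel + _ar1(rng, n, params.temp_ar1_phi, params.temp_noise_sd_c)

    # rain: sparse date-level events spread over a few consecutive hours
    precip = np.zeros(n)
    for d in range(len(dates)):
        if rng.random() < params.rain_day_prob:
            total = rng.gamma(params.rain_event_mm_shape, params.rain_event_mm_scale)
            n_hours = int(rng.integers(1, params.rain_event_max_hours + 1))
            start = int(rng.integers(0, 24 - n_hours + 1))
            weights = rng.dirichlet(np.ones(n_hours))
            precip[d * 24 + start : d * 24 + start + n_hours] += total * weights

    rh = (
        params.rh_mean_pct
        - params.rh_diel_amp_pct * np.cos(2 * np.pi * (hour - params.temp_diel_peak_hour) / 24.0)
        + params.rh_rain_boost_pct * (precip > 0)
        + rng.normal(0.0, params.rh_noise_sd_pct, size=n)
    )
    rh = np.clip(rh, 0.0, 100.0)

    wind = np.clip(
        params.wind_mean_kmph + _ar1(rng, n, params.wind_ar1_phi, params.wind_noise_sd_kmph),
        0.0, None,
    )

    # Ornstein-Uhlenbeck-style pressure walk: bounded around the mean
    steps = rng.normal(0.0, params.pressure_step_sd, size=n)
    pressure = np.empty(n)
    p = params.pressure_mean
    for i in range(n):
        p = p + params.pressure_reversion * (params.pressure_mean - p) + steps[i]
        pressure[i] = p

    env = pd.DataFrame(
        {
            "timestamp": ts,
            "temp_c": temp,
            "rh_pct": rh,
            "wind_kmph": wind,
            "pressure": pressure,
            "precip_mm": precip,
        }
    )

    epoch = pd.Timestamp(params.moon_new_moon_epoch)
    phase = ((dates - epoch).days % params.moon_period_d) / params.moon_period_d
    illumination = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    moon = pd.DataFrame({"date": dates, "illumination": illumination})
    return env, moon


def generate_chorus_activity(
    env: pd.DataFrame,
    moon: pd.DataFrame,  # accepted for interface symmetry; the model ignores moon
    params: SyntheticParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Interval table of chorus detections driven by the nightly conditions.

    Per site-night, a chorus initiates with logistic probability evaluated at
    the 22:00 observation of that date (night temperature, cumulative
    rainfall, 24-h pressure change) plus the phenology bump; an initiated
    chorus produces one (sometimes two) contiguous bouts of detection-positive
    bins. Recorder-failure days are absent from the output entirely.
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    fe = derive_env_features(env)
    night = fe[fe["timestamp"].dt.hour == 22].copy()
    night["date"] = night["timestamp"].dt.normalize()
    night = night.set_index("date")

    dates = _season_dates(params)
    doy = dates.dayofyear.to_numpy().astype(float)
    temp = night["temp_c"].reindex(dates).to_numpy()
    cum_precip = night["cum_precip_24h"].reindex(dates).fillna(0.0).to_numpy()
    dpressure = night["pressure_change_24h"].reindex(dates).fillna(0.0).to_numpy()
    temp = np.where(np.isnan(temp), params.temp_mean_c, temp)

    phenology = np.exp(-0.5 * ((doy - params.chorus_season_peak_doy) / params.chorus_season_sd_days) ** 2)
    eta = (
        params.chorus_beta0
        + params.chorus_beta_temp * temp
        + params.chorus_beta_cum_precip * cum_precip
        + params.chorus_beta_dpressure * dpressure
        + params.chorus_beta_season * phenology
    )
    p_chorus = 1.0 / (1.0 + np.exp(-np.clip(eta, -700.0, 700.0)))

    # year-block offsets into one flat bin array per site
    year_of = dates.year.to_numpy()
    date_pos = np.arange(len(dates))
    n_bins_total = len(dates) * BINS_PER_DAY

    sites = [f"S{i + 1}" for i in range(params.n_sites)]
    frames = []
    geometric_p = 1.0 / params.bout_mean_bins
    for site in sites:
        detected = np.zeros(n_bins_total, dtype=np.int64)
        for d in range(len(dates)):
            if rng.random() >= p_chorus[d]:
                continue
            n_bouts = 1 + (rng.random() < params.extra_bout_prob)
            for _ in range(n_bouts):
                start_hour = rng.normal(params.bout_start_mean_hour, params.bout_start_sd_hours)
                start_hour = float(np.clip(start_hour, 18.0, 29.5))  # within the night
                start = d * BINS_PER_DAY + int(start_hour * 60 // BIN_MINUTES)
                length = int(rng.geometric(geometric_p))
                stop = min(start + length, n_bins_total)
                # consecutive-day spillover past midnight stays contiguous in
                # the flat array unless the season (or year block) ends
                if d + 1 == len(dates) or year_of[d + 1] != year_of[d]:
                    stop = min(stop, (d + 1) * BINS_PER_DAY)
                if stop <= start:
                    continue
                hits = rng.random(stop - start) < params.bout_detect_prob
                detected[start:stop] |= hits
        keep_date = rng.random(len(dates)) >= params.dropout_day_prob
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site,
                    "date": np.repeat(dates.values, BINS_PER_DAY),
                    "bin_start": np.tile(
                        np.arange(0, 24 * 60, BIN_MINUTES, dtype=np.int64), len(dates)
                    ),
                    "detected": detected,
                }
            ).loc[np.repeat(keep_date, BINS_PER_DAY)]
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_dataset(params: SyntheticParams, seed: int | None = None):
    """Convenience wrapper: ``(intervals, env, moon)`` from one root seed."""
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    env_seed, chorus_seed = (int(s.generate_state(1, dtype=np.uint32)[0]) for s in root.spawn(2))
    env, moon = generate_environment(params, seed=env_seed)
    intervals = generate_chorus_activity(env, moon, params, seed=chorus_seed)
    return intervals, env, moon


def constant_rate_dataset(
    q: float, n_dates: int, bins_per_date: int, seed: int = 0, site_id: str = "S1",
    start_date: str = "2015-02-01",
) -> pd.DataFrame:
    """Interval table with every bin independently positive at rate ``q``.

    The null-structure oracle for the simulator: no date, season, or bout
    structure at all. Bins fill the evening window from 18:00 (up to 72 bins)
    and then the morning window from 00:00, so each date offers at least one
    contiguous run of ``min(bins_per_date, 72)`` bins.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if not 1 <= bins_per_date <= 144:
        raise ValueError("bins_per_date must be in 1..144 (the nightly window)")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_dates, freq="D")
    evening = np.arange(18 * 60, 24 * 60, BIN_MINUTES, dtype=np.int64)
    morning = np.arange(0, 6 * 60, BIN_MINUTES, dtype=np.int64)
    bins = np.concatenate([evening, morning])[:bins_per_date]
    bins = np.sort(bins)
    return pd.DataFrame(
        {
            "site_id": site_id,
            "date": np.repeat(dates.values, bins_per_date),
            "bin_start": np.tile(bins, n_dates),
            "detected": (rng.random(n_dates * bins_per_date) < q).astype(np.int64),
        }
    )
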