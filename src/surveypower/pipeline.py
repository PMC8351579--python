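"""End-to-end run orchestration: inputs -> features -> pools -> effort grid.

A single config mapping (typically loaded from YAML by the CLI) drives the
whole analysis. All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence``, so a rerun with the same config produces
byte-identical numeric outputs. A ``manifest.json`` records the config hash,
seed, per-stage row counts and warnings for provenance.

Config keys (see also ``examples/pipeline_config.yaml``)::

    seed: 1
    inputs:                  # EITHER paths to the three CSVs ...
      intervals: path.csv
      environment: path.csv
      moon: path.csv
    synthetic:               # ... OR synthetic-generator overrides (may be {})
      years: [2015, 2016]
    scenarios: [random, usfws, optimized]   # presets or rule mappings
    durations_min: [5, 10, ..., 60]         # default 5..60 by 5
    permutations: 1000
    mode: contiguous
    optimize:                # optional threshold search
      variables: [temp_c, cum_precip_24h, pressure_change_24h]
      min_dates: 100
      top_n: 20
      resolution: null
    plots: false
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np

from . import data_model, env_features, scenarios as scen, survey_effort, synthetic_data, threshold_search

log = logging.getLogger("surveypower")

DEFAULT_DURATIONS_MIN = tuple(range(5, 65, 5))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_inputs(config: Mapping, out_dir: Path, seed: int, manifest: dict):
    if "inputs" in config:
        paths = config["inputs"]
        intervals = data_model.read_interval_table(paths["intervals"])
        env = data_model.read_hourly_environment(
            paths["environment"], column_map=config.get("environment_column_map")
        )
        moon = data_model.read_moon(paths["moon"])
        manifest["inputs"] = {k: str(v) for k, v in paths.items()}
    elif "synthetic" in config:
        params = synthetic_data.SyntheticParams.from_dict(config["synthetic"] or {})
        intervals, env, moon = synthetic_data.generate_dataset(params, seed=seed)
        inputs_dir = out_dir / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        data_model.write_interval_table(intervals, inputs_dir / "intervals.csv")
        data_model.write_hourly_environment(env, inputs_dir / "environment.csv")
        data_model.write_moon(moon, inputs_dir / "moon.csv")
        manifest["inputs"] = {"synthetic": params.to_dict()}
    else:
        raise PipelineError("config must provide either 'inputs' (file paths) or 'synthetic' (params)")
    return intervals, env, moon


def run_pipeline(config: Mapping, out_dir) -> Path:
    """Run the full analysis described by ``config`` into ``out_dir``.

    Writes ``effort_table.csv``, ``condition_summary.csv``, optionally
    ``threshold_search.csv`` and ``effort_plot.png``, plus ``manifest.json``.
    Returns ``out_dir``. Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    root = np.random.SeedSequence(seed)
    synth_seed, sim_seed = (int(s.generate_state(1, dtype=np.uint32)[0]) for s in root.spawn(2))
    manifest: dict = {"config_sha256": _config_hash(config), "seed": seed,
                      "stages": {}, "warnings": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage = "inputs"
        try:
            intervals, env, moon = _load_inputs(config, out_dir, synth_seed, manifest)
            manifest["stages"][stage] = {
                "interval_rows": len(intervals), "env_rows": len(env), "moon_rows": len(moon),
            }
            log.info("loaded %d intervals, %d env hours", len(intervals), len(env))

            stage = "features"
            env = env_features.derive_env_features(env)
            summary = env_features.summarize_detection_conditions(intervals, env, moon)
            env_features.write_condition_summary(summary, out_dir / "condition_summary.csv")
            manifest["stages"][stage] = {"summary_rows": len(summary)}

            stage = "scenarios"
            scenario_specs = config.get("scenarios", ["random", "usfws", "optimized"])
            pools = {}
            for spec in scenario_specs:
                scenario = scen.resolve_scenario(spec)
                pools[scenario.name] = scenario.filter_pool(intervals, env, moon)
            manifest["stages"][stage] = {
                name: {"dates": len(pool.dates), "intervals": pool.n_intervals,
                       "positives": pool.n_positive}
                for name, pool in pools.items()
            }

            stage = "effort"
            durations_min = config.get("durations_min", list(DEFAULT_DURATIONS_MIN))
            bad = [d for d in durations_min if d % 5]
            if bad:
                raise PipelineError(f"durations_min must be multiples of 5, got {bad}")
            table = survey_effort.effort_table(
                pools,
                durations_bins=[d // 5 for d in durations_min],
                n_permutations=int(config.get("permutations", 1000)),
                seed=sim_seed,
                mode=config.get("mode", "contiguous"),
            )
            table.to_csv(out_dir / "effort_table.csv", index=False)
            manifest["stages"][stage] = {"cells": len(table)}

            if config.get("plots"):
                survey_effort.plot_effort(table, out_dir / "effort_plot.png")

            if "optimize" in config:
                stage = "optimize"
                opt = config["optimize"]
                peak = scen.peak_period_filter(intervals)
                combos = threshold_search.grid_search(
                    peak, env, moon,
                    variables=opt["variables"],
                    resolution=opt.get("resolution"),
                    min_dates=int(opt.get("min_dates", 0)),
                    top_n=int(opt.get("top_n", 20)),
                )
                threshold_search.combos_to_frame(combos).to_csv(
                    out_dir / "threshold_search.csv", index=False
                )
                manifest["stages"][stage] = {"combos_returned": len(combos)}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

        manifest["warnings"] = [str(w.message) for w in caught]

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
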