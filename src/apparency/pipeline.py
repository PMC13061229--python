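"""End-to-end orchestration: simulate -> score -> apparency -> crossover -> RCT.

One config drives all stages; all randomness flows from a single root seed
through per-stage spawned generators, so an identical config + seed yields
a byte-identical output bundle.  Every threshold and seed is echoed into
the report header for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import compute_apparency, interpolate_bathing_hour, measurements_frame
from .crossover import carryover_values, crossover_table, period_values, screen_sounds
from .io import write_apparency_table, write_events, write_or_table, write_report
from .orienting import (
    DEFAULT_K,
    DEFAULT_MAX_SPAN_MS,
    DEFAULT_THRESHOLD,
    score_events,
)
from .simulate import (
    SimulationParams,
    apply_missingness,
    populations,
    simulate_experiment,
    trial_shaped_scenario,
)
from .trial import run_rct

__all__ = ["RunConfig", "run_all", "score_experiment"]

logger = logging.getLogger("apparency")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "apparency_run"
    seed: int = 0
    # simulation
    n_participants: int = 22
    baseline_rri_ms: float = 850.0
    rri_noise_sd_ms: float = 25.0
    ar1_coeff: float = 0.0
    diurnal_drift_ms: float = 0.0
    p_acc: float = 0.12
    p_dec: float = 0.12
    response_delta_ms: float = 100.0
    missingness: str = "trial_shaped"  # "trial_shaped" | "none"
    # scoring
    k: int = DEFAULT_K
    threshold: float = DEFAULT_THRESHOLD
    max_span_ms: float = DEFAULT_MAX_SPAN_MS
    bathing_interpolation: bool = True
    # screening / trial
    alpha: float = 0.05
    period_orientation: str = "p1_minus_p2"
    write_events_csv: bool = True
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = {k: v for k, v in raw.items() if k not in known}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if extra:
            kwargs["extra"] = extra
        return cls(**kwargs)

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            n_participants=self.n_participants,
            baseline_rri_ms=self.baseline_rri_ms,
            rri_noise_sd_ms=self.rri_noise_sd_ms,
            ar1_coeff=self.ar1_coeff,
            diurnal_drift_ms=self.diurnal_drift_ms,
            p_acc=self.p_acc,
            p_dec=self.p_dec,
            response_delta_ms=self.response_delta_ms,
            seed=self.seed,
        )


def score_experiment(experiment, config: RunConfig) -> pd.DataFrame:
    """Score every event of an experiment; returns the measurements frame."""
    by_key: dict[tuple[str, int], list] = {}
    for e in experiment.events:
        by_key.setdefault((e.participant_id, e.period), []).append(e)
    measurements = []
    for key in sorted(by_key):
        if key not in experiment.beats:
            logger.info("no recording for participant %s period %d", *key)
            continue
        measurements.extend(
            score_events(
                experiment.beats[key],
                sorted(by_key[key], key=lambda e: e.onset_ms),
                k=config.k,
                max_span_ms=config.max_span_ms,
                threshold=config.threshold,
            )
        )
    return measurements_frame(measurements)


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline per config; write the bundle; return the report.

    Stage errors propagate annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "header": {
            "package_version": __version__,
            "seed": config.seed,
            "k": config.k,
            "threshold": config.threshold,
            "max_span_ms": config.max_span_ms,
            "alpha": config.alpha,
            "period_orientation": config.period_orientation,
            "missingness": config.missingness,
            "bathing_interpolation": config.bathing_interpolation,
            "simulation": dataclasses.asdict(config.simulation_params()),
        }
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        experiment = simulate_experiment(config.simulation_params())
        if config.missingness == "trial_shaped":
            scen_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed).spawn(6)[5]
            )
            scenario = trial_shaped_scenario(experiment, scen_rng)
            experiment = apply_missingness(experiment, scenario)
        elif config.missingness == "none":
            from .simulate import MissingnessScenario

            scenario = MissingnessScenario()
        else:
            raise ValueError(f"unknown missingness mode {config.missingness!r}")
        pops = populations(experiment, scenario)
        report["populations"] = {k: sorted(v) for k, v in pops.items()}
        report["groups"] = {p.id: p.group for p in experiment.participants}
        if config.write_events_csv:
            write_events(experiment.events, out_dir / "events.csv")
    except Exception as err:
        raise RuntimeError(f"stage simulate failed: {err}") from err

    try:
        _stage("score")
        scored = score_experiment(experiment, config)
        scored = interpolate_bathing_hour(
            scored, experiment.layout, enabled=config.bathing_interpolation
        )
        write_or_table(
            scored.drop(columns=["daypart", "interpolated"]), out_dir / "or_table.csv"
        )
    except Exception as err:
        raise RuntimeError(f"stage score failed: {err}") from err

    try:
        _stage("apparency")
        per_period = compute_apparency(scored, scope="period")
        write_apparency_table(per_period, out_dir / "apparency.csv")
    except Exception as err:
        raise RuntimeError(f"stage apparency failed: {err}") from err

    try:
        _stage("crossover")
        groups = {p.id: p.group for p in experiment.participants}
        cross_pop = set(pops["crossover"])
        cross_apparency = per_period[
            per_period["participant_id"].isin(cross_pop) & per_period["defined"]
        ]
        carry = crossover_table(
            carryover_values(cross_apparency), groups, alpha=config.alpha
        )
        periodt = crossover_table(
            period_values(cross_apparency, orientation=config.period_orientation),
            groups,
            alpha=config.alpha,
        )
        carry.to_csv(out_dir / "crossover_carryover.csv", index=False)
        periodt.to_csv(out_dir / "crossover_period.csv", index=False)
        retained, excluded = screen_sounds(carry, periodt, alpha=config.alpha)
        report["crossover"] = {
            "n_participants": len(cross_pop),
            "retained_sounds": retained,
            "excluded": excluded,
        }
    except Exception as err:
        raise RuntimeError(f"stage crossover failed: {err}") from err

    try:
        _stage("rct")
        period2 = scored[scored["period"] == 2]
        rct = run_rct(
            period2,
            retained,
            itt_participants=pops["itt"],
            pps_participants=pops["pps"],
            alpha=config.alpha,
        )
        report["rct"] = rct
    except Exception as err:
        raise RuntimeError(f"stage rct failed: {err}") from err

    write_report(report, out_dir / "report.json")
    logger.info("bundle written to %s", out_dir)
    return report
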