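"""Configuration-driven experiment orchestration.

Every named experiment composes generate -> (optionally reconstruct) ->
bin -> analyze and returns a result bundle whose JSON summary is a pure
function of the configuration (all randomness flows from config seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import airflow, geometry as geo, io, multimodal, opticflow, synth
from .circstats import circ_mean_sd

__all__ = ["RunConfig", "run_experiment", "EXPERIMENTS"]

log = logging.getLogger("antkin")


class RunConfig(BaseModel):
    """Reproducible description of one experiment run."""

    experiment: str
    n_bees: int = 10
    seed: int = 0
    profile_overrides: dict = Field(default_factory=dict)
    protocol_params: dict = Field(default_factory=dict)
    alpha: float = 0.05
    alpha_observed_change: float = 0.005
    frames_per_bin: int = 500
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _population(config: RunConfig, **extra):
    overrides = {**config.profile_overrides, **extra}
    return synth.make_bee_population(config.n_bees, config.seed, overrides or None)


def _tethered_airspeed_ramp(config: RunConfig) -> dict:
    protocol = synth.build_protocol(
        "linear_ramp_air", {"fps": 500.0, **config.protocol_params}
    )
    bees = _population(config)
    per_bee_bins = []
    for i, bee in enumerate(bees):
        trace = synth.simulate_iaa_trace(bee, protocol, seed=config.seed * 1000 + i)
        per_bee_bins.append(
            airflow.bin_by_level(trace, protocol, frames_per_bin=config.frames_per_bin)
        )
    region = airflow.locate_dynamic_region(per_bee_bins, alpha=config.alpha)
    mean_bins = [
        airflow.BinSummary(b.level, np.array([bins[j].circ_mean_deg for bins in per_bee_bins]))
        for j, b in enumerate(per_bee_bins[0])
    ]
    fit = airflow.fit_airspeed_sigmoid(mean_bins)
    normalized = airflow.normalize_response(mean_bins)
    return {
        "dynamic_region_mps": [region.lower_mps, region.upper_mps],
        "step_decisions": region.decisions,
        "sigmoid": {
            "amplitude_deg": fit.amplitude_deg,
            "midpoint_mps": fit.midpoint_mps,
            "slope_mps": fit.slope_mps,
        },
        "normalized_means": {str(b.level): b.normalized for b in normalized},
    }


def _free_flight_groundspeed(config: RunConfig) -> dict:
    winds = np.round(np.arange(0.0, 3.5 + 0.25, 0.5), 6)
    table = synth.simulate_free_flight(winds, seed=config.seed)
    speeds = {}
    for w, g in table.groupby("windspeed_mps"):
        pos = g[["x_mm", "y_mm", "z_mm"]].to_numpy()
        ground, air = geo.flight_speeds(pos, fps=500.0, windspeed_vector_mps=(-w, 0, 0))
        speeds[str(w)] = {
            "groundspeed_mps": float(np.mean(np.linalg.norm(ground, axis=1))),
            "airspeed_mps": float(np.mean(np.linalg.norm(air, axis=1))),
        }
    mean_ground = float(np.mean([v["groundspeed_mps"] for v in speeds.values()]))
    return {"per_windspeed": speeds, "mean_groundspeed_mps": mean_ground}


def _opticflow_random_sequence(config: RunConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    bee = synth.make_bee_profile(
        {"noise_sd": 0.1, **config.profile_overrides}, seed=config.seed
    )
    protocol = synth.build_protocol("random_of", {"seed": config.seed, **config.protocol_params})
    sequence = [e.tf_cps for e in protocol.epochs]
    bins = synth.simulate_bin_means(
        bee, sequence, n_per_bin=50, mode="of_ramp", seed=int(rng.integers(2 ** 31))
    )
    records = opticflow.predict_transitions(sequence, bee.of_threshold)
    records = opticflow.classify_observed_transitions(
        bins,
        records,
        alpha=config.alpha_observed_change,
        seed=int(rng.integers(2 ** 31)),
    )
    scores = opticflow.score_predictions(records)
    return {
        "sequence": sequence,
        "threshold_cps": bee.of_threshold,
        "n_scored": scores.n_scored,
        "motion_score": scores.motion_score,
        "direction_score": scores.direction_score,
        "transitions": [
            {
                "tf_from": r.tf_from,
                "tf_to": r.tf_to,
                "predicted_change": r.predicted_change,
                "predicted_direction": r.predicted_direction,
                "observed_change": r.observed_change,
                "observed_direction": r.observed_direction,
            }
            for r in records
        ],
    }


def _opticflow_ramp_threshold(config: RunConfig) -> dict:
    bee = synth.make_bee_profile(
        {"of_gain": 1.5, "noise_sd": 1.0, **config.profile_overrides}, seed=config.seed
    )
    levels = np.arange(1.0, 26.0)
    bins = synth.simulate_bin_means(bee, levels, n_per_bin=50, mode="of_ramp", seed=config.seed)
    result = opticflow.detect_threshold(bins, alpha=config.alpha, seed=config.seed)
    return {
        "threshold_cps": result.threshold_cps,
        "flagged": result.flagged,
        "generator_threshold_cps": bee.of_threshold,
    }


def _opticflow_low_range(config: RunConfig) -> dict:
    protocol = synth.build_protocol("low_range_of", dict(config.protocol_params))
    # slow adaptation: static interleaves re-zero the baseline, so each
    # moving epoch sustains a deflection ~ gain * tf and slope ~ gain
    bees = _population(
        config, of_gain=3.0, noise_sd=0.5, drift_sd=0.0, onset_jump=0.0, adaptation_tau=50.0
    )
    traces = [
        synth.simulate_iaa_trace(bee, protocol, seed=config.seed * 1000 + i)
        for i, bee in enumerate(bees)
    ]
    res = opticflow.low_range_response(traces, protocol, alpha=config.alpha)
    return {
        "levels_cps": [b.level for b in res.bins],
        "slope_deg_per_cps": res.slope_deg_per_cps,
        "step_decisions": res.step_decisions,
    }


def _opticflow_sinusoid(config: RunConfig) -> dict:
    protocol = synth.build_protocol("sinusoid_of", dict(config.protocol_params))
    bee = synth.make_bee_profile(
        {"noise_sd": 0.3, "onset_jump": 0.0, **config.profile_overrides}, seed=config.seed
    )
    trace = synth.simulate_iaa_trace(bee, protocol, seed=config.seed)
    res = opticflow.sinusoid_tracking(trace, protocol)
    return {
        "gain_deg_per_cps": res.gain_deg_per_cps,
        "phase_lag_s": res.phase_lag_s,
        "fit_correlation": res.fit_correlation,
    }


def _regime_covariation(config: RunConfig) -> dict:
    # onset transient zeroed: regime trials probe steady-state set points
    bees = _population(config, of_mode="matched", drift_sd=0.0, onset_jump=0.0)
    rows = []
    for i, bee in enumerate(bees):
        for cond in ("air", "of", "both"):
            protocol = synth.build_protocol(
                "regime", {"transition": "BC", "condition": cond, **config.protocol_params}
            )
            trace = synth.simulate_iaa_trace(bee, protocol, seed=config.seed * 997 + 13 * i)
            df = trace.frames
            for phase, epoch in (("before", 0), ("after", 1)):
                vals = df.loc[df.epoch == epoch, "iaa_deg"].to_numpy()[-config.frames_per_bin :]
                rows.extend(
                    {"bee": bee.bee_id, "condition": cond, "phase": phase, "iaa_deg": v}
                    for v in vals
                )
    res = multimodal.regime_delta_analysis(pd.DataFrame(rows), alpha=config.alpha)
    return {
        "condition_tests": res.condition_tests,
        "anova_p": res.anova.anova_p,
        "zero_significant": dict(res.anova.zero_significant),
    }


def _constant_cue_offset(config: RunConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    levels = [0.3, 0.6, 0.9, 1.2, 1.5, 1.8]
    n = config.n_bees
    offset = 5.0
    alone, with_const = [], []
    for lv in levels:
        base = 90.0 + 3.0 * lv + rng.normal(0, 0.5, n)
        alone.append(airflow.BinSummary(lv, base % 360.0))
        with_const.append(airflow.BinSummary(lv, (base + offset + rng.normal(0, 0.5, n)) % 360.0))
    res = multimodal.offset_classification(alone, with_const, alpha=config.alpha)
    return {
        "verdict": res.verdict,
        "per_level_delta_deg": res.per_level_delta_deg,
        "constancy_p": res.constancy_p,
        "zero_mean_p": res.zero_mean_p,
    }


def _calibration(config: RunConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    scene_gain = float(config.protocol_params.get("scene_gain_cps_per_mps", 2.0))
    v = np.array([1.5, 2.0, 2.5, 3.0])
    tf = scene_gain * v + rng.normal(0, 0.1, v.size)
    res = multimodal.crossmodal_calibrate(v, tf)
    return {
        "gain_cps_per_mps": res.gain_cps_per_mps,
        "speed_at_12cps_mps": float(res.estimate_speed(12.0)),
    }


EXPERIMENTS = {
    "tethered_airspeed_ramp": _tethered_airspeed_ramp,
    "free_flight_groundspeed": _free_flight_groundspeed,
    "opticflow_random_sequence": _opticflow_random_sequence,
    "opticflow_ramp_threshold": _opticflow_ramp_threshold,
    "opticflow_low_range": _opticflow_low_range,
    "opticflow_sinusoid": _opticflow_sinusoid,
    "regime_covariation": _regime_covariation,
    "constant_cue_offset": _constant_cue_offset,
    "crossmodal_calibration": _calibration,
}


def run_experiment(config: RunConfig) -> dict:
    """Execute a named experiment; returns (and optionally writes) a
    deterministic summary bundle tagged with the config hash."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; choose from {sorted(EXPERIMENTS)}"
        )
    log.info("running experiment %s (seed=%d)", config.experiment, config.seed)
    try:
        result = EXPERIMENTS[config.experiment](config)
    except Exception as exc:  # tag failures with the stage
        raise RuntimeError(f"experiment {config.experiment!r} failed: {exc}") from exc
    bundle = {
        "experiment": config.experiment,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "result": result,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_summary(bundle, out / f"{config.experiment}.summary.json")
    return bundle
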