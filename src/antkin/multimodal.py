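"""Combined-cue analyses: regime ΔIAA antagonism, constant-cue offset
classification, and the crossmodal speedometer calibration procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .airflow import BinSummary
from .circstats import (
    PairedAngles,
    circ_mean_sd,
    delta_vs_zero_tests,
    moore_paired_test,
    wrap_diff,
)

__all__ = [
    "RegimeSpec",
    "DEFAULT_REGIMES",
    "RegimeDeltaResult",
    "regime_delta_analysis",
    "OffsetClassification",
    "offset_classification",
    "CalibrationResult",
    "crossmodal_calibrate",
]


@dataclass(frozen=True)
class RegimeSpec:
    label: str
    airspeed_mps: float
    tf_cps: float


DEFAULT_REGIMES = {
    "A": RegimeSpec("A", 0.5, 0.3),
    "B": RegimeSpec("B", 2.5, 0.9),
    "C": RegimeSpec("C", 4.0, 1.8),
}


@dataclass
class RegimeDeltaResult:
    deltas: pd.DataFrame  # rows: bee, condition; columns delta_deg
    condition_tests: dict  # condition -> (moore p, mean delta)
    anova: object  # DeltaVsZeroResult over conditions
    alpha: float


def regime_delta_analysis(
    trials: pd.DataFrame,
    alpha: float = 0.05,
) -> RegimeDeltaResult:
    """ΔIAA analysis of paired before/after stimulus manipulations.

    ``trials`` is tidy with columns bee, condition, phase ("before"/"after")
    and iaa_deg (sample angles). Per bee and condition, ΔIAA is the wrapped
    circular-mean difference after - before. Each condition gets a paired
    circular test of the per-bee before vs after means, and all conditions
    are jointly compared to each other and to a hypothetical zero mean with
    ANOVA + Tukey HSD.
    """
    required = {"bee", "condition", "phase", "iaa_deg"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials must have columns {sorted(required)}")
    conditions = sorted(trials["condition"].unique())
    rows = []
    cond_tests = {}
    for cond in conditions:
        sub = trials[trials["condition"] == cond]
        before, after, bees = [], [], []
        for bee, g in sub.groupby("bee"):
            phases = set(g["phase"])
            if not {"before", "after"}.issubset(phases):
                raise ValueError(f"bee {bee!r} condition {cond!r} missing a phase")
            before.append(circ_mean_sd(g.loc[g.phase == "before", "iaa_deg"]).mean_deg)
            after.append(circ_mean_sd(g.loc[g.phase == "after", "iaa_deg"]).mean_deg)
            bees.append(bee)
        before, after = np.array(before), np.array(after)
        deltas = wrap_diff(after, before)
        res = moore_paired_test(PairedAngles(before, after))
        cond_tests[cond] = {"p": float(res.p), "mean_delta_deg": float(np.mean(deltas))}
        rows.extend(
            {"bee": b, "condition": cond, "delta_deg": float(d)} for b, d in zip(bees, deltas)
        )
    deltas_df = pd.DataFrame(rows)
    groups = {
        cond: deltas_df.loc[deltas_df.condition == cond, "delta_deg"].to_numpy()
        for cond in conditions
    }
    anova = delta_vs_zero_tests(groups, alpha=alpha)
    return RegimeDeltaResult(deltas_df, cond_tests, anova, alpha)


@dataclass
class OffsetClassification:
    verdict: str  # adaptation | uniform_offset | nonuniform
    per_level_delta_deg: Mapping[float, float]
    constancy_p: float  # ANOVA across levels on the deltas
    zero_mean_p: float  # pooled test of delta vs zero
    zero_by_level: Mapping[float, bool]
    alpha: float


def offset_classification(
    curve_alone: Sequence[BinSummary],
    curve_with_constant: Sequence[BinSummary],
    alpha: float = 0.05,
) -> OffsetClassification:
    """Classify how a constant second cue shifts a stimulus-response curve.

    Both curves hold per-bee sample angles at matching levels (samples
    paired by index = bee). Per level, Δ = wrapped difference (with - alone)
    per bee. Verdict:

    - ``adaptation``     : no level's Δ differs from zero,
    - ``uniform_offset`` : levels do not differ from each other (ANOVA)
      while the pooled Δ differs from zero,
    - ``nonuniform``     : otherwise.
    """
    la = [b.level for b in curve_alone]
    lw = [b.level for b in curve_with_constant]
    if la != lw:
        raise ValueError("curves must share identical stimulus levels")
    if len(la) < 3:
        raise ValueError("need at least 3 levels")
    groups = {}
    for ba, bw in zip(curve_alone, curve_with_constant):
        if ba.n != bw.n:
            raise ValueError("paired curves need equal per-level sample counts")
        groups[float(ba.level)] = np.asarray(
            wrap_diff(bw.angles_deg, ba.angles_deg), dtype=float
        )
    result = delta_vs_zero_tests({str(k): v for k, v in groups.items()}, alpha=alpha)
    zero_by_level = {float(k): bool(v) for k, v in result.zero_significant.items()}
    # constancy across levels only (zero group excluded)
    f, constancy_p = sps.f_oneway(*groups.values())
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) < 1e-12:
        zero_mean_p = 1.0 if abs(pooled[0]) < 1e-12 else 0.0
    else:
        zero_mean_p = float(sps.ttest_1samp(pooled, 0.0).pvalue)

    any_level_nonzero = any(zero_by_level.values())
    levels_differ = constancy_p < alpha
    if not any_level_nonzero and zero_mean_p >= alpha:
        verdict = "adaptation"
    elif not levels_differ:
        verdict = "uniform_offset"
    else:
        verdict = "nonuniform"
    per_level = {k: float(np.mean(v)) for k, v in groups.items()}
    return OffsetClassification(
        verdict, per_level, float(constancy_p), zero_mean_p, zero_by_level, alpha
    )


@dataclass(frozen=True)
class CalibrationResult:
    gain_cps_per_mps: float
    intercept_cps: float
    n_used: int
    rms_residual_cps: float
    flagged_nonpositive: bool

    def estimate_speed(self, tf_cps):
        """Airspeed estimate from observed temporal frequency; valid for
        extrapolation beyond the calibration range."""
        return (np.asarray(tf_cps, dtype=float) - self.intercept_cps) / self.gain_cps_per_mps


def crossmodal_calibrate(
    airspeeds_mps,
    observed_tf_cps,
    speed_range=(1.5, 3.0),
    through_origin: bool = True,
) -> CalibrationResult:
    """Calibrate the optic-flow speedometer against absolute airspeed.

    Least-squares line ``tf = k * v`` (through the origin: zero optic flow
    at zero airspeed in steady flight; an intercept variant is available)
    fitted on samples inside the airflow sensor's dynamic ``speed_range``.
    The returned estimator extrapolates speed from temporal frequency over
    an arbitrarily larger range.
    """
    v = np.asarray(airspeeds_mps, dtype=float)
    tf = np.asarray(observed_tf_cps, dtype=float)
    if v.shape != tf.shape or v.ndim != 1:
        raise ValueError("airspeeds and temporal frequencies must be matching 1-D arrays")
    mask = (v >= speed_range[0]) & (v <= speed_range[1])
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 samples inside the calibration range {speed_range}"
        )
    vs, tfs = v[mask], tf[mask]
    if through_origin:
        k = float(np.sum(vs * tfs) / np.sum(vs ** 2))
        b = 0.0
    else:
        k, b = (float(x) for x in np.polyfit(vs, tfs, 1))
    resid = tfs - (k * vs + b)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return CalibrationResult(k, b, int(mask.sum()), rms, flagged_nonpositive=bool(k <= 0))
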