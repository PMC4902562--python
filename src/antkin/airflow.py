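"""Airspeed stimulus-response characterization of the inter-antennal angle:
steady-state binning, plateau normalization, sigmoid fitting, and detection
of the dynamic (significantly-changing) airspeed region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .circstats import PairedAngles, circ_mean_sd, moore_paired_test, wrap_diff

__all__ = [
    "BinSummary",
    "SigmoidFit",
    "DynamicRegion",
    "bin_by_level",
    "normalize_response",
    "fit_airspeed_sigmoid",
    "locate_dynamic_region",
]


@dataclass
class BinSummary:
    """IAA samples and circular summary for one stimulus level."""

    level: float
    angles_deg: np.ndarray
    circ_mean_deg: float = field(default=float("nan"))
    circ_sd_deg: float = field(default=float("nan"))
    n: int = 0
    normalized: float | None = None

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if a.size < 1:
            raise ValueError("a bin needs at least one angle")
        if not np.isfinite(self.level):
            raise ValueError("bin level must be finite")
        object.__setattr__(self, "angles_deg", a)
        m = circ_mean_sd(a)
        self.circ_mean_deg = m.mean_deg
        self.circ_sd_deg = m.sd_deg
        self.n = int(a.size)


@dataclass(frozen=True)
class SigmoidFit:
    lower_plateau_deg: float
    amplitude_deg: float
    midpoint_mps: float
    slope_mps: float
    rms_residual_deg: float

    def __post_init__(self):
        if self.amplitude_deg < 0 or self.slope_mps <= 0:
            raise ValueError("amplitude must be >= 0 and slope > 0")

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        return self.lower_plateau_deg + self.amplitude_deg / (
            1.0 + np.exp((v - self.midpoint_mps) / self.slope_mps)
        )


def bin_by_level(trace, protocol, frames_per_bin: int = 500, level: str = "windspeed_mps"):
    """One BinSummary per stimulus level from the epoch-final frames.

    Uses the last ``frames_per_bin`` frames of each epoch (steady state,
    onset transients excluded); epochs sharing a level are pooled. Epochs
    shorter than the requested count contribute all their frames with a
    warning.

    ``level`` selects the stimulus column: "windspeed_mps" or "tf_cps".
    """
    df = trace.frames
    if "epoch" not in df.columns or level not in df.columns:
        raise ValueError(f"trace must carry 'epoch' and {level!r} columns")
    chunks: dict[float, list[np.ndarray]] = {}
    for _, g in df.groupby("epoch", sort=True):
        lv = float(g[level].iloc[0])
        if len(g) < frames_per_bin:
            warnings.warn(
                f"epoch with level {lv} has {len(g)} frames < frames_per_bin={frames_per_bin};"
                " using all frames",
                stacklevel=2,
            )
            sel = g
        else:
            sel = g.iloc[-frames_per_bin:]
        chunks.setdefault(lv, []).append(sel["iaa_deg"].to_numpy())
    return [
        BinSummary(lv, np.concatenate(parts)) for lv, parts in sorted(chunks.items())
    ]


def normalize_response(
    bins: Sequence[BinSummary],
    slow_range=(0.0, 1.5),
    fast_range=(3.0, 5.5),
) -> list[BinSummary]:
    """Normalize bin means so the slow-plateau mean maps to 1 and the
    fast-plateau mean to 0 (normalized IAA decreases with airspeed).

    ``norm = (IAA - mu_fast) / (mu_slow - mu_fast)``.
    """
    slow = [b.circ_mean_deg for b in bins if slow_range[0] <= b.level <= slow_range[1]]
    fast = [b.circ_mean_deg for b in bins if fast_range[0] <= b.level <= fast_range[1]]
    if not slow or not fast:
        raise ValueError("both plateau ranges must contain at least one bin")
    mu_slow, mu_fast = float(np.mean(slow)), float(np.mean(fast))
    if abs(mu_slow - mu_fast) < 1e-9:
        raise ValueError("degenerate normalization: plateau means are equal")
    out = []
    for b in bins:
        nb = BinSummary(b.level, b.angles_deg)
        nb.normalized = float((b.circ_mean_deg - mu_fast) / (mu_slow - mu_fast))
        out.append(nb)
    return out


def _falling_logistic(v, lower, amplitude, midpoint, slope):
    return lower + amplitude / (1.0 + np.exp((v - midpoint) / slope))


def fit_airspeed_sigmoid(bins: Sequence[BinSummary]) -> SigmoidFit:
    """Least-squares 4-parameter falling logistic on the bin circular means,
    with multistart initialization over midpoint/slope guesses."""
    if len(bins) < 5:
        raise ValueError("need at least 5 bins spanning both plateaus")
    v = np.array([b.level for b in bins], dtype=float)
    y = np.array([b.circ_mean_deg for b in bins], dtype=float)
    amp0 = float(y.max() - y.min())
    lo0 = float(y.min())
    span = float(v.max() - v.min()) or 1.0
    best = None
    for mid0 in np.quantile(v, [0.3, 0.5, 0.7]):
        for k0 in (span / 20.0, span / 8.0, span / 3.0):
            try:
                popt, _ = curve_fit(
                    _falling_logistic,
                    v,
                    y,
                    p0=[lo0, max(amp0, 1e-6), mid0, k0],
                    bounds=([-np.inf, 0.0, v.min() - span, 1e-6], [np.inf, np.inf, v.max() + span, 10 * span]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            resid = y - _falling_logistic(v, *popt)
            rms = float(np.sqrt(np.mean(resid ** 2)))
            if best is None or rms < best[1]:
                best = (popt, rms)
    if best is None:
        raise RuntimeError(
            "sigmoid fit failed to converge from all starts; "
            f"levels span [{v.min()}, {v.max()}], response span {amp0:.3g} deg"
        )
    popt, rms = best
    return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), rms)


@dataclass
class DynamicRegion:
    lower_mps: float | None
    upper_mps: float | None
    decisions: list  # per consecutive step: (level_from, level_to, p, significant, mean_delta)
    alpha: float

    @property
    def empty(self) -> bool:
        return self.lower_mps is None


def locate_dynamic_region(
    per_bee_bins: Sequence[Sequence[BinSummary]],
    alpha: float = 0.05,
) -> DynamicRegion:
    """Find the stimulus interval over which IAA changes with every step.

    For each pair of consecutive levels, the per-bee bin circular means are
    compared with the paired circular test (one pair per bee). Step p-values
    are Holm-corrected so the familywise error over all steps is ``alpha``.
    The dynamic region is the longest run of >= 2 consecutive significant
    steps (ties broken by total |mean step|); isolated single significant
    steps are treated as noise and no run of length >= 2 yields an empty
    region.
    """
    if len(per_bee_bins) < 4:
        raise ValueError("need at least 4 bees for across-bee pairing")
    levels = [b.level for b in per_bee_bins[0]]
    if len(levels) < 2:
        raise ValueError("need at least 2 stimulus levels")
    for bins in per_bee_bins:
        if [b.level for b in bins] != levels:
            raise ValueError("all bees must share the same stimulus levels")

    means = np.array([[b.circ_mean_deg for b in bins] for bins in per_bee_bins])
    n_steps = len(levels) - 1
    raw = np.empty(n_steps)
    deltas = np.empty(n_steps)
    for j in range(n_steps):
        res = moore_paired_test(PairedAngles(means[:, j], means[:, j + 1]))
        raw[j] = res.p
        deltas[j] = float(np.mean(wrap_diff(means[:, j + 1], means[:, j])))
    # Holm step-down correction
    order = np.argsort(raw)
    significant = np.zeros(n_steps, dtype=bool)
    for rank, j in enumerate(order):
        if raw[j] <= alpha / (n_steps - rank):
            significant[j] = True
        else:
            break

    decisions = [
        (levels[j], levels[j + 1], float(raw[j]), bool(significant[j]), float(deltas[j]))
        for j in range(n_steps)
    ]
    # longest run of consecutive significant steps, length >= 2
    best_run = None
    j = 0
    while j < n_steps:
        if significant[j]:
            k = j
            while k + 1 < n_steps and significant[k + 1]:
                k += 1
            length = k - j + 1
            weight = float(np.sum(np.abs(deltas[j : k + 1])))
            if length >= 2 and (
                best_run is None
                or length > best_run[0]
                or (length == best_run[0] and weight > best_run[1])
            ):
                best_run = (length, weight, j, k)
            j = k + 1
        else:
            j += 1
    if best_run is None:
        return DynamicRegion(None, None, decisions, alpha)
    _, _, j, k = best_run
    return DynamicRegion(float(levels[j]), float(levels[k + 1]), decisions, alpha)
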