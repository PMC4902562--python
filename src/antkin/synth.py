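"""Synthetic-data generator carrying the statistical structure the analysis
modules assume: per-bee generative profiles, stimulus protocols, IAA traces,
two-camera landmark projections, and free-flight trajectories.

Generative model of the antennal set point S(t), degrees:

    S(t) = baseline
         - A * logistic((v(t) - v50) / k)          (airflow: antennae forward)
         + G(t)                                     (optic flow: antennae back)
         + onset_jump * exp(-(t - t_on)/tau)        (first optic-flow onset)
         + per-epoch drift                          (slow set-point wander)

with the optic-flow term either an adapting change integrator

    G <- G * exp(-dt/tau) + of_gain * d[clip(phi, -theta, +theta)]

(responds to *changes* in temporal frequency, saturating at the per-bee
threshold theta, and decays back with time constant tau), or, in "matched"
mode, a static contribution A * logistic((v_eq(phi) - v50)/k) with v_eq a
piecewise-linear airspeed-equivalent of temporal frequency anchored at the
paired stimulus regimes — the configuration in which the two cues cancel
exactly when co-varied along the regime pairs.

Measured IAA = S + wrapped-Gaussian frame noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry as geo
from .airflow import BinSummary

__all__ = [
    "BeeProfile",
    "ProfileValidationError",
    "StimulusProtocol",
    "Epoch",
    "IAATrace",
    "REGIME_ANCHORS",
    "make_bee_profile",
    "make_bee_population",
    "build_protocol",
    "simulate_iaa_trace",
    "simulate_bin_means",
    "simulate_geometry",
    "simulate_free_flight",
    "HeadGeometry",
    "default_camera_rig",
]

# (temporal frequency cps, airspeed-equivalent m/s) anchors of the paired
# stimulus regimes A/B/C; used by the "matched" optic-flow response mode.
REGIME_ANCHORS = ((0.0, 0.0), (0.3, 0.5), (0.9, 2.5), (1.8, 4.0))

# Per-epoch set-point drift (deg) applied to simulated bee populations; a
# single noise-free profile keeps drift at 0.
POPULATION_DRIFT_SD = 1.0


class ProfileValidationError(ValueError):
    pass


@dataclass(frozen=True)
class BeeProfile:
    """Generative parameters of one synthetic bee."""

    baseline_iaa: float = 96.0      # deg, set point with no stimulus
    sigmoid_amplitude: float = 35.0  # deg, airflow dynamic range (A)
    sigmoid_midpoint: float = 2.25   # m/s (v50)
    sigmoid_slope: float = 0.14      # m/s (k)
    of_gain: float = 1.0             # deg per cps (gamma)
    of_threshold: float = 10.0       # cps (theta)
    adaptation_tau: float = 4.0      # s (tau)
    noise_sd: float = 0.8            # deg, per-frame wrapped-Gaussian noise
    onset_jump: float = 5.0          # deg, one-time optic-flow onset offset
    drift_sd: float = 0.0            # deg, per-epoch set-point jitter
    of_mode: str = "linear"          # "linear" (clipped change integrator) or "matched"
    bee_id: str = "bee-0"

    def __post_init__(self):
        checks = [
            ("sigmoid_amplitude", self.sigmoid_amplitude >= 0),
            ("of_threshold", self.of_threshold > 0),
            ("noise_sd", self.noise_sd >= 0),
            ("adaptation_tau", self.adaptation_tau > 0),
            ("baseline_iaa", 0.0 < self.baseline_iaa < 180.0),
            ("sigmoid_slope", self.sigmoid_slope > 0),
            ("drift_sd", self.drift_sd >= 0),
            ("of_mode", self.of_mode in ("linear", "matched")),
        ]
        for name, ok in checks:
            if not ok:
                raise ProfileValidationError(
                    f"invalid value for {name}: {getattr(self, name)!r}"
                )

    def airflow_term(self, v_mps):
        """Airflow contribution to the set point (deg, <= 0)."""
        x = (np.asarray(v_mps, dtype=float) - self.sigmoid_midpoint) / self.sigmoid_slope
        return -self.sigmoid_amplitude / (1.0 + np.exp(-x))

    def matched_of_term(self, tf_cps):
        """Static optic-flow contribution in 'matched' mode (deg, >= 0)."""
        tfs = np.array([a[0] for a in REGIME_ANCHORS])
        veq = np.array([a[1] for a in REGIME_ANCHORS])
        phi = np.abs(np.asarray(tf_cps, dtype=float))
        v = np.interp(phi, tfs, veq)
        # extrapolate linearly beyond the last anchor
        slope = (veq[-1] - veq[-2]) / (tfs[-1] - tfs[-2])
        v = np.where(phi > tfs[-1], veq[-1] + slope * (phi - tfs[-1]), v)
        x = (v - self.sigmoid_midpoint) / self.sigmoid_slope
        return self.sigmoid_amplitude / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class Epoch:
    duration_s: float
    windspeed_mps: float
    tf_cps: float  # signed: positive = front-to-back
    spatial_freq_per_cm: float = 0.44

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.spatial_freq_per_cm <= 0:
            raise ValueError("spatial frequency must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    epochs: tuple
    fps: float = 250.0
    kind: str = "custom"

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.epochs) == 0:
            raise ValueError("protocol needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @property
    def total_duration_s(self) -> float:
        return float(sum(e.duration_s for e in self.epochs))

    def to_records(self):
        return [dataclasses.asdict(e) for e in self.epochs]


@dataclass
class IAATrace:
    """Per-frame IAA series with stimulus annotation.

    ``frames`` columns: time_s, iaa_deg (wrapped to [0, 360)), epoch,
    windspeed_mps, tf_cps.
    """

    frames: pd.DataFrame
    bee_id: str = "bee-0"
    protocol_kind: str = "custom"
    seed: int | None = None
    set_point_deg: np.ndarray | None = None  # noise-free ground truth


_PROFILE_DEFAULTS = {f.name: f.default for f in dataclasses.fields(BeeProfile)}


def make_bee_profile(config: Mapping | None = None, seed: int | None = None) -> BeeProfile:
    """Build a profile from a parameter map; missing entries take the
    defaults above. Deterministic: same config + seed -> identical profile.

    ``seed`` only labels the profile (``bee_id`` fallback); stochastic
    population spread lives in :func:`make_bee_population`.
    """
    cfg = dict(config or {})
    unknown = set(cfg) - set(_PROFILE_DEFAULTS)
    if unknown:
        raise ProfileValidationError(f"unknown profile parameters: {sorted(unknown)}")
    if "bee_id" not in cfg and seed is not None:
        cfg["bee_id"] = f"bee-{seed}"
    return BeeProfile(**{**_PROFILE_DEFAULTS, **cfg})


def make_bee_population(
    n_bees: int,
    seed: int,
    overrides: Mapping | None = None,
    baseline_spread: float = 4.0,
    midpoint_spread: float = 0.05,
    drift_sd: float = POPULATION_DRIFT_SD,
) -> list[BeeProfile]:
    """n profiles with between-bee spread in baseline set point and sigmoid
    midpoint, plus per-epoch set-point drift (trial-to-trial wander)."""
    rng = np.random.default_rng(seed)
    bees = []
    for i in range(n_bees):
        cfg = dict(overrides or {})
        cfg.setdefault("baseline_iaa", float(np.clip(96.0 + rng.normal(0, baseline_spread), 60, 130)))
        cfg.setdefault("sigmoid_midpoint", float(2.25 + rng.normal(0, midpoint_spread)))
        cfg.setdefault("drift_sd", drift_sd)
        cfg.setdefault("bee_id", f"bee-{i}")
        bees.append(make_bee_profile(cfg))
    return bees


def _air_epochs(levels, duration, wind_first=True):
    return tuple(Epoch(duration, float(v), 0.0) for v in levels)


def build_protocol(kind: str, params: Mapping | None = None) -> StimulusProtocol:
    """Construct a standard stimulus protocol.

    kinds: linear_ramp_air, random_air, linear_ramp_of, random_of,
    sinusoid_of, low_range_of, regime.
    """
    p = dict(params or {})
    fps = float(p.pop("fps", 250.0))
    if kind == "linear_ramp_air":
        step = float(p.pop("step_mps", 0.5))
        if step <= 0:
            raise ValueError("step must be positive")
        lo, hi = float(p.pop("min_mps", 0.0)), float(p.pop("max_mps", 5.5))
        duration = float(p.pop("epoch_s", 1.0))
        descending = bool(p.pop("descending", False))
        levels = np.round(np.arange(lo, hi + step / 2, step), 9)
        if descending:
            levels = levels[::-1]
        epochs = _air_epochs(levels, duration)
    elif kind == "random_air":
        step = float(p.pop("step_mps", 0.5))
        if step <= 0:
            raise ValueError("step must be positive")
        lo, hi = float(p.pop("min_mps", 0.0)), float(p.pop("max_mps", 5.5))
        duration = float(p.pop("epoch_s", 1.0))
        seed = p.pop("seed", 0)
        levels = np.round(np.arange(lo, hi + step / 2, step), 9)
        levels = np.random.default_rng(seed).permutation(levels)
        epochs = _air_epochs(levels, duration)
    elif kind == "linear_ramp_of":
        step = float(p.pop("step_cps", 1.0))
        if step <= 0:
            raise ValueError("step must be positive")
        lo, hi = float(p.pop("min_cps", 0.0)), float(p.pop("max_cps", 25.0))
        duration = float(p.pop("epoch_s", 1.0))
        descending = bool(p.pop("descending", False))
        levels = np.round(np.arange(lo, hi + step / 2, step), 9)
        if descending:
            levels = levels[::-1]
        epochs = tuple(Epoch(duration, 0.0, float(tf)) for tf in levels)
    elif kind == "random_of":
        seed = p.pop("seed", 0)
        duration = float(p.pop("epoch_s", 1.0))
        levels = np.random.default_rng(seed).permutation(np.arange(1, 26))
        epochs = tuple(Epoch(duration, 0.0, float(tf)) for tf in levels)
    elif kind == "sinusoid_of":
        amplitude = float(p.pop("amplitude_cps", 1.8))
        period = float(p.pop("period_s", 10.0))
        n_periods = int(p.pop("n_periods", 6))
        step_s = float(p.pop("step_s", 0.1))
        if step_s <= 0:
            raise ValueError("step must be positive")
        t = np.arange(0.0, period * n_periods, step_s)
        epochs = tuple(
            Epoch(step_s, 0.0, float(amplitude * np.sin(2 * np.pi * tt / period))) for tt in t
        )
    elif kind == "low_range_of":
        moving_s = float(p.pop("moving_s", 6.0))
        static_s = float(p.pop("static_s", 3.0))
        # six levels: 9 s each (6 s moving + 3 s static) -> 54 s total
        levels = p.pop("levels_cps", (1.8, 1.5, 1.2, 0.9, 0.6, 0.3))
        epochs = []
        for tf in levels:
            epochs.append(Epoch(moving_s, 0.0, float(tf)))
            epochs.append(Epoch(static_s, 0.0, 0.0))
        epochs = tuple(epochs)
    elif kind == "regime":
        transition = str(p.pop("transition", "BC"))  # "BA" or "BC"
        condition = str(p.pop("condition", "both"))  # air | of | both
        duration = float(p.pop("epoch_s", 6.0))
        regimes = {"A": (0.5, 0.3), "B": (2.5, 0.9), "C": (4.0, 1.8)}
        if transition not in ("BA", "BC"):
            raise ValueError("transition must be 'BA' or 'BC'")
        if condition not in ("air", "of", "both"):
            raise ValueError("condition must be 'air', 'of' or 'both'")
        v_b, tf_b = regimes["B"]
        v_t, tf_t = regimes[transition[1]]
        if condition == "air":
            after = (v_t, tf_b)
        elif condition == "of":
            after = (v_b, tf_t)
        else:
            after = (v_t, tf_t)
        epochs = (Epoch(duration, v_b, tf_b), Epoch(duration, *after))
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    if p:
        raise ValueError(f"unused parameters for kind {kind!r}: {sorted(p)}")
    return StimulusProtocol(epochs, fps=fps, kind=kind)


def _frame_stimuli(protocol: StimulusProtocol):
    """Per-frame (time, epoch index, windspeed, tf) arrays."""
    fps = protocol.fps
    n = int(round(protocol.total_duration_s * fps))
    t = np.arange(n) / fps
    bounds = np.cumsum([e.duration_s for e in protocol.epochs])
    epoch_idx = np.searchsorted(bounds, t, side="right")
    epoch_idx = np.clip(epoch_idx, 0, len(protocol.epochs) - 1)
    v = np.array([protocol.epochs[i].windspeed_mps for i in epoch_idx])
    tf = np.array([protocol.epochs[i].tf_cps for i in epoch_idx])
    return t, epoch_idx, v, tf


def simulate_iaa_trace(
    bee: BeeProfile, protocol: StimulusProtocol, seed: int | None = None
) -> IAATrace:
    """Simulate a per-frame IAA trace for one bee under one protocol."""
    rng = np.random.default_rng(seed)
    t, epoch_idx, v, tf = _frame_stimuli(protocol)
    n = t.size
    dt = 1.0 / protocol.fps
    decay = np.exp(-dt / bee.adaptation_tau)

    s = bee.baseline_iaa + bee.airflow_term(v)

    if bee.of_mode == "matched":
        s = s + bee.matched_of_term(tf)
    else:
        theta = bee.of_threshold
        clipped = np.clip(tf, -theta, theta)
        g = np.empty(n)
        prev_clip = 0.0
        g_cur = 0.0
        for i in range(n):
            g_cur = g_cur * decay + bee.of_gain * (clipped[i] - prev_clip)
            prev_clip = clipped[i]
            g[i] = g_cur
        s = s + g

    # one-time onset readjustment at the first non-zero optic-flow frame
    nz = np.nonzero(tf != 0.0)[0]
    if bee.onset_jump != 0.0 and nz.size:
        t0 = t[nz[0]]
        mask = t >= t0
        s = s + np.where(mask, bee.onset_jump * np.exp(-(t - t0) / bee.adaptation_tau), 0.0)

    if bee.drift_sd > 0:
        drift = rng.normal(0.0, bee.drift_sd, size=len(protocol.epochs))
        s = s + drift[epoch_idx]

    iaa = s.copy()
    if bee.noise_sd > 0:
        iaa = iaa + rng.normal(0.0, bee.noise_sd, size=n)
    iaa = iaa % 360.0

    frames = pd.DataFrame(
        {
            "time_s": t,
            "iaa_deg": iaa,
            "epoch": epoch_idx,
            "windspeed_mps": v,
            "tf_cps": tf,
        }
    )
    return IAATrace(frames, bee.bee_id, protocol.kind, seed, set_point_deg=s)


def simulate_bin_means(
    bee: BeeProfile,
    levels: Sequence[float],
    n_per_bin: int,
    mode: str = "air",
    seed: int | None = None,
) -> list[BinSummary]:
    """Statistical shortcut: per-level bins of wrapped-Gaussian samples around
    the closed-form steady-state set point.

    air:          mean = baseline - A * logistic((v - v50)/k)
    of_ramp:      mean = baseline + gamma * min(phi, theta)
    of_low_range: mean = baseline + gamma * phi      (valid for phi <= theta)

    Bins are produced in the order the levels are given (presentation order).
    With ``drift_sd > 0`` each bin additionally receives a set-point offset.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if n_per_bin < 2:
        raise ValueError("n_per_bin must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for lv in levels:
        lv = float(lv)
        if mode == "air":
            mean = bee.baseline_iaa + float(bee.airflow_term(lv))
        elif mode == "of_ramp":
            mean = bee.baseline_iaa + bee.of_gain * min(lv, bee.of_threshold)
        elif mode == "of_low_range":
            mean = bee.baseline_iaa + bee.of_gain * lv
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if bee.drift_sd > 0:
            mean = mean + rng.normal(0.0, bee.drift_sd)
        samples = (mean + rng.normal(0.0, bee.noise_sd, size=n_per_bin)) % 360.0
        out.append(BinSummary(lv, samples))
    return out


@dataclass(frozen=True)
class HeadGeometry:
    """Antennal landmark layout: bases on the x-axis symmetric about the
    midline, tips forward (+y) at the trace IAA, fixed antennal length."""

    base_separation_mm: float = 1.5
    antenna_length_mm: float = 3.0


def default_camera_rig():
    """Dorsal + lateral synthetic pinhole pair (non-parallel axes)."""
    dorsal = geo.pinhole_dlt((0.0, 0.0, 200.0), up=(0.0, 1.0, 0.0))
    lateral = geo.pinhole_dlt((200.0, 30.0, 10.0))
    return dorsal, lateral


_LANDMARKS = ("LB", "LT", "RB", "RT")


def simulate_geometry(
    trace: IAATrace,
    head: HeadGeometry | None = None,
    cameras=None,
    pixel_noise: float = 0.0,
    seed: int | None = None,
):
    """Realize the trace's IAA as 3D landmarks and two-camera projections.

    Returns ``(pixels, truth)`` DataFrames: pixels with columns
    (frame, camera, landmark, x_px, y_px), truth with
    (frame, landmark, X_mm, Y_mm, Z_mm). Landmarks: LB/LT/RB/RT =
    left/right base/tip.
    """
    head = head or HeadGeometry()
    if cameras is None:
        cameras = default_camera_rig()
    if len(cameras) != 2:
        raise ValueError("exactly two cameras required")
    axes = []
    for cam in cameras:
        L = cam.coefficients
        axes.append(L[8:11] / np.linalg.norm(L[8:11]))
    if abs(float(np.dot(axes[0], axes[1]))) > 0.999:
        raise geo.CalibrationError("degenerate camera pair: optical axes near-parallel")

    rng = np.random.default_rng(seed)
    iaa = trace.frames["iaa_deg"].to_numpy()
    half = np.radians(iaa / 2.0)
    bx = head.base_separation_mm / 2.0
    L = head.antenna_length_mm
    lb = np.tile([-bx, 0.0, 0.0], (iaa.size, 1))
    rb = np.tile([bx, 0.0, 0.0], (iaa.size, 1))
    lt = lb + L * np.column_stack([-np.sin(half), np.cos(half), np.zeros_like(half)])
    rt = rb + L * np.column_stack([np.sin(half), np.cos(half), np.zeros_like(half)])

    truth_rows, pixel_rows = [], []
    points = {"LB": lb, "LT": lt, "RB": rb, "RT": rt}
    for name in _LANDMARKS:
        pts = points[name]
        for ci, cam in enumerate(cameras):
            uv = geo.dlt_project(cam, pts)
            if pixel_noise > 0:
                uv = uv + rng.normal(0.0, pixel_noise, size=uv.shape)
            pixel_rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(iaa.size),
                        "camera": ci,
                        "landmark": name,
                        "x_px": uv[:, 0],
                        "y_px": uv[:, 1],
                    }
                )
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(iaa.size),
                    "landmark": name,
                    "X_mm": pts[:, 0],
                    "Y_mm": pts[:, 1],
                    "Z_mm": pts[:, 2],
                }
            )
        )
    pixels = pd.concat(pixel_rows, ignore_index=True).sort_values(
        ["frame", "camera", "landmark"], kind="stable", ignore_index=True
    )
    truth = pd.concat(truth_rows, ignore_index=True).sort_values(
        ["frame", "landmark"], kind="stable", ignore_index=True
    )
    return pixels, truth


def simulate_free_flight(
    windspeeds_mps: Sequence[float],
    groundspeed_target: float = 0.43,
    duration_s: float = 1.0,
    fps: float = 500.0,
    speed_noise_sd: float = 0.02,
    position_noise_mm: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Upwind constant-groundspeed trajectories, one per windspeed.

    The bee holds its ground-frame velocity near ``groundspeed_target``
    regardless of wind (AR(1) fluctuation of SD ``speed_noise_sd``); wind
    blows along -x, flight along +x, so the implied airspeed magnitude is
    ``groundspeed + windspeed``. Positions are in mm with additive
    digitization noise.

    Columns: windspeed_mps, time_s, x_mm, y_mm, z_mm.
    """
    if groundspeed_target <= 0:
        raise ValueError("groundspeed target must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    dt = 1.0 / fps
    rows = []
    for w in windspeeds_mps:
        fluct = np.empty(n)
        ar = 0.9
        innov_sd = speed_noise_sd * np.sqrt(1 - ar ** 2)
        x_prev = rng.normal(0.0, speed_noise_sd)
        for i in range(n):
            x_prev = ar * x_prev + rng.normal(0.0, innov_sd)
            fluct[i] = x_prev
        vx = groundspeed_target + fluct  # m/s, upwind = +x
        pos_x = np.concatenate([[0.0], np.cumsum(vx[:-1]) * dt]) * 1000.0  # mm
        noise = rng.normal(0.0, position_noise_mm, size=(n, 3))
        rows.append(
            pd.DataFrame(
                {
                    "windspeed_mps": float(w),
                    "time_s": np.arange(n) * dt,
                    "x_mm": pos_x + noise[:, 0],
                    "y_mm": noise[:, 1],
                    "z_mm": noise[:, 2],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
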