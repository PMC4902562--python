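"""Circular descriptive statistics and paired tests for angular data.

All public functions take and return angles in **degrees**. The paired test
is a rank-based test on the rectangular (vector) differences of angle pairs,
with significance assessed by within-pair order swaps: either exhaustively
(all 2^n sign patterns, exact) or by seeded Monte-Carlo sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CircSummary",
    "circ_mean_sd",
    "wrap_angle",
    "wrap_diff",
    "PairedAngles",
    "MooreResult",
    "moore_paired_test",
    "DeltaVsZeroResult",
    "delta_vs_zero_tests",
]

# Exhaustive enumeration is used whenever 2^n sign patterns are affordable.
_EXHAUSTIVE_MAX_N = 14


def wrap_angle(angles_deg):
    """Wrap angles to [0, 360)."""
    return np.asarray(angles_deg, dtype=float) % 360.0


def wrap_diff(a_deg, b_deg):
    """Signed circular difference a - b wrapped to (-180, 180]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


class CircSummary(NamedTuple):
    mean_deg: float
    sd_deg: float
    resultant: float


def circ_mean_sd(angles_deg: Sequence[float]) -> CircSummary:
    """Circular mean, circular SD (sqrt(-2 ln R), degrees) and resultant length.

    The mean is flagged as undefined (NaN) when the resultant length is
    numerically zero (e.g. antipodal samples); the SD is then infinite.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circ_mean_sd requires at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = min(float(np.hypot(c, s)), 1.0)
    if r < 1e-12:
        return CircSummary(float("nan"), float("inf"), r)
    mean = float(np.degrees(np.arctan2(s, c))) % 360.0
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(r))))
    return CircSummary(mean, sd, r)


@dataclass(frozen=True)
class PairedAngles:
    """Paired angular observations (alpha_i, beta_i) in degrees."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("alpha and beta must be 1-D arrays of equal length")
        if a.size < 2:
            raise ValueError("paired test needs at least 2 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)

    @property
    def n(self) -> int:
        return int(self.alpha.size)


class MooreResult(NamedTuple):
    r_star: float
    p: float
    n: int
    n_perm: int
    method: str  # "exhaustive" or "montecarlo"


def _rank_average(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def moore_paired_test(
    data: PairedAngles,
    n_perm: int = 1023,
    seed: int | None = None,
    method: str = "auto",
) -> MooreResult:
    """Rank-based paired test for a common displacement between angle pairs.

    For each pair the rectangular difference ``(cos a - cos b, sin a - sin b)``
    is formed; magnitudes are rank-transformed (average ranks on ties) and the
    statistic is ``R* = |sum_i rank_i * u_i| / n^1.5`` with ``u_i`` the unit
    direction of the i-th difference. The null (no systematic displacement)
    is generated by flipping the order within each pair, i.e. negating each
    difference vector.

    Pairs with a numerically zero difference carry no direction and are
    dropped; if every pair is zero, ``R* = 0`` and ``p = 1``.

    ``method``: "exhaustive" (all 2^n patterns, exact p = count/2^n),
    "montecarlo" (p = (count >= observed + 1)/(n_perm + 1)), or "auto"
    (exhaustive whenever n <= 14 or n_perm >= 2^n).
    """
    dc = np.cos(np.radians(data.alpha)) - np.cos(np.radians(data.beta))
    ds = np.sin(np.radians(data.alpha)) - np.sin(np.radians(data.beta))
    r = np.hypot(dc, ds)
    keep = r > 1e-12
    if not np.any(keep):
        return MooreResult(0.0, 1.0, data.n, 0, "degenerate")
    dc, ds, r = dc[keep], ds[keep], r[keep]
    n = int(r.size)
    ranks = _rank_average(r)
    ux = ranks * dc / r
    uy = ranks * ds / r
    scale = n ** 1.5
    r_obs = float(np.hypot(ux.sum(), uy.sum()) / scale)

    if method == "auto":
        method = "exhaustive" if (n <= _EXHAUSTIVE_MAX_N or n_perm >= 2 ** n) else "montecarlo"

    if method == "exhaustive":
        m = 2 ** n
        # all sign patterns as a (m, n) matrix of +-1
        bits = (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 2.0 * bits - 1.0
        r_perm = np.hypot(signs @ ux, signs @ uy) / scale
        p = float(np.mean(r_perm >= r_obs - 1e-9))
        return MooreResult(r_obs, p, n, m, "exhaustive")
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        r_perm = np.hypot(signs @ ux, signs @ uy) / scale
        count = int(np.sum(r_perm >= r_obs - 1e-9))
        p = (count + 1.0) / (n_perm + 1.0)
        return MooreResult(r_obs, float(p), n, n_perm, "montecarlo")
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DeltaVsZeroResult:
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    zero_significant: Mapping[str, bool]
    pairwise_significant: Mapping[tuple, bool] = field(default_factory=dict)
    alpha: float = 0.05


def delta_vs_zero_tests(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    zero_label: str = "zero",
) -> DeltaVsZeroResult:
    """One-way ANOVA + Tukey HSD over labelled samples plus a hypothetical
    zero group.

    The "hypothetical mean of zero" is materialized as a degenerate group of
    exact zeros (size = median group size) so that every group's contrast
    against zero appears in the Tukey table; per-group zero-mean decisions
    are read off those contrasts at ``alpha``.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    arrays = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        arrays[str(name)] = v
    if zero_label in arrays:
        raise ValueError(f"group label {zero_label!r} is reserved")
    n_zero = int(np.median([v.size for v in arrays.values()]))
    arrays[zero_label] = np.zeros(max(n_zero, 2))

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])

    if np.ptp(values) < 1e-12:
        # all observations identical: nothing can differ
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "lower", "upper", "reject"]
        )
        zero_sig = {k: False for k in groups}
        return DeltaVsZeroResult(0.0, 1.0, tukey_df, zero_sig, {}, alpha)

    f, p = sps.f_oneway(*arrays.values())
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    zero_sig: dict[str, bool] = {}
    pair_sig: dict[tuple, bool] = {}
    for _, row in tukey_df.iterrows():
        g1, g2, reject = str(row["group1"]), str(row["group2"]), bool(row["reject"])
        if zero_label in (g1, g2):
            other = g2 if g1 == zero_label else g1
            zero_sig[other] = reject
        else:
            pair_sig[tuple(sorted((g1, g2)))] = reject
    return DeltaVsZeroResult(float(f), float(p), tukey_df, zero_sig, pair_sig, alpha)
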