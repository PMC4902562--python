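"""Two-camera 3D kinematics: DLT calibration, triangulation, inter-antennal
angle, digitization error, and groundspeed/airspeed vector algebra.

Conventions: right-handed coordinates in millimetres, tunnel axis = +x,
upwind flight = +x; angles in degrees; speeds in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CameraCalibration",
    "CalibrationError",
    "ReconstructionError",
    "dlt_calibrate",
    "dlt_project",
    "dlt_reconstruct",
    "pinhole_dlt",
    "AntennaFrame",
    "compute_iaa",
    "digitization_error",
    "flight_speeds",
    "angular_speed",
]


class CalibrationError(ValueError):
    pass


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class CameraCalibration:
    """11-parameter direct linear transformation camera model.

    ``u = (L1 X + L2 Y + L3 Z + L4) / (L9 X + L10 Y + L11 Z + 1)``
    ``v = (L5 X + L6 Y + L7 Z + L8) / (L9 X + L10 Y + L11 Z + 1)``
    """

    coefficients: np.ndarray  # shape (11,)
    residual_px: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float).ravel()
        if c.shape != (11,):
            raise CalibrationError("DLT calibration requires exactly 11 coefficients")
        object.__setattr__(self, "coefficients", c)


def dlt_calibrate(world_points, pixel_points) -> CameraCalibration:
    """Least-squares 11-parameter DLT fit from >=6 non-coplanar correspondences.

    Returns the calibration with its RMS reprojection residual in pixels.
    """
    X = np.asarray(world_points, dtype=float)
    uv = np.asarray(pixel_points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or uv.shape != (X.shape[0], 2):
        raise CalibrationError("expected (N,3) world points and matching (N,2) pixels")
    n = X.shape[0]
    if n < 6:
        raise CalibrationError(f"DLT calibration needs at least 6 points, got {n}")
    # coplanarity makes the design rank-deficient
    centred = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(X).max())) < 3:
        raise CalibrationError("calibration points are coplanar (rank-deficient design)")

    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    x, y, z = X[:, 0], X[:, 1], X[:, 2]
    u, v = uv[:, 0], uv[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2], A[0::2, 3] = x, y, z, 1.0
    A[0::2, 8], A[0::2, 9], A[0::2, 10] = -u * x, -u * y, -u * z
    A[1::2, 4], A[1::2, 5], A[1::2, 6], A[1::2, 7] = x, y, z, 1.0
    A[1::2, 8], A[1::2, 9], A[1::2, 10] = -v * x, -v * y, -v * z
    b[0::2], b[1::2] = u, v
    coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
    reproj = dlt_project(CameraCalibration(coeffs), X)
    residual = float(np.sqrt(np.mean(np.sum((reproj - uv) ** 2, axis=1))))
    return CameraCalibration(coeffs, residual)


def dlt_project(calibration: CameraCalibration, points) -> np.ndarray:
    """Project (N,3) world points (mm) to (N,2) pixel coordinates."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    L = calibration.coefficients
    den = X @ L[8:11] + 1.0
    u = (X @ L[0:3] + L[3]) / den
    v = (X @ L[4:7] + L[7]) / den
    return np.column_stack([u, v])


def dlt_reconstruct(
    calibrations: Sequence[CameraCalibration],
    pixels,
    cond_limit: float = 1e10,
) -> np.ndarray:
    """Triangulate one 3D point (mm) from one pixel observation per camera.

    Linear least squares on the stacked DLT ray equations (2 per camera).
    Raises on fewer than two cameras or a near-degenerate (parallel-ray)
    system.
    """
    cams = list(calibrations)
    if len(cams) < 2:
        raise ReconstructionError("triangulation needs at least two cameras")
    uv = np.asarray(pixels, dtype=float).reshape(len(cams), 2)
    A = np.zeros((2 * len(cams), 3))
    b = np.zeros(2 * len(cams))
    for i, cam in enumerate(cams):
        L = cam.coefficients
        u, v = uv[i]
        A[2 * i] = [L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]]
        A[2 * i + 1] = [L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]]
        b[2 * i] = u - L[3]
        b[2 * i + 1] = v - L[7]
    if np.linalg.cond(A) > cond_limit:
        raise ReconstructionError("near-parallel rays: triangulation is ill-conditioned")
    point, *_ = np.linalg.lstsq(A, b, rcond=None)
    return point


def pinhole_dlt(
    center_mm,
    look_at_mm=(0.0, 0.0, 0.0),
    up=(0.0, 0.0, 1.0),
    focal_px: float = 2000.0,
    principal_px=(512.0, 512.0),
) -> CameraCalibration:
    """Exact DLT coefficients of an ideal pinhole camera (synthetic rigs)."""
    c = np.asarray(center_mm, dtype=float)
    fwd = np.asarray(look_at_mm, dtype=float) - c
    nf = np.linalg.norm(fwd)
    if nf < 1e-12:
        raise CalibrationError("camera center coincides with look-at point")
    fwd = fwd / nf
    upv = np.asarray(up, dtype=float)
    right = np.cross(fwd, upv)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise CalibrationError("up vector parallel to optical axis")
    right /= nr
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])  # world -> camera
    K = np.array(
        [[focal_px, 0.0, principal_px[0]], [0.0, focal_px, principal_px[1]], [0.0, 0.0, 1.0]]
    )
    P = K @ np.hstack([R, (-R @ c)[:, None]])
    if abs(P[2, 3]) < 1e-12:
        raise CalibrationError("degenerate pinhole geometry (principal plane through origin)")
    P = P / P[2, 3]
    coeffs = np.concatenate([P[0, :], P[1, :], P[2, :3]])
    return CameraCalibration(coeffs, 0.0)


@dataclass(frozen=True)
class AntennaFrame:
    """Four digitized 3D landmarks (mm) of one video frame."""

    left_base: np.ndarray
    left_tip: np.ndarray
    right_base: np.ndarray
    right_tip: np.ndarray
    time_s: float = 0.0

    def __post_init__(self):
        for name in ("left_base", "left_tip", "right_base", "right_tip"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)

    def vectors(self):
        return self.left_tip - self.left_base, self.right_tip - self.right_base


def compute_iaa(frame: AntennaFrame) -> float:
    """Inter-antennal angle: angle in [0, 180] degrees between the
    base-to-tip vectors of the left and right antennae."""
    u, v = frame.vectors()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length antenna vector")
    cosang = np.dot(u, v) / (nu * nv)
    sinang = np.linalg.norm(np.cross(u, v)) / (nu * nv)
    return float(np.degrees(np.arctan2(sinang, cosang)))


def digitization_error(frames: Sequence[AntennaFrame]) -> dict:
    """Per-antenna length coefficient of variation (%) across frames.

    The frame-to-frame spread of the (physically constant) antennal length
    measures digitization noise.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    left = np.array([np.linalg.norm(f.left_tip - f.left_base) for f in frames])
    right = np.array([np.linalg.norm(f.right_tip - f.right_base) for f in frames])
    return {
        "left_cv_pct": float(100.0 * left.std(ddof=1) / left.mean()),
        "right_cv_pct": float(100.0 * right.std(ddof=1) / right.mean()),
    }


def flight_speeds(
    positions_mm,
    fps: float,
    windspeed_vector_mps=(0.0, 0.0, 0.0),
    smooth_window: int = 5,
):
    """Per-frame groundspeed and airspeed vectors (m/s) from a tracked point.

    Positions (N,3) in mm at uniform 1/fps intervals are smoothed with a
    centered moving average (edge-truncated) and differentiated; airspeed is
    groundspeed minus windspeed. A stationary track returns airspeed equal
    to minus the wind vector.
    """
    p = np.asarray(positions_mm, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
        raise ValueError("positions must be (N,3) with N >= 2")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    w = int(smooth_window)
    if w > 1:
        kernel = np.ones(w)
        counts = np.convolve(np.ones(p.shape[0]), kernel, mode="same")
        sm = np.column_stack(
            [np.convolve(p[:, k], kernel, mode="same") / counts for k in range(3)]
        )
    else:
        sm = p
    ground = np.gradient(sm, axis=0) * fps / 1000.0  # mm/frame -> m/s
    wind = np.broadcast_to(np.asarray(windspeed_vector_mps, dtype=float), ground.shape)
    air = ground - wind
    return ground, air


def angular_speed(tf_cps: float, spatial_frequency_per_cm: float, distance_cm: float) -> float:
    """Angular image speed (deg/s): linear grating speed per unit distance
    from the eye. ``tf / sf`` is the linear speed (cm/s); dividing by the
    viewing distance gives rad/s."""
    if tf_cps < 0 or spatial_frequency_per_cm <= 0 or distance_cm <= 0:
        raise ValueError("temporal frequency must be >= 0; spatial frequency and distance > 0")
    return float(np.degrees((tf_cps / spatial_frequency_per_cm) / distance_cm))
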