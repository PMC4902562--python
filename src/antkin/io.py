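"""Reading and writing the toolkit's plain-text interchange formats.

CSV dialect: comma-separated, dot decimal, mandatory header row; units are
embedded in column names (deg, m/s = mps, cps, mm, px). Protocols and
analysis summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CameraCalibration
from .synth import Epoch, IAATrace, StimulusProtocol

__all__ = [
    "LandmarkFormatError",
    "read_protocol",
    "write_protocol",
    "read_trace",
    "write_trace",
    "read_landmarks",
    "write_landmarks",
    "read_calibrations",
    "write_calibrations",
    "write_summary",
]

_LANDMARK_COLUMNS = ["frame", "camera", "landmark", "x_px", "y_px"]
_VALID_LANDMARKS = {"LB", "LT", "RB", "RT"}


class LandmarkFormatError(ValueError):
    pass


def write_protocol(protocol: StimulusProtocol, path) -> None:
    payload = {
        "kind": protocol.kind,
        "fps": protocol.fps,
        "epochs": protocol.to_records(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_protocol(path) -> StimulusProtocol:
    payload = json.loads(Path(path).read_text())
    epochs = tuple(Epoch(**e) for e in payload["epochs"])
    return StimulusProtocol(epochs, fps=payload.get("fps", 250.0), kind=payload.get("kind", "custom"))


def write_trace(trace: IAATrace, path) -> None:
    trace.frames.to_csv(path, index=False)


def read_trace(path, bee_id: str = "bee-0") -> IAATrace:
    df = pd.read_csv(path)
    required = {"time_s", "iaa_deg", "epoch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return IAATrace(df, bee_id=bee_id)


def write_landmarks(pixels: pd.DataFrame, path) -> None:
    pixels.to_csv(path, index=False)


def read_landmarks(path):
    """Schema-validated landmark table.

    Returns ``(table, report)``: frames missing any of the four landmarks in
    either camera are excluded and listed in the report; malformed rows are
    reported with 1-based data line numbers.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise LandmarkFormatError(f"{path}: empty file") from None
    missing = set(_LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    report = {"bad_rows": [], "excluded_frames": [], "n_frames": 0}

    bad_mask = pd.Series(False, index=df.index)
    for col in ("frame", "camera", "x_px", "y_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_mask |= coerced.isna()
        df[col] = coerced
    bad_mask |= ~df["landmark"].isin(_VALID_LANDMARKS)
    if bad_mask.any():
        report["bad_rows"] = [int(i) + 1 for i in df.index[bad_mask]]
        df = df[~bad_mask]

    dupes = df.duplicated(subset=["frame", "camera", "landmark"], keep=False)
    if dupes.any():
        raise LandmarkFormatError(
            f"{path}: duplicate (frame, camera, landmark) keys at data lines "
            f"{[int(i) + 1 for i in df.index[dupes]]}"
        )

    cameras = sorted(df["camera"].unique())
    expected = len(cameras) * len(_VALID_LANDMARKS)
    counts = df.groupby("frame").size()
    complete = counts[counts == expected].index
    incomplete = sorted(set(counts.index) - set(complete))
    if incomplete:
        report["excluded_frames"] = [int(f) for f in incomplete]
        df = df[df["frame"].isin(complete)]
    report["n_frames"] = int(df["frame"].nunique())
    return df.reset_index(drop=True), report


def write_calibrations(cameras, path) -> None:
    payload = [
        {"coefficients": list(map(float, c.coefficients)), "residual_px": c.residual_px}
        for c in cameras
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibrations(path):
    payload = json.loads(Path(path).read_text())
    return [CameraCalibration(np.array(c["coefficients"]), c.get("residual_px", 0.0)) for c in payload]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_summary(summary: dict, path) -> None:
    """Deterministic JSON summary (sorted keys, no timestamps)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
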