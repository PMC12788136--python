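"""Trajectory file formats.

Trajectories are stored as long-format CSV (one row per joint per frame)
with a JSON metadata sidecar (``<stem>.meta.json``) carrying fps, units and
the angle convention tag.  Two dialects share the columns
``frame_index, time_s, finger, joint``:

* angle dialect: extra column ``angle_deg``;
* keypoint dialect: extra columns ``x_mm, y_mm, z_mm``.  The wrist keypoint
  is written with ``finger = joint = "wrist"`` ("NA" is reserved for
  missing values).

Missing values are spelled ``NA``.  Frame indices are contiguous from 0 and
``time_s`` must be consistent with the sidecar fps to within 1e-6 s.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .hand import (ANGLE_LABELS, KEYPOINTS, AngleTrajectory,
                   KeypointTrajectory)

CONVENTION_TAG = "interior-angle-deg-180ext"

ANGLE_COLUMNS = ["frame_index", "time_s", "finger", "joint", "angle_deg"]
KEYPOINT_COLUMNS = ["frame_index", "time_s", "finger", "joint",
                    "x_mm", "y_mm", "z_mm"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _split_keypoint(name: str) -> tuple[str, str]:
    if name == "wrist":
        return "wrist", "wrist"
    finger, joint = name.split("_", 1)
    return finger, joint


def write_trajectory(traj: AngleTrajectory | KeypointTrajectory,
                     path, skeleton_ref: str | None = None) -> Path:
    """Write a trajectory as CSV plus its JSON sidecar; returns the CSV
    path.  Values round-trip losslessly (shortest-repr floats) and missing
    samples are written as ``NA``."""
    path = Path(path)
    t = traj.timestamps
    rows = []
    if isinstance(traj, AngleTrajectory):
        kind, units = "angle", {"angle_deg": "deg", "time_s": "s"}
        for i in range(traj.n_frames):
            for j, (f, jt) in enumerate(traj.joints):
                rows.append((i, t[i], f, jt, traj.angles[i, j]))
        df = pd.DataFrame(rows, columns=ANGLE_COLUMNS)
    elif isinstance(traj, KeypointTrajectory):
        kind, units = "keypoint", {"x_mm": "mm", "time_s": "s"}
        for i in range(traj.n_frames):
            for k, name in enumerate(traj.keypoints):
                f, jt = _split_keypoint(name)
                rows.append((i, t[i], f, jt, *traj.positions[i, k]))
        df = pd.DataFrame(rows, columns=KEYPOINT_COLUMNS)
    else:
        raise ParseError(f"cannot serialise object of type {type(traj)!r}")
    df.to_csv(path, index=False, na_rep="NA")
    meta = {"kind": kind, "fps": traj.fps, "units": units,
            "convention": CONVENTION_TAG, "skeleton": skeleton_ref,
            "n_frames": traj.n_frames}
    _sidecar_path(path).write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path


def _read_meta(path: Path, fps: float | None) -> float:
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if fps is None:
            fps = meta.get("fps")
    if fps is None:
        raise ParseError(
            f"no fps available: sidecar {side.name} missing and no explicit "
            f"fps given")
    return float(fps)


def _frame_grid(df: pd.DataFrame, fps: float, path: Path) -> np.ndarray:
    frames = np.sort(df["frame_index"].unique())
    if frames[0] != 0 or not np.array_equal(frames,
                                            np.arange(len(frames))):
        raise ParseError(f"{path.name}: frame_index not contiguous from 0")
    t = df.groupby("frame_index")["time_s"].first().to_numpy(dtype=float)
    expected = t[0] + frames / fps
    bad = np.nonzero(np.abs(t - expected) > 1e-6)[0]
    if bad.size:
        raise ParseError(
            f"time_s inconsistent with fps={fps} at frame {bad[0]}",
            line=int(bad[0]) + 2)
    return t


def read_trajectory(path, fps: float | None = None
                    ) -> AngleTrajectory | KeypointTrajectory:
    """Read a trajectory CSV (either dialect), using the JSON sidecar (or an
    explicit ``fps``) for the timebase."""
    path = Path(path)
    fps = _read_meta(path, fps)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    cols = set(df.columns)
    if not {"frame_index", "time_s", "finger", "joint"}.issubset(cols):
        raise ParseError(
            f"{path.name}: expected the angle dialect {ANGLE_COLUMNS} or the "
            f"keypoint dialect {KEYPOINT_COLUMNS}, got {sorted(cols)}")
    if "angle_deg" in cols:
        return _read_angle(df, fps, path)
    if {"x_mm", "y_mm", "z_mm"}.issubset(cols):
        return _read_keypoint(df, fps, path)
    raise ParseError(
        f"{path.name}: no value columns; expected 'angle_deg' (angle "
        f"dialect) or 'x_mm, y_mm, z_mm' (keypoint dialect)")


def _read_angle(df: pd.DataFrame, fps: float, path: Path) -> AngleTrajectory:
    t = _frame_grid(df, fps, path)
    labels = sorted({(str(f), str(j)) for f, j in zip(df["finger"], df["joint"])},
                    key=lambda lab: ANGLE_LABELS.index(lab)
                    if lab in ANGLE_LABELS else -1)
    unknown = [lab for lab in labels if lab not in ANGLE_LABELS]
    if unknown:
        raise ParseError(f"{path.name}: unknown joint names {unknown}")
    n = len(t)
    angles = np.full((n, len(labels)), np.nan)
    col = {lab: j for j, lab in enumerate(labels)}
    idx = df["frame_index"].to_numpy(dtype=int)
    jidx = np.array([col[(str(f), str(j))]
                     for f, j in zip(df["finger"], df["joint"])])
    angles[idx, jidx] = df["angle_deg"].to_numpy(dtype=float)
    return AngleTrajectory(angles, fps=fps, joints=tuple(labels),
                           timestamps=t)


def _read_keypoint(df: pd.DataFrame, fps: float,
                   path: Path) -> KeypointTrajectory:
    t = _frame_grid(df, fps, path)
    names = []
    for f, j in zip(df["finger"], df["joint"]):
        name = "wrist" if str(j) == "wrist" else f"{f}_{j}"
        if name not in KEYPOINTS:
            raise ParseError(f"{path.name}: unknown keypoint {f}/{j}")
        names.append(name)
    present = [k for k in KEYPOINTS if k in set(names)]
    kidx = {k: i for i, k in enumerate(present)}
    n = len(t)
    pos = np.full((n, len(present), 3), np.nan)
    idx = df["frame_index"].to_numpy(dtype=int)
    rows = np.array([kidx[name] for name in names])
    pos[idx, rows, :] = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return KeypointTrajectory(pos, fps=fps, keypoints=tuple(present),
                              timestamps=t)


def count_missing(traj: AngleTrajectory | KeypointTrajectory) -> int:
    """Number of missing samples (NaN angles, or keypoints with any NaN
    coordinate)."""
    if isinstance(traj, AngleTrajectory):
        return int(np.sum(~np.isfinite(traj.angles)))
    return int(np.sum(~np.isfinite(traj.positions).all(axis=2)))
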