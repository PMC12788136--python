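"""Angle extraction, MCP offset correction, angular velocity, ROM, resampling.

All angles are interior angles in degrees (180 deg = full extension), all
velocities deg/s.  Missing samples are NaN throughout and are excluded,
with counts, rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hand import (ANGLE_JOINTS, FINGERS, AngleTrajectory, HandSkeleton,
                   KeypointTrajectory)

_COINCIDENT_MM = 1e-9


@dataclass
class AngularVelocityTrajectory:
    """Signed angular velocity (deg/s) per joint per frame.

    Same frame count and timebase as the source angle trajectory; NaN where
    the source angle (or a neighbour used by the difference stencil) is
    missing.
    """

    velocities: np.ndarray  # (n_frames, n_joints)
    fps: float
    joints: tuple[tuple[str, str], ...]
    timestamps: np.ndarray

    def column(self, finger: str, joint: str) -> np.ndarray:
        return self.velocities[:, self.joints.index((finger, joint))]


@dataclass
class RomTable:
    """Per-joint (min, max) angle over the non-missing frames."""

    rom: dict[tuple[str, str], tuple[float, float] | None]
    n_frames: int
    n_missing: dict[tuple[str, str], int] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]):
        return self.rom[key]


def extract_joint_angles(traj: KeypointTrajectory,
                         skeleton: HandSkeleton) -> AngleTrajectory:
    """Interior joint angles from a 3D keypoint trajectory.

    The angle at each joint is the angle between the vectors from the joint
    to its proximal and distal neighbours (arccos of the clamped normalised
    dot product), which equals 180 deg minus the bend: collinear segments
    give 180.  Fingers whose five keypoints (wrist, MCP, PIP, DIP, TIP) are
    all present in the trajectory's keypoint set are reported; adjacent
    keypoints closer than 1e-9 mm make that joint's angle missing.
    """
    kp = set(traj.keypoints)
    if "wrist" not in kp:
        raise ValidationError("trajectory has no wrist keypoint")
    fingers = [f for f in FINGERS
               if all(f"{f}_{p}" in kp for p in ("mcp", "pip", "dip", "tip"))]
    if not fingers:
        raise ValidationError(
            "no finger has the full wrist/MCP/PIP/DIP/TIP keypoint chain")

    T = traj.n_frames
    labels: list[tuple[str, str]] = []
    cols: list[np.ndarray] = []
    for f in fingers:
        chain = [traj.point("wrist")] + [traj.point(f"{f}_{p}")
                                         for p in ("mcp", "pip", "dip", "tip")]
        for i, joint in enumerate(ANGLE_JOINTS):  # joint sits at chain[i+1]
            prox = chain[i] - chain[i + 1]
            dist = chain[i + 2] - chain[i + 1]
            np_ = np.linalg.norm(prox, axis=1)
            nd = np.linalg.norm(dist, axis=1)
            ok = (np_ > _COINCIDENT_MM) & (nd > _COINCIDENT_MM)
            cosang = np.full(T, np.nan)
            dot = np.einsum("ij,ij->i", prox, dist)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang[ok] = np.clip(dot[ok] / (np_[ok] * nd[ok]), -1.0, 1.0)
            labels.append((f, joint))
            cols.append(np.degrees(np.arccos(cosang)))
    return AngleTrajectory(np.column_stack(cols), fps=traj.fps,
                           joints=tuple(labels), timestamps=traj.timestamps)


def apply_mcp_offset(angles: AngleTrajectory, offset_deg: float = 40.0,
                     clamp: bool = False) -> AngleTrajectory:
    """Add a constant correction to every MCP angle.

    Compensates a wrist marker mounted above the skin, which biases the
    measured MCP angle; the default of +40 deg matches that correction.
    Values pushed past 180 deg are kept (clamping would bias downstream
    error metrics) and counted in ``overextension_count`` on the result,
    unless ``clamp=True``.
    """
    if not np.isfinite(offset_deg):
        raise ValidationError("offset must be finite")
    out = angles.angles.copy()
    mcp = [i for i, (_, j) in enumerate(angles.joints) if j == "mcp"]
    out[:, mcp] += offset_deg
    over = int(np.sum(out[:, mcp] > 180.0))
    if clamp:
        out[:, mcp] = np.minimum(out[:, mcp], 180.0)
    return AngleTrajectory(out, fps=angles.fps, joints=angles.joints,
                           timestamps=angles.timestamps,
                           overextension_count=over)


def angular_velocity(angles: AngleTrajectory,
                     smooth_window: int | None = None) -> AngularVelocityTrajectory:
    """Angular velocity by finite differences, scaled to deg/s.

    Central differences on interior frames, one-sided at the endpoints
    (exact for linear signals).  ``smooth_window`` applies an optional
    moving-average pre-filter of that many frames before differentiation,
    for noisy series.  A frame whose stencil touches a missing angle gets a
    missing velocity.
    """
    if angles.n_frames < 2:
        raise ValidationError("need >= 2 frames for angular velocity")
    a = angles.angles
    if smooth_window is not None:
        if smooth_window < 1:
            raise ValidationError("smooth_window must be >= 1")
        k = np.ones(smooth_window) / smooth_window
        sm = np.empty_like(a)
        for j in range(a.shape[1]):
            sm[:, j] = np.convolve(a[:, j], k, mode="same")
            # renormalise the shrunk edge windows
            norm = np.convolve(np.ones(len(a)), k, mode="same")
            sm[:, j] /= norm
        a = sm
    v = np.gradient(a, axis=0, edge_order=1) * angles.fps
    # mask stencil neighbourhoods of missing samples
    miss = ~np.isfinite(angles.angles)
    bad = miss.copy()
    bad[1:] |= miss[:-1]
    bad[:-1] |= miss[1:]
    v[bad] = np.nan
    return AngularVelocityTrajectory(v, fps=angles.fps, joints=angles.joints,
                                     timestamps=angles.timestamps)


def compute_rom(angles: AngleTrajectory) -> RomTable:
    """Per-joint range of motion: (min, max) over non-missing frames.

    A joint with no non-missing frame is marked unavailable (None).
    """
    rom: dict[tuple[str, str], tuple[float, float] | None] = {}
    missing: dict[tuple[str, str], int] = {}
    for i, lab in enumerate(angles.joints):
        col = angles.angles[:, i]
        ok = np.isfinite(col)
        missing[lab] = int(np.sum(~ok))
        rom[lab] = (float(col[ok].min()), float(col[ok].max())) if ok.any() else None
    return RomTable(rom, n_frames=angles.n_frames, n_missing=missing)


def _interp_with_gaps(t_new: np.ndarray, t: np.ndarray,
                      y: np.ndarray) -> np.ndarray:
    """Linear interpolation that propagates NaN: a target time whose
    bracketing source samples include a NaN comes out NaN (a target exactly
    on a finite source sample only needs that sample)."""
    nan = ~np.isfinite(y)
    if not nan.any():
        return np.interp(t_new, t, y)
    out = np.interp(t_new, t, np.where(nan, 0.0, y))
    idx = np.searchsorted(t, t_new, side="right")
    lo = np.clip(idx - 1, 0, len(t) - 1)
    hi = np.clip(idx, 0, len(t) - 1)
    exact = np.abs(t_new - t[lo]) <= 1e-12
    bad = np.where(exact, nan[lo], nan[lo] | nan[hi])
    return np.where(bad, np.nan, out)


def resample(traj: AngleTrajectory | KeypointTrajectory,
             target_fps: float):
    """Linearly resample a trajectory onto a uniform grid at ``target_fps``
    spanning the original time range.  Missing spans propagate as missing."""
    if target_fps <= 0:
        raise ValidationError("target_fps must be > 0")
    t = traj.timestamps
    if len(t) < 2:
        raise ValidationError("need >= 2 frames to resample")
    n_new = int(np.floor((t[-1] - t[0]) * target_fps + 1e-9)) + 1
    if n_new < 2:
        raise ValidationError(
            "target grid does not overlap the source time range")
    t_new = t[0] + np.arange(n_new) / target_fps
    if isinstance(traj, AngleTrajectory):
        cols = [_interp_with_gaps(t_new, t, traj.angles[:, j])
                for j in range(traj.angles.shape[1])]
        return AngleTrajectory(np.column_stack(cols), fps=target_fps,
                               joints=traj.joints, timestamps=t_new)
    if isinstance(traj, KeypointTrajectory):
        P = traj.positions
        out = np.empty((n_new, P.shape[1], 3))
        for k in range(P.shape[1]):
            for d in range(3):
                out[:, k, d] = _interp_with_gaps(t_new, t, P[:, k, d])
        return KeypointTrajectory(out, fps=target_fps,
                                  keypoints=traj.keypoints, timestamps=t_new)
    raise ValidationError(f"cannot resample object of type {type(traj)!r}")
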