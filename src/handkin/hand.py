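"""Hand skeleton model, trajectory containers and forward kinematics.

The hand is modelled as 21 keypoints: the wrist plus, for each of the five
fingers, a four-joint chain wrist -> MCP -> PIP -> DIP -> TIP.  The thumb's
anatomical TM-MCP-IP joints occupy the same MCP/PIP/DIP slots as the other
fingers, so every finger exposes exactly three interior angles.

Angles follow the interior-angle convention: the angle at a joint is measured
between the incoming and outgoing bone segments *through the hand*, so 180
degrees is full extension and flexion decreases the angle.  Each finger
flexes in a single plane, given by the skeleton's per-finger unit normal;
abduction/adduction is out of scope.

Positions are millimetres, angles degrees, time seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError

FINGERS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "pinky")
ANGLE_JOINTS: tuple[str, ...] = ("mcp", "pip", "dip")
SEGMENTS: tuple[str, ...] = ("wrist_mcp", "mcp_pip", "pip_dip", "dip_tip")

#: keypoint names in canonical order: wrist first, then per finger MCP..TIP
KEYPOINTS: tuple[str, ...] = ("wrist",) + tuple(
    f"{f}_{j}" for f in FINGERS for j in ("mcp", "pip", "dip", "tip")
)

#: (finger, joint) labels for the 15 interior angles, canonical order
ANGLE_LABELS: tuple[tuple[str, str], ...] = tuple(
    (f, j) for f in FINGERS for j in ANGLE_JOINTS
)

_EPS_UNIT = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < _EPS_UNIT:
        raise ValidationError("cannot normalise a near-zero vector")
    return np.asarray(v, dtype=float) / n


def _default_directions() -> dict[str, np.ndarray]:
    # Fingers fan out in the x-y palm plane; the exact splay is irrelevant to
    # every angle-based quantity and only sets the resting keypoint layout.
    splay_deg = {"thumb": 45.0, "index": 12.0, "middle": 0.0,
                 "ring": -12.0, "pinky": -24.0}
    out = {}
    for f, a in splay_deg.items():
        r = math.radians(a)
        out[f] = np.array([math.sin(r), math.cos(r), 0.0])
    return out


@dataclass(frozen=True)
class HandSkeleton:
    """Kinematic tree of the 21-keypoint hand.

    Parameters
    ----------
    bone_lengths
        ``{(finger, segment): length_mm}`` for the 20 segments
        (5 fingers x wrist_mcp, mcp_pip, pip_dip, dip_tip), all > 0.
    directions
        Unit ray of each finger at full extension, from the wrist.
    finger_planes
        Unit normal of each finger's flexion plane (perpendicular to the
        finger ray).
    root
        Wrist position in mm.  Configurable but irrelevant to all
        angle-based metrics.
    """

    bone_lengths: dict[tuple[str, str], float]
    directions: dict[str, np.ndarray]
    finger_planes: dict[str, np.ndarray]
    root: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        for f in FINGERS:
            for s in SEGMENTS:
                L = self.bone_lengths.get((f, s))
                if L is None:
                    raise ValidationError(f"missing bone length for {f}/{s}")
                if not np.isfinite(L) or L <= 0:
                    raise ValidationError(
                        f"bone length for segment {f}/{s} must be finite and "
                        f"> 0, got {L!r}")
        for f in FINGERS:
            d = np.asarray(self.directions[f], dtype=float)
            n = np.asarray(self.finger_planes[f], dtype=float)
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ValidationError(f"direction of {f} is not unit length")
            if abs(np.linalg.norm(n) - 1.0) > 1e-9:
                raise ValidationError(
                    f"flexion-plane normal of {f} is not unit length")
            if abs(float(d @ n)) > 1e-9:
                raise ValidationError(
                    f"flexion-plane normal of {f} is not perpendicular to "
                    f"the finger ray")

    @property
    def n_keypoints(self) -> int:
        return len(KEYPOINTS)

    def segment_length(self, finger: str, segment: str) -> float:
        return self.bone_lengths[(finger, segment)]

    def with_root(self, root: Sequence[float]) -> "HandSkeleton":
        return HandSkeleton(self.bone_lengths, self.directions,
                            self.finger_planes, np.asarray(root, dtype=float))


def _load_default_lengths() -> dict[tuple[str, str], float]:
    text = resources.files("handkin.data").joinpath(
        "default_skeleton.yaml").read_text()
    doc = yaml.safe_load(text)
    return {(f, s): float(L) for f, segs in doc["fingers"].items()
            for s, L in segs.items()}


def build_default_skeleton(
    bone_length_spec: Mapping[tuple[str, str], float] | Mapping[str, Mapping[str, float]] | None = None,
    root: Sequence[float] = (0.0, 0.0, 0.0),
) -> HandSkeleton:
    """Build a 21-keypoint skeleton, filling unspecified segments from the
    packaged adult-hand length table.

    ``bone_length_spec`` accepts either flat ``{(finger, segment): mm}`` or
    nested ``{finger: {segment: mm}}`` form.  Lengths are configuration, not
    anatomical claims.
    """
    lengths = _load_default_lengths()
    if bone_length_spec:
        flat: dict[tuple[str, str], float] = {}
        for k, v in bone_length_spec.items():
            if isinstance(k, tuple):
                flat[k] = v  # type: ignore[index]
            else:
                for s, L in v.items():  # nested form
                    flat[(k, s)] = L
        for (f, s), L in flat.items():
            if f not in FINGERS or s not in SEGMENTS:
                raise ValidationError(f"unknown segment {f}/{s}")
            if not np.isfinite(L) or L <= 0:
                raise ValidationError(
                    f"bone length for segment {f}/{s} must be finite and "
                    f"> 0, got {L!r}")
            lengths[(f, s)] = float(L)
    dirs = _default_directions()
    zhat = np.array([0.0, 0.0, 1.0])
    planes = {f: _unit(np.cross(dirs[f], zhat)) for f in FINGERS}
    return HandSkeleton(lengths, dirs, planes, np.asarray(root, dtype=float))


def load_skeleton(path) -> HandSkeleton:
    """Load a skeleton from a ``{fingers: {finger: {segment: mm}}}`` YAML or
    JSON document, with optional ``root: [x, y, z]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    spec = doc.get("fingers", {})
    root = doc.get("root", (0.0, 0.0, 0.0))
    return build_default_skeleton(spec, root=root)


# ---------------------------------------------------------------------------
# frames and trajectories


@dataclass(frozen=True)
class JointAngleFrame:
    """Interior angles (degrees) for one time instant.

    Missing angles are NaN.  Values are expected in (0, 180]; values above
    180 can only arise from offset correction and are carried, flagged,
    rather than clamped.
    """

    angles: dict[tuple[str, str], float]
    timestamp: float = 0.0

    def __post_init__(self):
        if self.timestamp < 0:
            raise ValidationError("timestamp must be >= 0")
        for k in self.angles:
            if k not in ANGLE_LABELS:
                raise ValidationError(f"unknown joint label {k}")


@dataclass(frozen=True)
class KeypointFrame:
    """3D keypoint positions (mm) for one time instant; NaN rows = missing."""

    positions: dict[str, np.ndarray]
    timestamp: float = 0.0

    def __post_init__(self):
        if self.timestamp < 0:
            raise ValidationError("timestamp must be >= 0")
        for k in self.positions:
            if k not in KEYPOINTS:
                raise ValidationError(f"unknown keypoint {k}")


def _check_timebase(n: int, fps: float, timestamps: np.ndarray | None) -> np.ndarray:
    if fps <= 0 or not np.isfinite(fps):
        raise ValidationError(f"fps must be > 0, got {fps!r}")
    t = np.arange(n, dtype=float) / fps if timestamps is None \
        else np.asarray(timestamps, dtype=float)
    if t.shape != (n,):
        raise ValidationError("timestamps must match the frame count")
    if n > 1 and np.any(np.diff(t) <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    expected = t[0] + np.arange(n) / fps
    if np.max(np.abs(t - expected), initial=0.0) > 1e-6:
        raise ValidationError("timestamps inconsistent with fps (> 1e-6 s)")
    return t


@dataclass
class AngleTrajectory:
    """Time series of interior joint angles at a fixed frame rate.

    ``angles`` has shape ``(n_frames, n_joints)`` in degrees, NaN = missing;
    ``joints`` labels the columns with ``(finger, joint)`` pairs.
    """

    angles: np.ndarray
    fps: float
    joints: tuple[tuple[str, str], ...] = ANGLE_LABELS
    timestamps: np.ndarray | None = None
    overextension_count: int = 0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != len(self.joints):
            raise ValidationError(
                "angles must be (n_frames, n_joints) matching the labels")
        for j in self.joints:
            if tuple(j) not in ANGLE_LABELS:
                raise ValidationError(f"unknown joint label {j}")
        self.joints = tuple(tuple(j) for j in self.joints)
        self.timestamps = _check_timebase(len(self.angles), self.fps,
                                          self.timestamps)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def column(self, finger: str, joint: str) -> np.ndarray:
        return self.angles[:, self.joints.index((finger, joint))]

    def frame(self, i: int) -> JointAngleFrame:
        return JointAngleFrame(
            {lab: float(a) for lab, a in zip(self.joints, self.angles[i])},
            timestamp=float(self.timestamps[i]))


@dataclass
class KeypointTrajectory:
    """Time series of 3D keypoint positions (mm) at a fixed frame rate.

    ``positions`` has shape ``(n_frames, n_keypoints, 3)``, NaN = missing.
    """

    positions: np.ndarray
    fps: float
    keypoints: tuple[str, ...] = KEYPOINTS
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.keypoints), 3):
            raise ValidationError(
                "positions must be (n_frames, n_keypoints, 3)")
        for k in self.keypoints:
            if k not in KEYPOINTS:
                raise ValidationError(f"unknown keypoint {k}")
        self.keypoints = tuple(self.keypoints)
        self.timestamps = _check_timebase(len(self.positions), self.fps,
                                          self.timestamps)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def point(self, name: str) -> np.ndarray:
        return self.positions[:, self.keypoints.index(name), :]

    def frame(self, i: int) -> KeypointFrame:
        return KeypointFrame(
            {k: self.positions[i, j].copy()
             for j, k in enumerate(self.keypoints)},
            timestamp=float(self.timestamps[i]))


# ---------------------------------------------------------------------------
# forward kinematics


def _rotate_in_plane(u: np.ndarray, normal: np.ndarray,
                     beta: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``u`` (rows, perpendicular to ``normal``) by angle
    ``beta`` (radians) about ``normal``."""
    c = np.cos(beta)[:, None]
    s = np.sin(beta)[:, None]
    return u * c + np.cross(np.broadcast_to(normal, u.shape), u) * s


def forward_kinematics_trajectory(traj: AngleTrajectory,
                                  skeleton: HandSkeleton) -> KeypointTrajectory:
    """Place every finger chain in its flexion plane for each frame.

    The wrist sits at the skeleton root; each successive segment is rotated
    about the finger's plane normal so that the interior angle at the joint
    equals the input.  Angles must lie in (0, 180]; a NaN angle marks that
    joint's distal keypoints missing.
    """
    ang = traj.angles
    bad = (ang <= 0) | (ang > 180.0 + 1e-12)
    if np.any(bad & np.isfinite(ang)):
        i, j = np.argwhere(bad & np.isfinite(ang))[0]
        f, jt = traj.joints[j]
        raise ValidationError(
            f"angle out of (0, 180] at frame {i}, joint {f}/{jt}: "
            f"{ang[i, j]:g} deg")

    T = traj.n_frames
    pos = np.full((T, len(KEYPOINTS), 3), np.nan)
    kp_index = {k: i for i, k in enumerate(KEYPOINTS)}
    pos[:, kp_index["wrist"], :] = skeleton.root

    col = {lab: i for i, lab in enumerate(traj.joints)}
    for f in FINGERS:
        labels = [(f, j) for j in ANGLE_JOINTS]
        if any(lab not in col for lab in labels):
            raise ValidationError(
                f"trajectory lacks the {f} joint angles needed for FK")
        d = skeleton.directions[f]
        n = skeleton.finger_planes[f]
        u = np.broadcast_to(d, (T, 3)).copy()
        p = np.broadcast_to(skeleton.root, (T, 3)).copy()
        # wrist -> MCP along the finger ray, then one bend per joint
        p = p + skeleton.segment_length(f, "wrist_mcp") * u
        pos[:, kp_index[f + "_mcp"], :] = p
        missing = np.zeros(T, dtype=bool)
        for joint, seg, kp in (("mcp", "mcp_pip", "_pip"),
                               ("pip", "pip_dip", "_dip"),
                               ("dip", "dip_tip", "_tip")):
            theta = np.radians(ang[:, col[(f, joint)]])
            missing |= ~np.isfinite(theta)
            beta = np.where(missing, 0.0, np.pi - theta)
            u = _rotate_in_plane(u, n, beta)
            p = p + skeleton.segment_length(f, seg) * u
            q = p.copy()
            q[missing] = np.nan
            pos[:, kp_index[f + kp], :] = q
    return KeypointTrajectory(pos, fps=traj.fps, timestamps=traj.timestamps)


def forward_kinematics(frame: JointAngleFrame,
                       skeleton: HandSkeleton) -> KeypointFrame:
    """Single-frame forward kinematics; see
    :func:`forward_kinematics_trajectory`."""
    labels = tuple(frame.angles.keys())
    traj = AngleTrajectory(
        np.array([[frame.angles[lab] for lab in labels]]),
        fps=30.0, joints=labels,
        timestamps=np.array([0.0]))
    kp = forward_kinematics_trajectory(traj, skeleton)
    return KeypointFrame(
        {k: kp.positions[0, i].copy() for i, k in enumerate(kp.keypoints)},
        timestamp=frame.timestamp)
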