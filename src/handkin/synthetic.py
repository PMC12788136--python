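"""Synthetic single-finger flexion-extension motion with a known error model.

Real evaluations of vision-based hand tracking compare model output against
optical motion capture.  This module generates the same kind of data with
known statistical structure: a ground-truth angle trajectory oscillating
between per-joint range-of-motion (ROM) bounds, its keypoints via forward
kinematics, and a corrupted "prediction" carrying constant bias, Gaussian
angular noise, high-frequency ripple, positional noise and frame dropout.
Because every corruption parameter is known, metric outputs can be checked
against closed forms (e.g. MPJAE of pure bias b is exactly |b|; MPJAE of
Gaussian noise sigma is sigma*sqrt(2/pi)).

Per-finger presets reproduce measured ROM bounds of single-finger
flexion-extension cycles captured at 30 fps (10 s clips, 300 frames).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import ValidationError
from .hand import (ANGLE_LABELS, AngleTrajectory, HandSkeleton,
                   KeypointTrajectory, forward_kinematics_trajectory)

#: default resting angle for joints without a prescribed ROM (near full
#: extension; strictly inside (0, 180] so FK stays valid)
REST_ANGLE_DEG = 178.0


@dataclass(frozen=True)
class MotionSpec:
    """Specification of a ground-truth motion.

    ``rom`` maps ``(finger, joint)`` to (min_deg, max_deg) bounds; joints
    not listed rest at a constant near-extension angle.  ``waveform`` is
    ``"sinusoid"`` or ``"minjerk"`` (minimum-jerk half-cycles between the
    bounds).  ``frequency_hz`` counts full flexion-extension cycles per
    second and must respect Nyquist.  ``phase`` (radians, per joint or
    scalar) shifts the cycle; 0 starts fully extended.
    """

    rom: dict[tuple[str, str], tuple[float, float]]
    frequency_hz: float = 0.5
    duration_s: float = 10.0
    fps: float = 30.0
    waveform: str = "sinusoid"
    phase: float | dict[tuple[str, str], float] = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.rom:
            raise ValidationError("MotionSpec needs at least one joint ROM")
        for lab, (lo, hi) in self.rom.items():
            if tuple(lab) not in ANGLE_LABELS:
                raise ValidationError(f"unknown joint label {lab}")
            if not (0.0 < lo < hi <= 180.0):
                raise ValidationError(
                    f"ROM for {lab} must satisfy 0 < min < max <= 180, "
                    f"got ({lo}, {hi})")
        if self.duration_s <= 0:
            raise ValidationError("duration must be > 0")
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if not (0.0 < self.frequency_hz < self.fps / 2):
            raise ValidationError(
                "frequency must be in (0, fps/2) (Nyquist)")
        if self.waveform not in ("sinusoid", "minjerk"):
            raise ValidationError(f"unknown waveform {self.waveform!r}")

    def phase_of(self, label: tuple[str, str]) -> float:
        if isinstance(self.phase, dict):
            return float(self.phase.get(label, 0.0))
        return float(self.phase)


@dataclass(frozen=True)
class ErrorModel:
    """Statistical corruption applied to a ground-truth motion.

    ``angle_bias_deg``: constant offset, scalar or per-joint map.
    ``angle_noise_sigma_deg``: i.i.d. Gaussian noise on every angle sample.
    ``keypoint_noise_sigma_mm``: i.i.d. Gaussian noise per keypoint
    coordinate. ``hf_ripple``: (frequency_hz, amplitude_deg) sinusoidal
    jitter added to every angle. ``dropout_rate``: fraction of whole frames
    marked missing. ``ar1_rho``: optional AR(1) temporal correlation of the
    angle noise (0 = i.i.d., the default used by all closed-form checks).
    """

    angle_bias_deg: float | dict[tuple[str, str], float] = 0.0
    angle_noise_sigma_deg: float = 0.0
    keypoint_noise_sigma_mm: float = 0.0
    hf_ripple: tuple[float, float] = (0.0, 0.0)
    dropout_rate: float = 0.0
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.angle_noise_sigma_deg < 0 or self.keypoint_noise_sigma_mm < 0:
            raise ValidationError("noise sigmas must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValidationError("ar1_rho must be in [0, 1)")
        f, a = self.hf_ripple
        if f < 0 or a < 0:
            raise ValidationError("ripple frequency/amplitude must be >= 0")

    def bias_of(self, label: tuple[str, str]) -> float:
        if isinstance(self.angle_bias_deg, dict):
            return float(self.angle_bias_deg.get(label, 0.0))
        return float(self.angle_bias_deg)


def _minjerk_cycle(phase: np.ndarray) -> np.ndarray:
    """Periodic 0->1->0 profile built from minimum-jerk half-cycles.

    ``phase`` in cycles (1.0 = one full flexion-extension); returns the
    normalised excursion s in [0, 1] with zero velocity and acceleration at
    the turning points.
    """
    tau = np.mod(phase, 1.0)
    half = np.where(tau < 0.5, tau * 2.0, (1.0 - tau) * 2.0)
    return 10 * half ** 3 - 15 * half ** 4 + 6 * half ** 5


def generate_motion(spec: MotionSpec,
                    skeleton: HandSkeleton) -> tuple[AngleTrajectory, KeypointTrajectory]:
    """Ground-truth motion: angles oscillating between the ROM bounds per
    the waveform, keypoints via forward kinematics.  Deterministic given the
    spec (the seed only matters for downstream corruption streams)."""
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    angles = np.full((n, len(ANGLE_LABELS)), REST_ANGLE_DEG)
    for j, lab in enumerate(ANGLE_LABELS):
        if lab not in spec.rom:
            continue
        lo, hi = spec.rom[lab]
        ph = spec.phase_of(lab)
        if spec.waveform == "sinusoid":
            # starts at the max (extension) for phase 0
            s = 0.5 + 0.5 * np.cos(2 * np.pi * spec.frequency_hz * t + ph)
        else:
            s = 1.0 - _minjerk_cycle(spec.frequency_hz * t + ph / (2 * np.pi))
        angles[:, j] = lo + (hi - lo) * s
    traj = AngleTrajectory(angles, fps=spec.fps, timestamps=t)
    return traj, forward_kinematics_trajectory(traj, skeleton)


def corrupt(gt: tuple[AngleTrajectory, KeypointTrajectory],
            model: ErrorModel,
            skeleton: HandSkeleton) -> tuple[AngleTrajectory, KeypointTrajectory]:
    """Corrupted "prediction" from a ground-truth motion.

    Bias, Gaussian angle noise and ripple are applied in the angle domain;
    keypoints are regenerated through forward kinematics from the corrupted
    angles (so angle- and position-domain errors stay kinematically
    consistent), then perturbed by independent Gaussian positional noise.
    Dropout marks whole frames missing in both outputs.  The returned angle
    trajectory keeps unclamped values (they may exceed 180 deg near full
    extension); angles are clamped into (0, 180] only for the internal FK
    call, whose domain is bounded.

    One seed drives independent, documented substreams (angle noise,
    keypoint noise, dropout), so each corruption is reproducible in
    isolation.
    """
    ang_traj, _ = gt
    ss = np.random.SeedSequence(model.seed)
    rng_angle, rng_kp, rng_drop = (np.random.default_rng(s)
                                   for s in ss.spawn(3))
    a = ang_traj.angles.copy()
    t = ang_traj.timestamps
    for j, lab in enumerate(ang_traj.joints):
        a[:, j] += model.bias_of(lab)
    if model.angle_noise_sigma_deg > 0:
        eps = rng_angle.normal(0.0, model.angle_noise_sigma_deg, a.shape)
        if model.ar1_rho > 0:
            rho = model.ar1_rho
            eps[0] /= math.sqrt(1 - rho ** 2)
            for i in range(1, len(eps)):
                eps[i] += rho * eps[i - 1]
            eps *= math.sqrt(1 - rho ** 2)
        a += eps
    rip_f, rip_a = model.hf_ripple
    if rip_a > 0 and rip_f > 0:
        if rip_f >= ang_traj.fps / 2:
            raise ValidationError("ripple frequency must respect Nyquist")
        a += rip_a * np.sin(2 * np.pi * rip_f * t)[:, None]

    fk_angles = np.clip(a, 1e-9, 180.0)
    fk_traj = AngleTrajectory(fk_angles, fps=ang_traj.fps,
                              joints=ang_traj.joints, timestamps=t)
    kp = forward_kinematics_trajectory(fk_traj, skeleton)
    pos = kp.positions
    if model.keypoint_noise_sigma_mm > 0:
        pos = pos + rng_kp.normal(0.0, model.keypoint_noise_sigma_mm,
                                  pos.shape)
    if model.dropout_rate > 0:
        drop = rng_drop.random(len(a)) < model.dropout_rate
        a[drop] = np.nan
        pos = pos.copy()
        pos[drop] = np.nan
    return (AngleTrajectory(a, fps=ang_traj.fps, joints=ang_traj.joints,
                            timestamps=t),
            KeypointTrajectory(pos, fps=kp.fps, keypoints=kp.keypoints,
                               timestamps=t))


def table2_presets(frequency_hz: float = 0.5, duration_s: float = 10.0,
                   fps: float = 30.0) -> dict[str, MotionSpec]:
    """One MotionSpec per finger with the packaged measured ROM bounds
    (single-finger flexion-extension, ground-truth mocap column)."""
    text = resources.files("handkin.data").joinpath(
        "rom_presets.yaml").read_text()
    doc = yaml.safe_load(text)
    out = {}
    for finger, joints in doc["fingers"].items():
        rom = {(finger, j): (float(lo), float(hi))
               for j, (lo, hi) in joints.items()}
        out[finger] = MotionSpec(rom=rom, frequency_hz=frequency_hz,
                                 duration_s=duration_s, fps=fps)
    return out
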