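"""Evaluation metrics for predicted vs ground-truth hand motion.

Angle-domain: MPJAE (mean per joint angle error), APCK (angle percentage of
correct keypoints) and its threshold curve / normalised AUC, MPJAVE (mean
per joint angular velocity error), SPARC (spectral arc length smoothness)
and the angular SPARC error.  Position-domain: MPJPE (mean per joint
position error, mm).  Plus the weighted keypoint-regression losses used for
model training/fine-tuning, evaluated as pure functions on arrays.

All paired metrics require frame-aligned inputs (same fps, frame count and
joint set); use :func:`handkin.kinematics.resample` first if they differ.
Missing samples (NaN) are excluded pairwise, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError
from .hand import AngleTrajectory, KeypointTrajectory
from .kinematics import angular_velocity

# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class MeanStd:
    """Mean +/- sample standard deviation (ddof=1) of n samples."""

    mean: float
    std: float
    n: int
    units: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("MeanStd needs n >= 1")
        if not math.isfinite(self.mean):
            raise ValidationError("MeanStd mean must be finite")
        if self.std < 0:
            raise ValidationError("MeanStd std must be >= 0")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.std:.2f}"


def _mean_std(values: np.ndarray, units: str) -> MeanStd:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no overlapping non-missing samples")
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return MeanStd(float(np.mean(v)), std, int(v.size), units)


@dataclass(frozen=True)
class APCKCurve:
    """APCK score over a threshold grid with the normalised AUC.

    ``auc`` is the trapezoidal area under the curve divided by the grid span,
    so it lies in [0, 1] and is comparable across grids.
    """

    thresholds: np.ndarray
    scores: np.ndarray
    auc: float

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        s = np.asarray(self.scores, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValidationError(
                "thresholds must be a strictly increasing grid >= 0")
        if np.any(np.diff(s) < -1e-12):
            raise ValidationError("APCK scores must be non-decreasing")
        if not (0.0 <= self.auc <= 1.0 + 1e-12):
            raise ValidationError("normalised AUC must lie in [0, 1]")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the 3D-joint, 2D-joint and MANO-parameter loss terms."""

    w3d: float = 0.05
    w2d: float = 0.01
    wmano: float = 0.0005

    def __post_init__(self):
        for name in ("w3d", "w2d", "wmano"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class SparcParams:
    """Parameters of the spectral arc length estimator.

    ``amplitude_threshold``: fraction of the DC amplitude below which the
    spectrum is considered noise when choosing the adaptive cutoff.
    ``max_cutoff_hz``: hard upper bound on the cutoff frequency.
    ``padding_factor``: the FFT length is this multiple of the next power of
    two above the series length (finer frequency grid, smoother arc length).
    """

    amplitude_threshold: float = 0.05
    max_cutoff_hz: float = 10.0
    padding_factor: int = 4

    def __post_init__(self):
        if not (0.0 < self.amplitude_threshold < 1.0):
            raise ValidationError("amplitude_threshold must be in (0, 1)")
        if self.max_cutoff_hz <= 0:
            raise ValidationError("max_cutoff_hz must be > 0")
        if int(self.padding_factor) != self.padding_factor or self.padding_factor < 1:
            raise ValidationError("padding_factor must be an integer >= 1")


# ---------------------------------------------------------------------------
# alignment helpers


def _aligned_angles(pred: AngleTrajectory, gt: AngleTrajectory,
                    joints=None) -> tuple[np.ndarray, np.ndarray, list]:
    if abs(pred.fps - gt.fps) > 1e-9 or pred.n_frames != gt.n_frames:
        raise AlignmentError(
            f"trajectories are misaligned (pred {pred.n_frames} frames @ "
            f"{pred.fps} fps, gt {gt.n_frames} @ {gt.fps}); resample one "
            f"onto the other's timebase first")
    sel = list(joints) if joints is not None else list(gt.joints)
    missing = [j for j in sel if j not in pred.joints or j not in gt.joints]
    if missing:
        raise AlignmentError(f"joints absent from both inputs: {missing}")
    p = np.column_stack([pred.column(*j) for j in sel])
    g = np.column_stack([gt.column(*j) for j in sel])
    return p, g, sel


def _aligned_keypoints(pred: KeypointTrajectory, gt: KeypointTrajectory):
    if abs(pred.fps - gt.fps) > 1e-9 or pred.n_frames != gt.n_frames:
        raise AlignmentError(
            "keypoint trajectories are misaligned; resample first")
    if set(pred.keypoints) != set(gt.keypoints):
        raise AlignmentError("keypoint sets differ")
    order = [pred.keypoints.index(k) for k in gt.keypoints]
    return pred.positions[:, order, :], gt.positions, list(gt.keypoints)


# ---------------------------------------------------------------------------
# angle-domain metrics


def angle_errors(pred: AngleTrajectory, gt: AngleTrajectory,
                 joints=None) -> np.ndarray:
    """|pred - gt| per (frame, joint), NaN where either side is missing."""
    p, g, _ = _aligned_angles(pred, gt, joints)
    return np.abs(p - g)


def mpjae(pred: AngleTrajectory, gt: AngleTrajectory, joints=None) -> MeanStd:
    """Mean per joint angle error: mean (and spread) of the absolute angle
    difference over all selected (joint, frame) samples, in degrees."""
    return _mean_std(angle_errors(pred, gt, joints), units="°")


def apck(pred: AngleTrajectory, gt: AngleTrajectory,
         threshold_deg: float, joints=None) -> float:
    """Fraction of angle samples with error strictly below the threshold."""
    e = angle_errors(pred, gt, joints)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValidationError("no overlapping non-missing samples")
    return float(np.mean(e < threshold_deg))


def apck_curve(pred: AngleTrajectory, gt: AngleTrajectory,
               thresholds=None, joints=None) -> APCKCurve:
    """APCK over a threshold grid (default 0-30 deg in 0.5 deg steps) with
    trapezoidal AUC normalised by the grid span."""
    t = np.arange(0.0, 30.0 + 1e-9, 0.5) if thresholds is None \
        else np.asarray(thresholds, dtype=float)
    if t.size == 0:
        raise ValidationError("threshold grid is empty")
    e = angle_errors(pred, gt, joints)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValidationError("no overlapping non-missing samples")
    scores = np.array([np.mean(e < tau) for tau in t])
    auc = float(np.trapezoid(scores, t) / (t[-1] - t[0]))
    return APCKCurve(t, scores, auc)


def mpjave(pred: AngleTrajectory, gt: AngleTrajectory, joints=None,
           smooth_window: int | None = None) -> MeanStd:
    """Mean per joint angular velocity error in deg/s.

    Velocities come from finite differences of each trajectory; only the
    flexion joints (MCP/PIP/DIP) carry angles, so the wrist and fingertip
    are inherently excluded (their velocity metrics are undefined).
    """
    _aligned_angles(pred, gt, joints)  # validate before differentiating
    vp = angular_velocity(pred, smooth_window=smooth_window)
    vg = angular_velocity(gt, smooth_window=smooth_window)
    sel = list(joints) if joints is not None else list(gt.joints)
    p = np.column_stack([vp.column(*j) for j in sel])
    g = np.column_stack([vg.column(*j) for j in sel])
    return _mean_std(np.abs(p - g), units="°/s")


# ---------------------------------------------------------------------------
# position-domain metric


def _umeyama_align(P: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Least-squares similarity transform (rotation+scale+translation) of
    point set P onto G; returns the transformed P."""
    mp, mg = P.mean(axis=0), G.mean(axis=0)
    Pc, Gc = P - mp, G - mg
    H = Pc.T @ Gc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    var_p = np.sum(Pc ** 2)
    scale = np.sum(S * np.diag(D)) / var_p if var_p > 0 else 1.0
    return scale * (Pc @ R.T) + mg


def mpjpe(pred: KeypointTrajectory, gt: KeypointTrajectory,
          alignment: str = "none") -> MeanStd:
    """Mean per joint position error: Euclidean distance between predicted
    and ground-truth keypoints, in mm, pooled over (keypoint, frame).

    ``alignment="procrustes"`` first maps each predicted frame onto the
    ground truth by the best rigid+scale transform; the default compares
    absolute positions in the shared frame.
    """
    if alignment not in ("none", "procrustes"):
        raise ValidationError(f"unknown alignment mode {alignment!r}")
    P, G, _ = _aligned_keypoints(pred, gt)
    if alignment == "procrustes":
        P = P.copy()
        for i in range(P.shape[0]):
            ok = np.isfinite(P[i]).all(axis=1) & np.isfinite(G[i]).all(axis=1)
            if ok.sum() >= 3:
                P[i, ok] = _umeyama_align(P[i, ok], G[i, ok])
    d = np.linalg.norm(P - G, axis=2)
    return _mean_std(d, units="mm")


def position_errors(pred: KeypointTrajectory,
                    gt: KeypointTrajectory) -> tuple[np.ndarray, list[str]]:
    """Per-(frame, keypoint) Euclidean distances in mm with keypoint names."""
    P, G, names = _aligned_keypoints(pred, gt)
    return np.linalg.norm(P - G, axis=2), names


# ---------------------------------------------------------------------------
# smoothness (spectral arc length)


def sparc(angle_series: np.ndarray, fps: float,
          params: SparcParams = SparcParams(),
          on: str = "speed") -> float:
    """Spectral arc length of one joint's angle series (dimensionless, < 0;
    closer to 0 = smoother motion).

    The angular speed profile |d(theta)/dt| (or the raw angle series with
    ``on="angle"``) is zero-padded, its magnitude spectrum normalised by the
    DC amplitude, an adaptive cutoff chosen as the smaller of
    ``max_cutoff_hz`` and the highest frequency where the normalised
    spectrum still reaches ``amplitude_threshold``, and the negative arc
    length of the normalised spectrum up to the cutoff (frequency axis
    normalised by the cutoff) is returned.

    A constant series has an all-zero speed profile with no defined
    spectrum; NaN is returned as a flagged sentinel and such joints are
    excluded from aggregation.
    """
    x = np.asarray(angle_series, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValidationError("SPARC needs a 1-D series of >= 16 frames")
    if fps <= 0:
        raise ValidationError("fps must be > 0")
    if not np.isfinite(x).all():
        return float("nan")
    if on == "speed":
        v = np.abs(np.gradient(x) * fps)
    elif on == "angle":
        v = x.astype(float)
    else:
        raise ValidationError(f"unknown SPARC mode {on!r}")
    nfft = int(params.padding_factor * 2 ** math.ceil(math.log2(len(v))))
    spec = np.abs(np.fft.rfft(v, nfft))
    if spec[0] <= 0:
        return float("nan")  # degenerate: no DC content to normalise by
    freqs = np.arange(spec.size) * (fps / nfft)
    vhat = spec / spec[0]
    above = np.nonzero(vhat >= params.amplitude_threshold)[0]
    cutoff = min(params.max_cutoff_hz, float(freqs[above[-1]]))
    if cutoff <= 0:
        return float("nan")
    band = freqs <= cutoff
    if band.sum() < 2:
        return float("nan")
    f, s = freqs[band], vhat[band]
    df = np.diff(f) / cutoff
    ds = np.diff(s)
    return float(-np.sum(np.sqrt(df ** 2 + ds ** 2)))


def angular_sparc_error(pred: AngleTrajectory, gt: AngleTrajectory,
                        params: SparcParams = SparcParams(),
                        joints=None) -> MeanStd:
    """Absolute SPARC difference |SPARC(pred) - SPARC(gt)| per joint,
    aggregated across joints.  Joints degenerate on either side (constant
    angle, no speed spectrum) are excluded."""
    _aligned_angles(pred, gt, joints)
    sel = list(joints) if joints is not None else list(gt.joints)
    diffs = []
    for j in sel:
        sp = sparc(pred.column(*j), pred.fps, params)
        sg = sparc(gt.column(*j), gt.fps, params)
        if math.isfinite(sp) and math.isfinite(sg):
            diffs.append(abs(sp - sg))
    if not diffs:
        raise ValidationError("no joint has a defined SPARC on both sides")
    return _mean_std(np.array(diffs), units="")


def sparc_errors_per_joint(pred: AngleTrajectory, gt: AngleTrajectory,
                           params: SparcParams = SparcParams()
                           ) -> dict[tuple[str, str], float]:
    """|SPARC(pred) - SPARC(gt)| per joint; NaN marks degenerate joints."""
    _aligned_angles(pred, gt)
    out = {}
    for j in gt.joints:
        sp = sparc(pred.column(*j), pred.fps, params)
        sg = sparc(gt.column(*j), gt.fps, params)
        out[j] = abs(sp - sg) if math.isfinite(sp) and math.isfinite(sg) \
            else float("nan")
    return out


# ---------------------------------------------------------------------------
# training / fine-tuning losses


def _elementwise_norm(a: np.ndarray, b: np.ndarray, norm: str) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"shape mismatch in loss term: {a.shape} vs {b.shape}")
    d = a - b
    if norm == "l1":
        return float(np.mean(np.abs(d)))
    if norm == "l2":
        return float(np.sqrt(np.mean(d ** 2)))
    raise ValidationError(f"unknown norm {norm!r}; use 'l1' or 'l2'")


def finetune_loss(X, X_gt, norm: str = "l1") -> float:
    """Fine-tuning loss: the 3D joint position term alone, ||X - X*||."""
    return _elementwise_norm(X, X_gt, norm)


def training_loss(X, X_gt, x2d, x2d_gt, theta, theta_gt, beta, beta_gt,
                  weights: LossWeights = LossWeights(),
                  norm: str = "l1") -> float:
    """Weighted sum of 3D joint, 2D joint and MANO-parameter losses:

        L = w3D ||X - X*|| + w2D ||x - x*|| + wMANO (||theta - theta*|| + ||beta - beta*||)

    with ||.|| the selected per-element-averaged norm.  Pure evaluation on
    arrays; no gradients or training loop.
    """
    l3d = _elementwise_norm(X, X_gt, norm)
    l2d = _elementwise_norm(x2d, x2d_gt, norm)
    lmano = (_elementwise_norm(theta, theta_gt, norm)
             + _elementwise_norm(beta, beta_gt, norm))
    return weights.w3d * l3d + weights.w2d * l2d + weights.wmano * lmano


# ---------------------------------------------------------------------------
# aggregation


#: joint classes whose velocity/smoothness cells are undefined: no
#: flexion-extension angle exists at the wrist or the fingertip.
VELOCITY_UNDEFINED_CLASSES = frozenset({"Wrist", "Tip"})
VELOCITY_METRICS = frozenset({"mpjave", "sparc_error"})


def joint_class(joint: str) -> str:
    """Map a joint/keypoint slot to its report class (thumb TM/MCP/IP ride
    the same MCP/PIP/DIP slots)."""
    m = {"wrist": "Wrist", "mcp": "MCP", "pip": "PIP", "dip": "DIP",
         "tip": "Tip"}
    try:
        return m[joint.lower()]
    except KeyError:
        raise ValidationError(f"unknown joint {joint!r}") from None


@dataclass
class MetricReport:
    """Per-joint-class and pooled-overall mean +/- std of each metric.

    ``cells[metric][class]`` is a :class:`MeanStd`, or None for N/A cells
    (velocity/smoothness metrics at the wrist and fingertip, or empty
    classes).  Overall pools samples across classes (sample-weighted), not
    a mean of class means.
    """

    method: str
    classes: tuple[str, ...]
    cells: dict[str, dict[str, MeanStd | None]] = field(default_factory=dict)

    def metrics(self) -> list[str]:
        return list(self.cells)


def aggregate_report(samples, method: str = "pred",
                     classes: tuple[str, ...] | None = None) -> MetricReport:
    """Aggregate per-sample metric values into a per-class report.

    ``samples`` is a pandas DataFrame with columns
    ``metric, finger, joint, frame, value`` (one row per sample; NaN values
    are excluded with the rest of the class).  Classes default to the ones
    present, ordered Wrist, MCP, PIP, DIP, Tip.
    """
    import pandas as pd

    df = pd.DataFrame(samples)
    required = {"metric", "joint", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"samples must have columns {sorted(required)}")
    df = df.assign(cls=df["joint"].map(joint_class))
    order = ["Wrist", "MCP", "PIP", "DIP", "Tip"]
    present = [c for c in order if c in set(df["cls"])]
    cls_list = tuple(classes) if classes is not None else tuple(present)

    units = {"mpjae": "°", "mpjpe": "mm", "mpjave": "°/s",
             "sparc_error": "", "apck": ""}
    cells: dict[str, dict[str, MeanStd | None]] = {}
    for metric, sub in df.groupby("metric", sort=True):
        u = units.get(str(metric), "")
        row: dict[str, MeanStd | None] = {}
        pooled = []
        for c in cls_list:
            if str(metric) in VELOCITY_METRICS and c in VELOCITY_UNDEFINED_CLASSES:
                row[c] = None
                continue
            vals = sub.loc[sub["cls"] == c, "value"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[c] = None
                continue
            row[c] = _mean_std(vals, u)
            pooled.append(vals)
        row["Overall"] = _mean_std(np.concatenate(pooled), u) if pooled else None
        cells[str(metric)] = row
    return MetricReport(method=method, classes=cls_list + ("Overall",),
                        cells=cells)
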