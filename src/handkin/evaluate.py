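"""End-to-end evaluation of a predicted trajectory against ground truth.

Combines the individual metrics into one per-joint-class report (angle
error, APCK at chosen thresholds, angular velocity error, angular SPARC
error, and — when keypoint trajectories are supplied — position error),
mirroring the standard evaluation tables of hand-tracking studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hand import AngleTrajectory, KeypointTrajectory
from .kinematics import angular_velocity
from .metrics import (APCKCurve, MetricReport, SparcParams, aggregate_report,
                      angle_errors, apck_curve, position_errors,
                      sparc_errors_per_joint)


def _angle_rows(pred: AngleTrajectory, gt: AngleTrajectory,
                apck_thresholds) -> list[tuple]:
    rows = []
    err = angle_errors(pred, gt)
    vp = angular_velocity(pred).velocities
    vg = angular_velocity(gt).velocities
    joints = list(gt.joints)
    vcols = {j: list(pred.joints).index(j) for j in joints}
    for c, (finger, joint) in enumerate(joints):
        e = err[:, c]
        for i in np.nonzero(np.isfinite(e))[0]:
            rows.append(("mpjae", finger, joint, int(i), float(e[i])))
            for tau in apck_thresholds:
                rows.append((f"apck@{tau:g}", finger, joint, int(i),
                             float(e[i] < tau)))
        dv = np.abs(vp[:, vcols[(finger, joint)]] - vg[:, c])
        for i in np.nonzero(np.isfinite(dv))[0]:
            rows.append(("mpjave", finger, joint, int(i), float(dv[i])))
    return rows


def evaluate_pair(pred_angles: AngleTrajectory, gt_angles: AngleTrajectory,
                  pred_keypoints: KeypointTrajectory | None = None,
                  gt_keypoints: KeypointTrajectory | None = None,
                  apck_thresholds: tuple[float, ...] = (5.0, 10.0),
                  apck_grid=None,
                  sparc_params: SparcParams = SparcParams(),
                  method: str = "pred"
                  ) -> tuple[MetricReport, APCKCurve]:
    """Full metric report plus the pooled APCK threshold curve.

    Velocity and smoothness cells exist only for the flexion joints
    (MCP/PIP/DIP); wrist and fingertip rows, present when keypoints are
    given, carry N/A there.
    """
    rows = _angle_rows(pred_angles, gt_angles, apck_thresholds)
    for (finger, joint), v in sparc_errors_per_joint(
            pred_angles, gt_angles, sparc_params).items():
        if np.isfinite(v):
            rows.append(("sparc_error", finger, joint, 0, float(v)))
    if pred_keypoints is not None and gt_keypoints is not None:
        dist, names = position_errors(pred_keypoints, gt_keypoints)
        for k, name in enumerate(names):
            finger, joint = ("wrist", "wrist") if name == "wrist" \
                else tuple(name.split("_", 1))
            d = dist[:, k]
            for i in np.nonzero(np.isfinite(d))[0]:
                rows.append(("mpjpe", finger, joint, int(i), float(d[i])))
    samples = pd.DataFrame(rows, columns=["metric", "finger", "joint",
                                          "frame", "value"])
    report = aggregate_report(samples, method=method)
    # stable column order for serialisation
    order = (["mpjae"] + [f"apck@{t:g}" for t in apck_thresholds]
             + ["mpjpe", "mpjave", "sparc_error"])
    report.cells = {m: report.cells[m] for m in order if m in report.cells}
    curve = apck_curve(pred_angles, gt_angles, thresholds=apck_grid)
    return report, curve
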